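"""Candidate assignment enumeration.

Generates every admissible hypothesis pairing the sample's unlabeled
peaks with target compounds, applying the three elimination rules —
injectivity, strict elution-order preservation, and the RT cutoff
window — plus internal-standard partitioning.  The walk is a lazy
depth-first generator: the full combinatorial set is never
materialized.
"""

from __future__ import annotations

import math
from typing import Iterator, Sequence

from .core import (
    INTERFERENT,
    Assignment,
    MatchConfig,
    PeakList,
    RTTLib,
    RTTLibrary,
    ValidationError,
)

__all__ = [
    "count_candidates",
    "enumerate_candidates",
    "partition_by_standards",
    "admissible_compounds",
    "diagnose_empty",
]


def count_candidates(n_tgt: int, n_sample: int) -> int:
    """Number of injective, order-preserving assignments of ``n_sample``
    peaks to ``n_tgt`` compounds with no interferents and no RT cutoff.

    This is the binomial coefficient C(n_tgt, n_sample): choosing which
    compounds are present fixes the assignment, because elution order
    forces the pairing.
    """
    if n_tgt < 1:
        raise ValidationError("n_tgt must be positive")
    if not 0 <= n_sample <= n_tgt:
        raise ValidationError(
            f"need 0 <= n_sample <= n_tgt, got n_sample={n_sample}, n_tgt={n_tgt}"
        )
    return math.comb(n_tgt, n_sample)


def partition_by_standards(
    peaks: PeakList, library: RTTLibrary
) -> dict[int, tuple[int, int]]:
    """Admissible compound-id interval per unlabeled peak.

    Labeled standard peaks split the trajectory diagram into regions: a
    peak eluting between two standard peaks can only be a compound
    eluting between those standards in the library.  Because every
    trajectory preserves the roster's elution order and ids are
    elution ranks, the interval is the same in all trajectories.

    Returns ``{peak_index: (lo_id, hi_id)}`` (closed interval; ids
    outside it are excluded).  With no labeled standards every peak
    maps to the full id range.
    """
    ids = library.roster.ids
    lo_all, hi_all = ids[0], ids[-1]
    anchors = sorted(
        (peaks.peaks[i].rt, cid) for i, cid in peaks.std_labels.items()
    )
    out: dict[int, tuple[int, int]] = {}
    for j in peaks.unlabeled_indices:
        rt = peaks.peaks[j].rt
        lo, hi = lo_all, hi_all
        for anchor_rt, anchor_cid in anchors:
            if anchor_rt < rt:
                lo = max(lo, anchor_cid + 1)
            else:
                hi = min(hi, anchor_cid - 1)
        out[j] = (lo, hi)
    return out


def admissible_compounds(
    peaks: PeakList,
    library: RTTLibrary,
    cfg: MatchConfig,
    libs: Sequence[RTTLib] | None = None,
) -> list[tuple[int, ...]]:
    """Per unlabeled peak (in rt order), the sorted tuple of target ids
    it may be paired with.

    A pair (peak, compound) is admissible if ANY trajectory in ``libs``
    (default: the whole library) puts the compound within
    ``cfg.delta_t`` of the peak, and the compound id lies inside the
    peak's standard-partition interval.
    """
    libs = list(libs) if libs is not None else list(library.libs)
    intervals = partition_by_standards(peaks, library)
    targets = library.roster.target_ids
    out = []
    for j in peaks.unlabeled_indices:
        rt = peaks.peaks[j].rt
        lo, hi = intervals[j]
        adm = tuple(
            cid
            for cid in targets
            if lo <= cid <= hi
            and any(abs(lib.rts[cid] - rt) <= cfg.delta_t for lib in libs)
        )
        out.append(adm)
    return out


def _min_library_distance(rt: float, library: RTTLibrary) -> float:
    return min(abs(lib.rts[cid] - rt) for lib in library.libs for cid in lib.rts)


def enumerate_candidates(
    peaks: PeakList,
    library: RTTLibrary,
    cfg: MatchConfig | None = None,
    libs: Sequence[RTTLib] | None = None,
) -> Iterator[Assignment]:
    """Lazily yield every admissible :class:`Assignment`.

    The depth-first walk assigns compounds to peaks in retention-time
    order, pruning at each step by injectivity, elution order and the
    RT cutoff.  When ``cfg.allow_interferents`` is set, a peak may
    carry the interferent label instead of a compound — but only if it
    is far enough from every library RT (``interferent_gate_frac *
    delta_t``), has no admissible compound at all, or fails the ± delta_t
    out-of-range criterion (in which case the label is mandatory).
    """
    cfg = cfg or MatchConfig()
    peaks.validate(library.roster)
    adm = admissible_compounds(peaks, library, cfg, libs)
    n = len(adm)
    n_tgt = library.roster.n_tgt

    if not cfg.allow_interferents and peaks.n_sample > n_tgt:
        raise ValidationError(
            f"{peaks.n_sample} peaks but only {n_tgt} targets; "
            "enable interferent handling"
        )

    # Which peaks may (or must) carry the interferent label.
    gate = cfg.interferent_gate_frac * cfg.delta_t
    forced = [False] * n
    optional = [False] * n
    if cfg.allow_interferents:
        for p, j in enumerate(peaks.unlabeled_indices):
            rt = peaks.peaks[j].rt
            dist = _min_library_distance(rt, library)
            if dist > cfg.delta_t or not adm[p]:
                forced[p] = True
            elif dist > gate:
                optional[p] = True

    def walk(p: int, last_id: int, chosen: list[int]) -> Iterator[Assignment]:
        if p == n:
            yield Assignment(tuple(chosen))
            return
        if not forced[p]:
            for cid in adm[p]:
                if cid > last_id:
                    chosen.append(cid)
                    yield from walk(p + 1, cid, chosen)
                    chosen.pop()
        if forced[p] or optional[p]:
            chosen.append(INTERFERENT)
            yield from walk(p + 1, last_id, chosen)
            chosen.pop()

    return walk(0, 0, [])


def diagnose_empty(
    peaks: PeakList,
    library: RTTLibrary,
    cfg: MatchConfig,
    libs: Sequence[RTTLib] | None = None,
) -> str:
    """Explain why the candidate stream came out empty."""
    adm = admissible_compounds(peaks, library, cfg, libs)
    for a, j in zip(adm, peaks.unlabeled_indices):
        if not a:
            rt = peaks.peaks[j].rt
            return (
                f"delta_t too small: peak at {rt:.6g} s matches no compound "
                f"within ±{cfg.delta_t:.6g} s"
            )
    return (
        "order conflict: every peak has admissible compounds but no injective, "
        "order-preserving combination exists"
    )
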