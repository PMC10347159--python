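"""Interferent detection.

Two criteria flag a peak as a non-target interferent:

1. out-of-range — no library retention time falls within
   ``peak_rt ± delta_t``;
2. residual-based — after matching, the peak's squared residual
   against the matched trajectory is much larger (by default twice)
   than the pair's MSR.

After relabeling, the MSR is renormalized over the remaining
contributing pairs only.
"""

from __future__ import annotations

from dataclasses import replace

from .core import (
    INTERFERENT,
    Assignment,
    MatchConfig,
    MatchResult,
    PeakList,
    RTTLib,
    RTTLibrary,
)
from .match import ssr_std

__all__ = ["flag_out_of_range", "refine_interferents", "NOTE_DEMOTED", "is_demoted"]

#: Attached when the majority guard stops a refinement cascade; demoted
#: results sort after all others regardless of MSR.
NOTE_DEMOTED = (
    "majority of peaks would be interferents; result demoted (method validity reduced)"
)


def is_demoted(result: MatchResult) -> bool:
    return NOTE_DEMOTED in result.notes


def flag_out_of_range(peak_rt: float, library: RTTLibrary, delta_t: float) -> bool:
    """True iff no compound RT in any trajectory lies within
    ``[peak_rt - delta_t, peak_rt + delta_t]`` (closed interval)."""
    if not delta_t > 0:
        raise ValueError("delta_t must be positive")
    return all(
        abs(rt - peak_rt) > delta_t for lib in library.libs for rt in lib.rts.values()
    )


def refine_interferents(
    result: MatchResult,
    peaks: PeakList,
    lib: RTTLib,
    cfg: MatchConfig | None = None,
    library: RTTLibrary | None = None,
) -> MatchResult:
    """Greedily relabel outlier peaks as interferents and renormalize.

    One peak at a time — always the one with the largest squared
    residual — is relabeled interferent if its residual exceeds
    ``cfg.interferent_factor`` times the current MSR; the MSR is then
    recomputed with the residual removed and the denominator reduced.
    Only interferent-plausible peaks — those farther than
    ``cfg.interferent_gate_frac * cfg.delta_t`` from every RT of the
    matched trajectory (or of every trajectory, when the full
    ``library`` is supplied) — may be relabeled: a peak sitting on top
    of a library RT is a drifted target, however its residual compares
    to the others'.  Stops when no peak qualifies, when relabeling would
    leave nothing to normalize by, or when a majority of non-standard
    peaks would be interferents (the result is then demoted in the
    common ranking).  Refinement is idempotent and strictly decreases
    the MSR at every step.
    """
    cfg = cfg or MatchConfig()
    mapping = list(result.assignment.mapping)
    rts = peaks.unlabeled_rts
    n_std = len(peaks.std_labels)
    n_unlabeled = len(mapping)

    gate = cfg.interferent_gate_frac * cfg.delta_t
    if library is not None:
        lib_rts = [rt for l in library.libs for rt in l.rts.values()]
    else:
        lib_rts = list(lib.rts.values())
    base_std = ssr_std(lib, peaks)
    residuals = {
        p: (lib.rts[cid] - rts[p]) ** 2
        for p, cid in enumerate(mapping)
        if cid != INTERFERENT
    }
    plausible = {
        p for p in residuals if min(abs(rt - rts[p]) for rt in lib_rts) > gate
    }
    notes = list(result.notes)

    def totals() -> tuple[float, int]:
        return base_std + sum(residuals.values()), n_std + len(residuals)

    while residuals and plausible & residuals.keys():
        total, denom = totals()
        current_msr = total / denom
        p_max = max(plausible & residuals.keys(), key=lambda p: (residuals[p], p))
        if residuals[p_max] <= cfg.interferent_factor * current_msr:
            break
        if denom - 1 == 0:
            notes.append("refinement stopped: relabeling would leave nothing to normalize")
            break
        n_interf_next = (n_unlabeled - len(residuals)) + 1
        if n_interf_next > n_unlabeled / 2:
            if NOTE_DEMOTED not in notes:
                notes.append(NOTE_DEMOTED)
            break
        residuals.pop(p_max)
        mapping[p_max] = INTERFERENT

    new_assignment = Assignment(tuple(mapping))
    if new_assignment == result.assignment and tuple(notes) == result.notes:
        return result
    total, denom = totals()
    if denom == 0:
        return replace(result, notes=tuple(notes))
    return MatchResult(
        new_assignment, result.lib_label, total, total / denom, result.rank, tuple(notes)
    )
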