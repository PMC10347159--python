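"""Trajectory similarity scoring and ranking.

Matching proceeds in two stages: the library is first screened by the
sum of squared internal-standard residuals (SSR_std), then every
candidate assignment is scored against each retained trajectory by the
mean squared residual (MSR) over standards plus assigned target pairs.
The assignment/trajectory pair with the smallest MSR is the
identification.
"""

from __future__ import annotations

import heapq
import logging
from typing import Sequence

import numpy as np

from .core import (
    INTERFERENT,
    Assignment,
    MatchConfig,
    MatchResult,
    PeakList,
    RTTLib,
    RTTLibrary,
    RTTError,
    validate_assignment,
)
from .enumerate import diagnose_empty, enumerate_candidates

__all__ = ["ssr_std", "screen_libraries", "msr", "match_sample"]

log = logging.getLogger(__name__)


def ssr_std(lib: RTTLib, peaks: PeakList) -> float:
    """Sum of squared standard residuals between a trajectory and the
    sample; 0 when the sample has no labeled standards."""
    total = 0.0
    for cid, sample_rt in peaks.standard_rts.items():
        if cid not in lib.rts:
            raise RTTError(f"standard {cid} missing from trajectory {lib.label!r}")
        total += (lib.rts[cid] - sample_rt) ** 2
    return total


def screen_libraries(
    library: RTTLibrary, peaks: PeakList, cfg: MatchConfig
) -> list[RTTLib]:
    """Retain the trajectories best anchored by the internal standards.

    Trajectories are sorted by ascending :func:`ssr_std` (ties broken
    by label) and truncated per ``cfg.screen_rule``.  With no labeled
    standards, screening is skipped and all trajectories are returned
    in input order.
    """
    if not peaks.std_labels:
        return list(library.libs)
    scored = sorted(library.libs, key=lambda lib: (ssr_std(lib, peaks), lib.label))
    return scored[: cfg.screen_rule.n_keep(library.n_lib)]


def msr(lib: RTTLib, assignment: Assignment, peaks: PeakList) -> float:
    """Mean squared residual of one assignment against one trajectory.

    (SSR over standards + SSR over non-interferent target pairs)
    divided by (N_std + N_sample - N_interf).  Interferent-labeled
    peaks contribute neither residual nor count.
    """
    validate_assignment(assignment)
    denom = len(peaks.std_labels) + peaks.n_sample - assignment.n_interf
    if denom == 0:
        raise RTTError("vacuous assignment: no standards and every peak is an interferent")
    total = ssr_std(lib, peaks)
    for rt, cid in zip(peaks.unlabeled_rts, assignment.mapping):
        if cid == INTERFERENT:
            continue
        total += (lib.rts[cid] - rt) ** 2
    return total / denom


def _result_key(r: MatchResult):
    from .interferent import is_demoted

    return (is_demoted(r), r.msr, r.assignment.n_interf, r.assignment.sort_key(), r.lib_label)


def match_sample(
    peaks: PeakList,
    library: RTTLibrary,
    cfg: MatchConfig | None = None,
) -> list[MatchResult]:
    """Score all admissible assignments and rank them by minimal MSR.

    For each candidate the minimum MSR over the screened trajectories
    is taken; results are sorted ascending by that value (ties: fewer
    interferents, then lexicographic compound sequence, then trajectory
    label), ranked from 1, and truncated to ``cfg.max_results``.  When
    interferent handling is enabled, a residual-refined variant of each
    kept result joins the common ranking.

    Returns an empty list (with a logged diagnostic) when no candidate
    is admissible.
    """
    cfg = cfg or MatchConfig()
    peaks.validate(library.roster)
    retained = screen_libraries(library, peaks, cfg)
    n_retained = len(retained)

    roster = library.roster
    max_id = roster.ids[-1]
    # trajectory RT matrix indexed by compound id
    L = np.zeros((n_retained, max_id + 1))
    for i, lib in enumerate(retained):
        for cid, rt in lib.rts.items():
            L[i, cid] = rt
    ssr0 = np.array([ssr_std(lib, peaks) for lib in retained])
    rts = np.asarray(peaks.unlabeled_rts)
    n_std = len(peaks.std_labels)
    n_sample = peaks.n_sample

    # keep enough results that post-hoc interferent refinement of a
    # lower-ranked candidate can still surface at the top
    keep = max(cfg.max_results, 64) if cfg.allow_interferents else cfg.max_results
    heap: list = []  # max-heap (via _Rev) of the `keep` best results
    counter = 0
    n_candidates = 0
    for assignment in enumerate_candidates(peaks, library, cfg, retained):
        n_candidates += 1
        mask = np.fromiter(
            (cid != INTERFERENT for cid in assignment.mapping), bool, len(assignment.mapping)
        )
        ids = [cid for cid in assignment.mapping if cid != INTERFERENT]
        denom = n_std + n_sample - assignment.n_interf
        if denom == 0:
            continue
        res = ((L[:, ids] - rts[mask]) ** 2).sum(axis=1) if ids else 0.0
        totals = ssr0 + res
        msrs = totals / denom
        i_best = int(np.argmin(msrs))
        result = MatchResult(
            assignment, retained[i_best].label, float(totals[i_best]), float(msrs[i_best])
        )
        key = _result_key(result)
        counter += 1
        if len(heap) < keep:
            heapq.heappush(heap, (_Rev(key), counter, result))
        elif key < heap[0][0].key:
            heapq.heapreplace(heap, (_Rev(key), counter, result))

    if n_candidates == 0:
        log.warning("no admissible candidate: %s", diagnose_empty(peaks, library, cfg, retained))
        return []

    results = [r for _, _, r in heap]

    if cfg.allow_interferents:
        from .interferent import refine_interferents

        by_label = {lib.label: lib for lib in retained}
        refined_extra = []
        seen = {(r.assignment, r.lib_label) for r in results}
        for r in results:
            refined = refine_interferents(r, peaks, by_label[r.lib_label], cfg, library=library)
            key = (refined.assignment, refined.lib_label)
            if key not in seen:
                seen.add(key)
                refined_extra.append(refined)
        results += refined_extra

    results.sort(key=_result_key)
    out = []
    for rank, r in enumerate(results[: cfg.max_results], start=1):
        out.append(
            MatchResult(r.assignment, r.lib_label, r.ssr, r.msr, rank, r.notes)
        )
    log.info(
        "matched %d candidates against %d/%d trajectories; best MSR %.6g",
        n_candidates,
        n_retained,
        library.n_lib,
        out[0].msr if out else float("nan"),
    )
    return out


class _Rev:
    """Reverses comparison order, for max-heap behavior via heapq."""

    __slots__ = ("key",)

    def __init__(self, key):
        self.key = key

    def __lt__(self, other):
        return self.key > other.key

    def __gt__(self, other):
        return self.key < other.key

    def __eq__(self, other):
        return self.key == other.key
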