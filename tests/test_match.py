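import itertools
import math

import numpy as np
import pytest

import rttmatch as rtt
from rttmatch.core import (
    Assignment,
    MatchConfig,
    Peak,
    PeakList,
    RTTLib,
    RTTLibrary,
    ScreenRule,
)
from rttmatch.match import match_sample, msr, screen_libraries, ssr_std

from conftest import envelope_sample_lib, make_library, make_roster, peak_list


def std_peaklist(pairs, std_map):
    """pairs: iterable of rt; std_map: rt -> std id."""
    rts = sorted(pairs)
    labels = {i: std_map[rt] for i, rt in enumerate(rts) if rt in std_map}
    return PeakList(tuple(Peak(rt) for rt in rts), labels)


class TestSSRStd:
    def test_identity_is_zero(self):
        roster = make_roster(3, std_ids=(1, 3))
        lib = make_library(roster, {"a": [100.0, 150.0, 200.0]}).libs[0]
        peaks = std_peaklist([100.0, 200.0], {100.0: 1, 200.0: 3})
        assert ssr_std(lib, peaks) == 0.0

    def test_direct_arithmetic(self):
        roster = make_roster(3, std_ids=(1, 3))
        lib = make_library(roster, {"a": [100.0, 150.0, 200.0]}).libs[0]
        peaks = std_peaklist([101.0, 198.0], {101.0: 1, 198.0: 3})
        assert ssr_std(lib, peaks) == pytest.approx(1.0 + 4.0)

    def test_no_standards_is_zero(self, tiny_library):
        assert ssr_std(tiny_library.libs[0], peak_list([15.0])) == 0.0

    def test_term_by_term_oracle(self):
        rng = np.random.default_rng(11)
        n_std = 4
        std_ids = (2, 4, 6, 8)
        roster = make_roster(9, std_ids=std_ids)
        base = np.sort(rng.uniform(10, 500, 9))
        lib = make_library(roster, {"a": base.tolist()}).libs[0]
        sample_std_rts = {cid: lib.rts[cid] + rng.normal(0, 2) for cid in std_ids}
        peaks = std_peaklist(sorted(sample_std_rts.values()),
                             {rt: cid for cid, rt in sample_std_rts.items()})
        expected = 0.0
        for cid in std_ids:  # independent per-term accumulation
            expected += (lib.rts[cid] - sample_std_rts[cid]) ** 2
        assert ssr_std(lib, peaks) == pytest.approx(expected, rel=1e-12)


class TestScreening:
    def _library_six(self):
        roster = make_roster(3, std_ids=(1, 3))
        rows = {f"c{i}": [100.0 + i, 150.0, 200.0 + 2 * i] for i in range(6)}
        return make_library(roster, rows)

    def test_keep_fraction_half(self):
        library = self._library_six()
        peaks = std_peaklist([100.0, 200.0], {100.0: 1, 200.0: 3})
        cfg = MatchConfig(screen_rule=ScreenRule.keep_fraction(0.5))
        kept = screen_libraries(library, peaks, cfg)
        assert [lib.label for lib in kept] == ["c0", "c1", "c2"]

    def test_keep_all_is_sorted_identity(self):
        library = self._library_six()
        peaks = std_peaklist([103.0, 206.0], {103.0: 1, 206.0: 3})
        cfg = MatchConfig(screen_rule=ScreenRule.keep_all())
        kept = screen_libraries(library, peaks, cfg)
        assert {lib.label for lib in kept} == {lib.label for lib in library.libs}
        ssrs = [ssr_std(lib, peaks) for lib in kept]
        assert ssrs == sorted(ssrs)

    def test_ties_broken_by_label_stable_sort_oracle(self):
        roster = make_roster(2, std_ids=(1,))
        rows = {"z": [100.0, 200.0], "a": [100.0, 210.0], "m": [100.0, 220.0]}
        library = make_library(roster, rows)
        peaks = std_peaklist([100.0], {100.0: 1})
        kept = screen_libraries(library, peaks, MatchConfig(screen_rule=ScreenRule.keep_all()))
        # oracle: pre-sort by label, then stable-sort by ssr
        by_label = sorted(library.libs, key=lambda l: l.label)
        expected = sorted(by_label, key=lambda l: ssr_std(l, peaks))
        assert [l.label for l in kept] == [l.label for l in expected]

    def test_no_standards_keeps_all_in_input_order(self, tiny_library):
        kept = screen_libraries(tiny_library, peak_list([12.0]), MatchConfig())
        assert kept == list(tiny_library.libs)

    def test_floor_raises_retained_count(self):
        library = self._library_six()
        peaks = std_peaklist([100.0, 200.0], {100.0: 1, 200.0: 3})
        cfg = MatchConfig(screen_rule=ScreenRule.keep_fraction(0.5, floor=20))
        assert len(screen_libraries(library, peaks, cfg)) == 6


class TestMSR:
    def _setup(self):
        roster = make_roster(5, std_ids=(1, 5))
        lib = make_library(roster, {"a": [100.0, 150.0, 200.0, 250.0, 300.0]}).libs[0]
        return roster, lib

    def test_perfect_match_is_zero(self):
        roster, lib = self._setup()
        peaks = std_peaklist([100.0, 150.0, 250.0, 300.0], {100.0: 1, 300.0: 5})
        assert msr(lib, Assignment((2, 4)), peaks) == 0.0

    def test_direct_arithmetic(self):
        roster, lib = self._setup()
        # std residuals^2: 1, 4; target residuals^2: 0.25, 0.25, 1
        peaks = std_peaklist(
            [101.0, 150.5, 199.5, 251.0, 298.0], {101.0: 1, 298.0: 5}
        )
        got = msr(lib, Assignment((2, 3, 4)), peaks)
        assert got == pytest.approx(6.5 / 5)

    def test_interferent_excluded_from_residual_and_count(self):
        roster, lib = self._setup()
        peaks = std_peaklist(
            [101.0, 150.5, 199.5, 251.0, 298.0], {101.0: 1, 298.0: 5}
        )
        got = msr(lib, Assignment((2, 3, rtt.INTERFERENT)), peaks)
        assert got == pytest.approx(5.5 / 4)

    def test_vacuous_assignment_rejected(self):
        roster, lib = self._setup()
        peaks = peak_list([120.0])
        with pytest.raises(rtt.RTTError, match="vacuous"):
            msr(lib, Assignment((rtt.INTERFERENT,)), peaks)


def brute_force_best(peaks, library):
    """Exhaustive oracle over all admissible assignment x trajectory pairs.

    Admissibility restated independently: assigned ids increase with
    retention time, and every (unlabeled peak, standard peak) pair is
    ordered consistently — a peak eluting after a standard can only be
    a compound eluting after that standard, and vice versa.
    """
    target_ids = library.roster.target_ids
    n = peaks.n_sample
    unlabeled = peaks.unlabeled_indices
    anchors = [(peaks.peaks[k].rt, sid) for k, sid in peaks.std_labels.items()]

    def legal(combo):
        for i, cid in zip(unlabeled, combo):
            rt = peaks.peaks[i].rt
            for srt, sid in anchors:
                if (srt < rt and sid >= cid) or (srt > rt and sid <= cid):
                    return False
        return True

    best = None
    for combo in itertools.combinations(sorted(target_ids), n):
        if not legal(combo):
            continue
        for lib in library.libs:
            m = msr(lib, Assignment(combo), peaks)
            key = (m, 0, combo, lib.label)
            if best is None or key < best[0]:
                best = (key, Assignment(combo), lib.label, m)
    return best


def random_instance(rng):
    n_tgt = int(rng.integers(2, 9))
    n_std = int(rng.integers(0, 3))
    n_all = n_tgt + n_std
    std_ids = tuple(sorted(rng.choice(np.arange(1, n_all + 1), n_std, replace=False).tolist()))
    roster = make_roster(n_all, std_ids=std_ids)
    n_lib = int(rng.integers(1, 6))
    rows = {}
    base = np.sort(rng.uniform(10, 500, n_all))
    while np.any(np.diff(base) < 1e-3):
        base = np.sort(rng.uniform(10, 500, n_all))
    for i in range(n_lib):
        drift = rng.uniform(-2, 2, n_all)
        row = np.sort(base + drift)
        rows[f"c{i}"] = row.tolist()
    library = make_library(roster, rows)
    n_sample = int(rng.integers(0 if n_std else 1, min(n_tgt, 5) + 1))
    subset = sorted(rng.choice(roster.target_ids, n_sample, replace=False).tolist())
    truth_lib = library.libs[int(rng.integers(0, n_lib))]
    entries = [(truth_lib.rts[cid] + rng.normal(0, 1), cid) for cid in subset]
    entries += [(truth_lib.rts[cid] + rng.normal(0, 1), cid) for cid in std_ids]
    entries.sort()
    rts = np.array([rt for rt, _ in entries])
    if len(rts) and np.any(np.diff(rts) <= 0):
        return None
    if np.any(rts <= 0):
        return None
    std_idset = set(std_ids)
    peaks = PeakList(
        tuple(Peak(float(rt)) for rt in rts),
        {i: cid for i, (_, cid) in enumerate(entries) if cid in std_idset},
    )
    if peaks.n_sample == 0 and not std_ids:
        return None
    return peaks, library


class TestMatchSample:
    def test_self_match_is_rank1_identity_msr_zero(self, family):
        roster, base, library = family
        peaks, truth = rtt.simulate_sample(
            roster, library.libs[2], subset=set(roster.target_ids)
        )
        results = match_sample(peaks, library, MatchConfig(delta_t=30.0))
        assert results[0].rank == 1
        assert results[0].assignment == truth
        assert results[0].msr == pytest.approx(0.0, abs=1e-18)
        assert results[0].lib_label == library.libs[2].label

    def test_oracle_equivalence_small_instances(self):
        rng = np.random.default_rng(123)
        cfg = MatchConfig(delta_t=math.inf, screen_rule=ScreenRule.keep_all())
        checked = 0
        while checked < 60:
            inst = random_instance(rng)
            if inst is None:
                continue
            peaks, library = inst
            results = match_sample(peaks, library, cfg)
            oracle = brute_force_best(peaks, library)
            if oracle is None:
                assert results == []
                continue
            _, bf_assignment, bf_label, bf_msr = oracle
            assert results[0].msr == pytest.approx(bf_msr, rel=1e-12)
            assert results[0].assignment == bf_assignment
            assert results[0].lib_label == bf_label
            checked += 1

    def test_screening_never_changes_retained_scores(self):
        rng = np.random.default_rng(5)
        inst = None
        while inst is None:
            inst = random_instance(rng)
        peaks, library = inst
        cfg_all = MatchConfig(delta_t=math.inf, screen_rule=ScreenRule.keep_all())
        cfg_half = MatchConfig(delta_t=math.inf, screen_rule=ScreenRule.keep_fraction(0.5))
        res_all = {
            (r.assignment, r.lib_label): r.msr for r in match_sample(peaks, library, cfg_all)
        }
        for r in match_sample(peaks, library, cfg_half):
            if (r.assignment, r.lib_label) in res_all:
                assert r.msr == pytest.approx(res_all[(r.assignment, r.lib_label)], rel=1e-12)

    def test_msr_recomputable_from_ssr_and_counts(self, family):
        roster, base, library = family
        rng = np.random.default_rng(9)
        lib = envelope_sample_lib(library, rng)
        subset = sorted(rng.choice(roster.target_ids, 8, replace=False).tolist())
        peaks, _ = rtt.simulate_sample(roster, lib, subset=subset)
        for r in match_sample(peaks, library, MatchConfig(delta_t=20.0)):
            n_pairs = r.n_pairs(peaks)
            assert r.msr == pytest.approx(r.ssr / n_pairs, rel=1e-12)

    def test_library_order_does_not_change_scores(self):
        rng = np.random.default_rng(17)
        inst = None
        while inst is None:
            inst = random_instance(rng)
        peaks, library = inst
        cfg = MatchConfig(delta_t=math.inf, screen_rule=ScreenRule.keep_all())
        res_fwd = match_sample(peaks, library, cfg)
        shuffled = RTTLibrary(library.roster, tuple(reversed(library.libs)))
        res_rev = match_sample(peaks, shuffled, cfg)
        assert [(r.assignment, r.lib_label, r.msr) for r in res_fwd] == [
            (r.assignment, r.lib_label, r.msr) for r in res_rev
        ]

    def test_empty_candidate_stream_returns_empty(self, tiny_library):
        results = match_sample(peak_list([500.0]), tiny_library, MatchConfig(delta_t=2.0))
        assert results == []

    def test_results_sorted_and_ranked(self, family):
        roster, base, library = family
        rng = np.random.default_rng(21)
        lib = envelope_sample_lib(library, rng)
        subset = sorted(rng.choice(roster.target_ids, 6, replace=False).tolist())
        peaks, _ = rtt.simulate_sample(roster, lib, subset=subset)
        results = match_sample(peaks, library, MatchConfig(delta_t=25.0, max_results=5))
        assert [r.rank for r in results] == list(range(1, len(results) + 1))
        msrs = [r.msr for r in results]
        assert msrs == sorted(msrs)
        assert len(results) <= 5
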