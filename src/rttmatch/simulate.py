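"""Synthetic chromatogram families with known ground truth.

Generates a roster with a base trajectory, applies smooth strictly
order-preserving retention-time drifts to emulate run-to-run condition
changes, and produces sample peak lists (arbitrary target subsets,
optional interferents) paired with their true assignments.  All
randomness flows from explicit seeds; identical seeds give identical
outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .core import (
    INTERFERENT,
    Assignment,
    Compound,
    CompoundRoster,
    Peak,
    PeakList,
    RTTLib,
    RTTLibrary,
    ROLE_STANDARD,
    ROLE_TARGET,
    ValidationError,
)
from .peakdetect import Trace

__all__ = [
    "DriftModel",
    "simulate_roster",
    "apply_drift",
    "simulate_library",
    "simulate_sample",
    "gaussian_trace",
]


@dataclass(frozen=True)
class DriftModel:
    """Smooth monotone retention-time perturbation.

    RT' = linear_scale * RT + curvature * RT^2 / span + wobble(RT),
    where the wobble is a seeded combination of three low-frequency
    sinusoids with peak magnitude ``wobble_amplitude`` seconds.  The
    induced map must be strictly increasing over the trajectory's span;
    :func:`apply_drift` rejects models that are not.
    """

    linear_scale: float = 1.0
    curvature: float = 0.0
    wobble_amplitude: float = 0.0
    seed: int = 0

    def wobble(self, rt: np.ndarray, span: float) -> np.ndarray:
        if self.wobble_amplitude == 0.0:
            return np.zeros_like(np.asarray(rt, float))
        rng = np.random.default_rng(self.seed)
        coeffs = rng.uniform(-1.0, 1.0, 3)
        phases = rng.uniform(0.0, 2.0 * math.pi, 3)
        norm = np.sum(np.abs(coeffs)) or 1.0
        rt = np.asarray(rt, float)
        out = np.zeros_like(rt)
        for m, (c, phi) in enumerate(zip(coeffs, phases), start=1):
            out += c * np.sin(m * math.pi * rt / span + phi)
        return self.wobble_amplitude * out / norm

    def warp(self, rt, span: float):
        rt = np.asarray(rt, float)
        out = self.linear_scale * rt + self.curvature * rt**2 / span + self.wobble(rt, span)
        return out

    def to_dict(self) -> dict:
        return {
            "linear_scale": self.linear_scale,
            "curvature": self.curvature,
            "wobble_amplitude": self.wobble_amplitude,
            "seed": self.seed,
        }


IDENTITY = DriftModel()


def simulate_roster(
    n_tgt: int,
    n_std: int,
    span: float,
    min_gap: float,
    seed: int = 0,
) -> tuple[CompoundRoster, RTTLib]:
    """Draw a roster and its base trajectory.

    Retention times are spread over ``(0, span]`` with pairwise spacing
    of at least ``min_gap`` seconds.  The ``n_std`` compounds sitting
    in the lowest-density sections (largest distance to their
    neighbors) become the internal standards.
    """
    n = n_tgt + n_std
    if n_tgt < 1 or n_std < 0:
        raise ValidationError("need n_tgt >= 1 and n_std >= 0")
    if n * min_gap >= span:
        raise ValidationError(
            f"cannot place {n} compounds with min_gap {min_gap} s in a {span} s span"
        )
    rng = np.random.default_rng(seed)
    slack = span - n * min_gap
    u = np.sort(rng.uniform(0.0, slack, n))
    rts = u + min_gap * np.arange(1, n + 1)

    # isolation of each compound: distance to nearest neighbor (chromatogram
    # edges count as neighbors so standards avoid the very ends too)
    padded = np.concatenate([[0.0], rts, [span + min_gap]])
    isolation = np.minimum(np.diff(padded)[:-1], np.diff(padded)[1:])
    std_idx = set(np.argsort(-isolation, kind="stable")[:n_std].tolist())

    compounds = tuple(
        Compound(i + 1, ROLE_STANDARD if i in std_idx else ROLE_TARGET)
        for i in range(n)
    )
    roster = CompoundRoster(compounds)
    base = RTTLib("base", {i + 1: float(rts[i]) for i in range(n)})
    base.validate(roster)
    return roster, base


def apply_drift(lib: RTTLib, model: DriftModel, span: float | None = None) -> RTTLib:
    """Warp a trajectory's retention times through a drift model.

    The warped trajectory must remain strictly increasing and positive
    in the original elution order; otherwise the model is rejected.
    """
    cids = sorted(lib.rts, key=lambda c: lib.rts[c])
    rts = np.array([lib.rts[c] for c in cids])
    span = span if span is not None else float(rts[-1])
    warped = model.warp(rts, span)
    if np.any(warped <= 0) or np.any(np.diff(warped) <= 0):
        raise ValidationError(
            "drift model violates elution order or positivity on this trajectory"
        )
    return replace(lib, rts={c: float(w) for c, w in zip(cids, warped)})


def simulate_library(
    roster: CompoundRoster,
    base: RTTLib,
    models: list[DriftModel],
    labels: list[str] | None = None,
) -> RTTLibrary:
    """Apply each drift model to the base trajectory to build a library."""
    labels = labels or [f"cond_{i+1}" for i in range(len(models))]
    libs = []
    for label, model in zip(labels, models):
        drifted = apply_drift(base, model)
        libs.append(replace(drifted, label=label))
    return RTTLibrary(roster, tuple(libs))


def simulate_sample(
    roster: CompoundRoster,
    lib: RTTLib,
    subset: set[int] | list[int],
    interferent_rts: list[float] = (),
    model: DriftModel = IDENTITY,
    clearance: float = 3.0,
    jitter: float = 0.0,
    seed: int = 0,
) -> tuple[PeakList, Assignment]:
    """Simulate one sample chromatogram and its ground truth.

    The trajectory is drifted through ``model``; the peaks are the
    drifted RTs of the target ``subset`` and of every roster standard,
    plus any interferent peaks.  Interferent RTs must clear every
    drifted target RT by at least ``clearance`` seconds.  ``jitter``
    adds seeded Gaussian measurement noise per apex (order must
    survive it).
    """
    subset = set(subset)
    targets = set(roster.target_ids)
    if not subset <= targets:
        raise ValidationError(f"subset contains non-target ids: {sorted(subset - targets)}")
    drifted = apply_drift(lib, model)
    for irt in interferent_rts:
        nearest = min(abs(drifted.rts[cid] - irt) for cid in roster.target_ids)
        if nearest < clearance:
            raise ValidationError(
                f"interferent at {irt:.6g} s is only {nearest:.3g} s from a drifted "
                f"target RT (clearance {clearance} s)"
            )

    entries: list[tuple[float, int]] = []  # (rt, compound id or INTERFERENT)
    for cid in subset:
        entries.append((drifted.rts[cid], cid))
    std_entries = [(drifted.rts[cid], cid) for cid in roster.standard_ids]
    entries += std_entries
    entries += [(float(irt), INTERFERENT) for irt in interferent_rts]
    entries.sort()

    rts = np.array([rt for rt, _ in entries])
    if jitter > 0:
        rng = np.random.default_rng(seed)
        rts = rts + rng.normal(0.0, jitter, len(rts))
        if np.any(np.diff(rts) <= 0):
            raise ValidationError("jitter broke the elution order; reduce it")

    std_ids = set(roster.standard_ids)
    peaks = tuple(Peak(float(rt)) for rt in rts)
    std_labels = {
        i: cid for i, (_, cid) in enumerate(entries) if cid != INTERFERENT and cid in std_ids
    }
    truth = Assignment(
        tuple(cid for _, cid in entries if cid == INTERFERENT or cid not in std_ids)
    )
    return PeakList(peaks, std_labels), truth


def gaussian_trace(
    rts: list[float],
    heights: list[float],
    width: float = 2.0,
    t_start: float = 0.0,
    t_end: float | None = None,
    dt: float = 0.1,
) -> Trace:
    """Sum-of-Gaussian-bumps trace for exercising apex detection."""
    if t_end is None:
        t_end = max(rts) + 10 * width
    t = np.arange(t_start, t_end + dt / 2, dt)
    y = np.zeros_like(t)
    for rt, h in zip(rts, heights):
        y += h * np.exp(-0.5 * ((t - rt) / width) ** 2)
    return Trace(t, y)
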