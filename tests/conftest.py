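"""Shared fixtures: small hand-built libraries and a seeded 22-compound
drifted family mirroring a realistic GC validation design."""

from __future__ import annotations

import numpy as np
import pytest

import rttmatch as rtt
from rttmatch.core import (
    Compound,
    CompoundRoster,
    Peak,
    PeakList,
    RTTLib,
    RTTLibrary,
)


def make_roster(n: int, std_ids: tuple[int, ...] = ()) -> CompoundRoster:
    return CompoundRoster(
        tuple(
            Compound(i, "standard" if i in std_ids else "target")
            for i in range(1, n + 1)
        )
    )


def make_library(roster: CompoundRoster, rt_rows: dict[str, list[float]]) -> RTTLibrary:
    libs = tuple(
        RTTLib(label, dict(zip(roster.ids, row))) for label, row in rt_rows.items()
    )
    return RTTLibrary(roster, libs)


def peak_list(rts, std_labels=None) -> PeakList:
    return PeakList(tuple(Peak(float(rt)) for rt in rts), std_labels or {})


@pytest.fixture
def tiny_roster() -> CompoundRoster:
    return make_roster(4)


@pytest.fixture
def tiny_library(tiny_roster) -> RTTLibrary:
    return make_library(tiny_roster, {"ref": [10.0, 20.0, 30.0, 40.0]})


def drift_family(seed: int, n_lib: int = 6):
    """Roster of 20 targets + 2 standards, base trajectory over 600 s,
    and a library of ``n_lib`` smoothly drifted conditions."""
    rng = np.random.default_rng(seed)
    roster, base = rtt.simulate_roster(20, 2, span=600.0, min_gap=4.0, seed=seed)
    models = [
        rtt.DriftModel(
            linear_scale=float(1.0 + 0.003 * rng.uniform(-1, 1)),
            curvature=float(0.003 * rng.uniform(-1, 1)),
            wobble_amplitude=float(rng.uniform(0.2, 0.8)),
            seed=int(rng.integers(0, 2**31)),
        )
        for _ in range(n_lib)
    ]
    library = rtt.simulate_library(roster, base, models)
    return roster, base, library


def envelope_sample_lib(library: RTTLibrary, rng: np.random.Generator) -> rtt.RTTLib:
    """A trajectory inside the library's drift envelope: a random convex
    combination of two library trajectories."""
    i, j = rng.choice(library.n_lib, size=2, replace=False)
    lam = float(rng.uniform(0.0, 1.0))
    return rtt.hybridize(
        [library.libs[i], library.libs[j]], [lam, 1.0 - lam], roster=library.roster
    )


@pytest.fixture(scope="session")
def family():
    return drift_family(seed=42)
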