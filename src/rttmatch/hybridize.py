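"""Library expansion by linear hybridization of trajectories.

New trajectories are synthesized as per-compound linear combinations
of experimentally measured ones, extending the library's drift
envelope without extra measurements.  The three stock two-parent
formulas are the midpoint (a+b)/2 and the two extrapolations 2a-b and
2b-a; coefficients always sum to 1 so the RT scale is preserved.
"""

from __future__ import annotations

import itertools
import logging
from typing import Mapping, Sequence

from .core import (
    Provenance,
    RTTLib,
    RTTLibrary,
    ValidationError,
)

__all__ = ["FORMULAS", "hybridize", "expand_library"]

log = logging.getLogger(__name__)

#: Named two-parent hybridization formulas (coefficients on (a, b)).
FORMULAS: Mapping[str, tuple[float, float]] = {
    "mid": (0.5, 0.5),
    "extrap_ab": (2.0, -1.0),
    "extrap_ba": (-1.0, 2.0),
}

#: Two hybrids closer than this per-compound (seconds) are duplicates.
DEDUP_TOL = 0.05


def hybridize(
    parents: Sequence[RTTLib],
    coeffs: Sequence[float],
    roster=None,
    label: str | None = None,
    allow_non_affine: bool = False,
) -> RTTLib:
    """Linear-combine 2 or 3 parent trajectories into a new one.

    Coefficients must sum to 1 (override with ``allow_non_affine``).
    The hybrid is validated for positivity and strict elution-order
    preservation when a roster is given; an invalid combination is
    rejected with a diagnostic naming the first offending compounds.
    """
    if len(parents) not in (2, 3):
        raise ValidationError("hybridization takes 2 or 3 parent trajectories")
    if len(coeffs) != len(parents):
        raise ValidationError("need exactly one coefficient per parent")
    if not allow_non_affine and abs(sum(coeffs) - 1.0) > 1e-9:
        raise ValidationError(
            f"hybridization coefficients must sum to 1, got {sum(coeffs)}"
        )
    keys = set(parents[0].rts)
    for p in parents[1:]:
        if set(p.rts) != keys:
            raise ValidationError(
                f"parents {parents[0].label!r} and {p.label!r} cover different compounds"
            )
    rts = {
        cid: sum(c * p.rts[cid] for c, p in zip(coeffs, parents)) for cid in keys
    }
    if label is None:
        terms = "+".join(f"{c:g}*{p.label}" for c, p in zip(coeffs, parents))
        label = f"hyb({terms})"
    hybrid = RTTLib(
        label,
        rts,
        Provenance(
            "hybridized",
            tuple(p.label for p in parents),
            tuple(float(c) for c in coeffs),
        ),
    )
    if roster is not None:
        hybrid.validate(roster)
    return hybrid


def _is_duplicate(a: RTTLib, b: RTTLib) -> bool:
    return max(abs(a.rts[c] - b.rts[c]) for c in a.rts) < DEDUP_TOL


def expand_library(
    library: RTTLibrary,
    formulas: Sequence[str | Sequence[float]] = ("mid", "extrap_ab", "extrap_ba"),
) -> RTTLibrary:
    """Append two-parent hybrids of every unordered experimental pair.

    Each formula is a name from :data:`FORMULAS` or a raw coefficient
    pair.  Hybrids violating elution order or positivity are skipped
    (and counted in the log); hybrids within :data:`DEDUP_TOL` of an
    existing trajectory are dropped.  Hybrids never serve as parents,
    so re-running the expansion adds nothing new.
    """
    parents = library.experimental
    if len(parents) < 2:
        raise ValidationError("library needs at least 2 experimental trajectories to expand")
    coeff_list: list[tuple[float, float]] = []
    for f in formulas:
        if isinstance(f, str):
            if f not in FORMULAS:
                raise ValidationError(f"unknown formula {f!r}; known: {sorted(FORMULAS)}")
            coeff_list.append(FORMULAS[f])
        else:
            if len(f) != 2:
                raise ValidationError("raw formula must have exactly 2 coefficients")
            coeff_list.append((float(f[0]), float(f[1])))

    existing = list(library.libs)
    added: list[RTTLib] = []
    n_invalid = 0
    n_dup = 0
    for a, b in itertools.combinations(parents, 2):
        for coeffs in coeff_list:
            try:
                hyb = hybridize([a, b], coeffs, roster=library.roster)
            except ValidationError:
                n_invalid += 1
                continue
            if any(_is_duplicate(hyb, other) for other in existing + added):
                n_dup += 1
                continue
            added.append(hyb)
    log.info(
        "hybridization: %d added, %d invalid skipped, %d duplicates dropped",
        len(added),
        n_invalid,
        n_dup,
    )
    return RTTLibrary(library.roster, tuple(existing + added))
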