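"""Domain types, validation and text-format I/O.

The central objects are:

* :class:`CompoundRoster` — the ordered list of target compounds and
  internal standards, in elution order of the reference chromatogram.
* :class:`RTTLib` — one library trajectory: a retention time per roster
  compound, characterizing one chromatographic condition (experimental
  or hybridized from experimental parents).
* :class:`PeakList` — the detected peak apex times of a sample
  chromatogram, with internal-standard peaks labeled.
* :class:`Assignment` — an injective, order-preserving mapping of the
  sample's unlabeled peaks onto target compounds, where a peak may also
  be flagged as an interferent.

Peak lists are comma-separated text with a header
(``rt_seconds[,height][,standard_id]``); libraries are YAML documents
with a roster block and one block per condition.  Both formats
round-trip exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "INTERFERENT",
    "RTTError",
    "ValidationError",
    "Compound",
    "CompoundRoster",
    "Provenance",
    "EXPERIMENTAL",
    "RTTLib",
    "RTTLibrary",
    "Peak",
    "PeakList",
    "Assignment",
    "MatchResult",
    "ScreenRule",
    "MatchConfig",
    "validate_assignment",
    "read_peak_list",
    "write_peak_list",
    "read_library",
    "write_library",
    "read_roster",
    "write_roster",
    "label_standards",
]

#: Sentinel compound id marking a peak as an interferent (not a target).
INTERFERENT: int = -1

#: Retention times are compared at this absolute tolerance (seconds).
RT_TOL = 1e-9


class RTTError(ValueError):
    """Base class for all package errors."""


class ValidationError(RTTError):
    """An input object violates a structural invariant."""


# ---------------------------------------------------------------------------
# Roster
# ---------------------------------------------------------------------------

ROLE_TARGET = "target"
ROLE_STANDARD = "standard"


@dataclass(frozen=True)
class Compound:
    """One roster member.

    Parameters
    ----------
    id
        1-based elution-order rank in the reference chromatogram,
        unique across the whole roster (targets and standards share one
        id space, so id comparisons encode elution order).
    role
        ``"target"`` or ``"standard"``.
    name
        Optional human-readable name.
    """

    id: int
    role: str
    name: str | None = None

    def __post_init__(self) -> None:
        if self.role not in (ROLE_TARGET, ROLE_STANDARD):
            raise ValidationError(f"unknown compound role {self.role!r}")
        if not isinstance(self.id, int) or self.id < 1:
            raise ValidationError(f"compound id must be a positive integer, got {self.id!r}")


@dataclass(frozen=True)
class CompoundRoster:
    """Ordered roster of targets and internal standards.

    Compounds are listed in elution order of the reference
    chromatogram; ids must be strictly increasing along the sequence.
    """

    compounds: tuple[Compound, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "compounds", tuple(self.compounds))
        ids = [c.id for c in self.compounds]
        if len(set(ids)) != len(ids):
            raise ValidationError("compound ids must be unique")
        if any(b <= a for a, b in zip(ids, ids[1:])):
            raise ValidationError("compound ids must increase along elution order")
        if self.n_tgt < 1:
            raise ValidationError("roster needs at least one target compound")

    @property
    def n_tgt(self) -> int:
        return sum(1 for c in self.compounds if c.role == ROLE_TARGET)

    @property
    def n_std(self) -> int:
        return sum(1 for c in self.compounds if c.role == ROLE_STANDARD)

    @property
    def target_ids(self) -> tuple[int, ...]:
        return tuple(c.id for c in self.compounds if c.role == ROLE_TARGET)

    @property
    def standard_ids(self) -> tuple[int, ...]:
        return tuple(c.id for c in self.compounds if c.role == ROLE_STANDARD)

    @property
    def ids(self) -> tuple[int, ...]:
        return tuple(c.id for c in self.compounds)

    def __getitem__(self, cid: int) -> Compound:
        for c in self.compounds:
            if c.id == cid:
                return c
        raise KeyError(cid)

    def __contains__(self, cid: int) -> bool:
        return any(c.id == cid for c in self.compounds)


# ---------------------------------------------------------------------------
# Library trajectories
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Provenance:
    """Where a trajectory came from.

    ``kind`` is ``"experimental"`` or ``"hybridized"``; hybridized
    trajectories record their parent labels and linear coefficients.
    """

    kind: str
    parents: tuple[str, ...] = ()
    coefficients: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("experimental", "hybridized"):
            raise ValidationError(f"unknown provenance kind {self.kind!r}")
        if self.kind == "hybridized" and len(self.parents) != len(self.coefficients):
            raise ValidationError("hybridized provenance needs one coefficient per parent")
        object.__setattr__(self, "parents", tuple(self.parents))
        object.__setattr__(self, "coefficients", tuple(float(c) for c in self.coefficients))


EXPERIMENTAL = Provenance("experimental")


@dataclass(frozen=True)
class RTTLib:
    """One library trajectory: compound id -> retention time (seconds)."""

    label: str
    rts: Mapping[int, float]
    provenance: Provenance = EXPERIMENTAL

    def __post_init__(self) -> None:
        object.__setattr__(self, "rts", dict(self.rts))

    def validate(self, roster: CompoundRoster) -> None:
        """Check coverage, positivity and strict elution-order preservation."""
        missing = [cid for cid in roster.ids if cid not in self.rts]
        if missing:
            raise ValidationError(
                f"trajectory {self.label!r} is missing compound(s) {missing}"
            )
        extra = [cid for cid in self.rts if cid not in roster.ids]
        if extra:
            raise ValidationError(
                f"trajectory {self.label!r} has retention times for unknown compound(s) {extra}"
            )
        prev_id: int | None = None
        for cid in roster.ids:
            rt = self.rts[cid]
            if not (rt > 0):
                raise ValidationError(
                    f"trajectory {self.label!r}: compound {cid} has nonpositive RT {rt}"
                )
            if prev_id is not None and self.rts[prev_id] >= rt - RT_TOL:
                raise ValidationError(
                    f"trajectory {self.label!r}: elution order violated between "
                    f"compounds {prev_id} and {cid} "
                    f"({self.rts[prev_id]:.6g} s >= {rt:.6g} s)"
                )
            prev_id = cid

    def rt(self, cid: int) -> float:
        return self.rts[cid]


@dataclass(frozen=True)
class RTTLibrary:
    """A roster plus one or more trajectories sharing it."""

    roster: CompoundRoster
    libs: tuple[RTTLib, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "libs", tuple(self.libs))
        if not self.libs:
            raise ValidationError("library must contain at least one trajectory")
        labels = [lib.label for lib in self.libs]
        if len(set(labels)) != len(labels):
            raise ValidationError("trajectory labels must be unique")
        for lib in self.libs:
            lib.validate(self.roster)

    @property
    def n_lib(self) -> int:
        return len(self.libs)

    @property
    def experimental(self) -> tuple[RTTLib, ...]:
        return tuple(lib for lib in self.libs if lib.provenance.kind == "experimental")

    def __getitem__(self, label: str) -> RTTLib:
        for lib in self.libs:
            if lib.label == label:
                return lib
        raise KeyError(label)


# ---------------------------------------------------------------------------
# Sample peak lists
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Peak:
    rt: float
    height: float | None = None

    def __post_init__(self) -> None:
        if not (self.rt > 0):
            raise ValidationError(f"peak retention time must be positive, got {self.rt}")
        if self.height is not None and self.height < 0:
            raise ValidationError(f"peak height must be nonnegative, got {self.height}")


@dataclass(frozen=True)
class PeakList:
    """Detected apex retention times of one sample chromatogram.

    ``std_labels`` maps a peak index (into ``peaks``) to the internal
    standard compound id it was recognized as; all other peaks are the
    ``n_sample`` unlabeled peaks awaiting identification.
    """

    peaks: tuple[Peak, ...]
    std_labels: Mapping[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks", tuple(self.peaks))
        object.__setattr__(self, "std_labels", dict(self.std_labels))
        rts = [p.rt for p in self.peaks]
        for a, b in zip(rts, rts[1:]):
            if b <= a + RT_TOL:
                raise ValidationError(
                    f"peak retention times must be strictly increasing "
                    f"({a:.6g} s followed by {b:.6g} s); collapse duplicate apexes upstream"
                )
        labels = list(self.std_labels.values())
        if len(set(labels)) != len(labels):
            raise ValidationError("two peaks are labeled with the same internal standard")
        for idx in self.std_labels:
            if not 0 <= idx < len(self.peaks):
                raise ValidationError(f"standard label refers to missing peak index {idx}")

    @property
    def n_sample(self) -> int:
        """Count of unlabeled (to-be-identified) peaks."""
        return len(self.peaks) - len(self.std_labels)

    @property
    def unlabeled_indices(self) -> tuple[int, ...]:
        return tuple(i for i in range(len(self.peaks)) if i not in self.std_labels)

    @property
    def unlabeled_rts(self) -> tuple[float, ...]:
        return tuple(self.peaks[i].rt for i in self.unlabeled_indices)

    @property
    def standard_rts(self) -> dict[int, float]:
        """Map standard compound id -> sample retention time."""
        return {cid: self.peaks[i].rt for i, cid in self.std_labels.items()}

    def validate(self, roster: CompoundRoster) -> None:
        std_ids = set(roster.standard_ids)
        for idx, cid in self.std_labels.items():
            if cid not in std_ids:
                raise ValidationError(
                    f"peak {idx} is labeled with id {cid}, which is not a roster standard"
                )


# ---------------------------------------------------------------------------
# Assignments and match results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Assignment:
    """Mapping of unlabeled sample peaks to target compound ids.

    ``mapping[j]`` is the compound id assigned to the j-th unlabeled
    peak (in retention-time order), or :data:`INTERFERENT`.
    """

    mapping: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "mapping", tuple(self.mapping))

    @property
    def n_interf(self) -> int:
        return sum(1 for cid in self.mapping if cid == INTERFERENT)

    @property
    def assigned_ids(self) -> tuple[int, ...]:
        return tuple(cid for cid in self.mapping if cid != INTERFERENT)

    def sort_key(self) -> tuple[int, ...]:
        # interferents sort after any real compound id
        big = 1 << 30
        return tuple(big if cid == INTERFERENT else cid for cid in self.mapping)


def validate_assignment(assignment: Assignment, roster: CompoundRoster | None = None) -> None:
    """Raise unless the assignment is injective and order-preserving.

    Rule 1: one target compound maps to at most one peak (injectivity).
    Rule 2: assigned compound ids strictly increase with peak retention
    time (elution-order preservation).  Interferent labels are exempt
    from both.
    """
    ids = assignment.assigned_ids
    if len(set(ids)) != len(ids):
        raise ValidationError(f"assignment maps one compound to two peaks: {ids}")
    if any(b <= a for a, b in zip(ids, ids[1:])):
        raise ValidationError(f"assignment violates elution order: {ids}")
    if roster is not None:
        targets = set(roster.target_ids)
        for cid in ids:
            if cid not in targets:
                raise ValidationError(f"assigned id {cid} is not a roster target")


@dataclass(frozen=True)
class MatchResult:
    """One scored identification hypothesis.

    ``ssr`` is the total sum of squared residuals (standards plus
    non-interferent target pairs, seconds squared); ``msr`` is ``ssr``
    divided by the number of contributing pairs.
    """

    assignment: Assignment
    lib_label: str
    ssr: float
    msr: float
    rank: int = 0
    notes: tuple[str, ...] = ()

    def n_pairs(self, peaks: PeakList) -> int:
        return len(peaks.std_labels) + peaks.n_sample - self.assignment.n_interf


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreenRule:
    """How many trajectories survive internal-standard screening.

    kind ``"all"`` keeps every trajectory, ``"fraction"`` keeps the
    smallest-SSR fraction ``value`` (rounded up), ``"top"`` keeps the
    ``value`` best.  ``floor`` raises the retained count to
    ``min(n_lib, floor)``.
    """

    kind: str = "fraction"
    value: float = 0.5
    floor: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("all", "fraction", "top"):
            raise ValidationError(f"unknown screen rule {self.kind!r}")
        if self.kind == "fraction" and not (0 < self.value <= 1):
            raise ValidationError("screen fraction must be in (0, 1]")
        if self.kind == "top" and (int(self.value) != self.value or self.value < 1):
            raise ValidationError("screen top-k must be a positive integer")

    def n_keep(self, n_lib: int) -> int:
        if self.kind == "all":
            n = n_lib
        elif self.kind == "fraction":
            n = math.ceil(self.value * n_lib)
        else:
            n = int(self.value)
        return min(n_lib, max(n, min(n_lib, self.floor)))

    @classmethod
    def keep_all(cls) -> "ScreenRule":
        return cls("all", 1.0)

    @classmethod
    def keep_fraction(cls, f: float, floor: int = 0) -> "ScreenRule":
        return cls("fraction", f, floor)

    @classmethod
    def keep_top(cls, k: int, floor: int = 0) -> "ScreenRule":
        return cls("top", k, floor)


@dataclass(frozen=True)
class MatchConfig:
    """Tunables of the matching pipeline.

    delta_t
        RT cutoff window (seconds): a peak may only be paired with a
        compound whose library RT lies within ``peak_rt ± delta_t``.
    screen_rule
        Library screening rule (default: keep the best half by
        standards-SSR, with a floor of 20 trajectories).
    interferent_factor
        A peak whose squared residual exceeds this factor times the
        current MSR is relabeled interferent during refinement.
    interferent_gate_frac
        A peak may carry an interferent hypothesis during candidate
        enumeration only if its distance to the nearest library RT
        exceeds this fraction of ``delta_t`` (residual-based refinement
        catches closer interferents afterwards).
    """

    delta_t: float = 30.0
    screen_rule: ScreenRule = field(default_factory=lambda: ScreenRule.keep_fraction(0.5, floor=20))
    interferent_factor: float = 2.0
    interferent_gate_frac: float = 0.1
    allow_interferents: bool = False
    max_results: int = 10

    def __post_init__(self) -> None:
        if not (self.delta_t > 0):
            raise ValidationError("delta_t must be positive")
        if not (self.interferent_factor > 1):
            raise ValidationError("interferent_factor must exceed 1")
        if not (0 <= self.interferent_gate_frac <= 1):
            raise ValidationError("interferent_gate_frac must be in [0, 1]")
        if self.max_results < 1:
            raise ValidationError("max_results must be positive")

    def to_dict(self) -> dict:
        return {
            "delta_t": self.delta_t,
            "screen": {
                "rule": self.screen_rule.kind,
                "value": self.screen_rule.value,
                "floor": self.screen_rule.floor,
            },
            "interferent_factor": self.interferent_factor,
            "interferent_gate_frac": self.interferent_gate_frac,
            "allow_interferents": self.allow_interferents,
            "max_results": self.max_results,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MatchConfig":
        kwargs: dict = {}
        d = dict(d)
        if "screen" in d:
            s = d.pop("screen")
            kwargs["screen_rule"] = ScreenRule(
                s.get("rule", "fraction"), s.get("value", 0.5), s.get("floor", 0)
            )
        for key in (
            "delta_t",
            "interferent_factor",
            "interferent_gate_frac",
            "allow_interferents",
            "max_results",
        ):
            if key in d:
                kwargs[key] = d.pop(key)
        if d:
            raise ValidationError(f"unknown config key(s): {sorted(d)}")
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Peak-list I/O
# ---------------------------------------------------------------------------


def read_peak_list(path: str | Path, roster: CompoundRoster) -> PeakList:
    """Read a delimited peak list and resolve standard labels.

    The file must have a header with at least ``rt_seconds``;
    ``height`` and ``standard_id`` columns are optional and may be
    blank row-wise.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if "rt_seconds" not in df.columns:
        raise ValidationError(f"{path}: missing required column 'rt_seconds'")
    rts = df["rt_seconds"].astype(float)
    if rts.isna().any():
        raise ValidationError(f"{path}: unparseable retention time")
    if (rts <= 0).any():
        bad = float(rts[rts <= 0].iloc[0])
        raise ValidationError(f"{path}: retention times must be positive (found {bad})")
    order = rts.sort_values(kind="stable").index
    df = df.loc[order].reset_index(drop=True)

    peaks = []
    for _, row in df.iterrows():
        h = row.get("height")
        height = None if h is None or pd.isna(h) else float(h)
        peaks.append(Peak(float(row["rt_seconds"]), height))

    std_labels: dict[int, int] = {}
    if "standard_id" in df.columns:
        for i, v in enumerate(df["standard_id"]):
            if pd.isna(v) or v == "":
                continue
            cid = int(v)
            if cid not in set(roster.standard_ids):
                raise ValidationError(
                    f"{path}: row {i} labels a peak with standard id {cid}, "
                    f"which is not a roster standard"
                )
            std_labels[i] = cid

    pl = PeakList(tuple(peaks), std_labels)
    pl.validate(roster)
    return pl


def write_peak_list(peaks: PeakList, path: str | Path) -> None:
    path = Path(path)
    rows = []
    for i, p in enumerate(peaks.peaks):
        rows.append(
            {
                "rt_seconds": p.rt,
                "height": "" if p.height is None else p.height,
                "standard_id": peaks.std_labels.get(i, ""),
            }
        )
    pd.DataFrame(rows, columns=["rt_seconds", "height", "standard_id"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# Library I/O (YAML)
# ---------------------------------------------------------------------------


def _roster_to_obj(roster: CompoundRoster) -> list:
    out = []
    for c in roster.compounds:
        d: dict = {"id": c.id, "role": c.role}
        if c.name is not None:
            d["name"] = c.name
        out.append(d)
    return out


def _roster_from_obj(obj: Iterable[Mapping]) -> CompoundRoster:
    comps = []
    for d in obj:
        comps.append(Compound(int(d["id"]), str(d["role"]), d.get("name")))
    return CompoundRoster(tuple(comps))


def _provenance_to_obj(p: Provenance):
    if p.kind == "experimental":
        return "experimental"
    return {
        "kind": "hybridized",
        "parents": list(p.parents),
        "coefficients": [float(c) for c in p.coefficients],
    }


def _provenance_from_obj(obj) -> Provenance:
    if obj is None or obj == "experimental":
        return EXPERIMENTAL
    return Provenance(
        obj["kind"], tuple(obj.get("parents", ())), tuple(obj.get("coefficients", ()))
    )


def write_roster(roster: CompoundRoster, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump({"roster": _roster_to_obj(roster)}, sort_keys=False)
    )


def read_roster(path: str | Path) -> CompoundRoster:
    doc = yaml.safe_load(Path(path).read_text())
    return _roster_from_obj(doc["roster"])


def write_library(library: RTTLibrary, path: str | Path) -> None:
    """Serialize a library to YAML; inverse of :func:`read_library`."""
    doc = {
        "roster": _roster_to_obj(library.roster),
        "libs": [
            {
                "label": lib.label,
                "provenance": _provenance_to_obj(lib.provenance),
                "rts": {int(cid): float(lib.rts[cid]) for cid in library.roster.ids},
            }
            for lib in library.libs
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_library(path: str | Path) -> RTTLibrary:
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    if not doc or "roster" not in doc or "libs" not in doc:
        raise ValidationError(f"{path}: not a library file (needs 'roster' and 'libs')")
    roster = _roster_from_obj(doc["roster"])
    libs = []
    for entry in doc["libs"]:
        libs.append(
            RTTLib(
                str(entry["label"]),
                {int(k): float(v) for k, v in entry["rts"].items()},
                _provenance_from_obj(entry.get("provenance")),
            )
        )
    try:
        return RTTLibrary(roster, tuple(libs))
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Standard auto-labeling fallback
# ---------------------------------------------------------------------------


def label_standards(peaks: PeakList, library: RTTLibrary, delta_t: float) -> PeakList:
    """Assign each roster standard to the nearest peak within ``delta_t``.

    Fallback for inputs whose preprocessing did not label standard
    peaks.  The library-side reference RT of a standard is its mean RT
    over trajectories.  Ambiguity (a peak claimed by two standards, or
    a standard with no peak in range) is an error.
    """
    if peaks.std_labels:
        return peaks
    claimed: dict[int, int] = {}
    for cid in library.roster.standard_ids:
        ref = sum(lib.rts[cid] for lib in library.libs) / library.n_lib
        dists = [(abs(p.rt - ref), i) for i, p in enumerate(peaks.peaks)]
        dist, idx = min(dists)
        if dist > delta_t:
            raise ValidationError(
                f"no peak within {delta_t} s of standard {cid} (nearest is {dist:.3g} s away)"
            )
        if idx in claimed:
            raise ValidationError(
                f"peak at {peaks.peaks[idx].rt:.6g} s claimed by standards "
                f"{claimed[idx]} and {cid}; label standards explicitly"
            )
        claimed[idx] = cid
    return replace(peaks, std_labels=claimed)
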