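"""Peak apex extraction from raw chromatogram traces.

Only local maxima (apex positions) are extracted; no baseline removal,
deconvolution or sub-sample interpolation is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .core import Peak, PeakList, ValidationError

__all__ = ["Trace", "read_trace", "detect_peaks"]


@dataclass(frozen=True)
class Trace:
    """A time/intensity series; spacing may be non-uniform."""

    t: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "y", y)
        if t.ndim != 1 or t.shape != y.shape:
            raise ValidationError("trace needs matching 1-D time and intensity arrays")
        if len(t) < 3:
            raise ValidationError("trace must have at least 3 samples")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("trace times must be strictly increasing")


def read_trace(path: str | Path) -> Trace:
    """Read a two-column delimited trace file (t_seconds, intensity)."""
    df = pd.read_csv(path)
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValidationError(f"{path}: trace file needs two columns (time, intensity)")
    return Trace(df[cols[0]].to_numpy(float), df[cols[1]].to_numpy(float))


def detect_peaks(
    trace: Trace, min_prominence: float = 0.0, min_separation: float = 0.0
) -> PeakList:
    """Scan for local maxima and return their apex retention times.

    Prominence is the apex height above the higher of the two flanking
    minima (scipy's definition).  Maxima closer than ``min_separation``
    seconds to a taller retained maximum are suppressed.  For a flat
    (plateau) maximum the leftmost sample is the apex.

    Returned apex times are a subset of the trace's sample times.
    """
    if min_prominence < 0 or min_separation < 0:
        raise ValidationError("min_prominence and min_separation must be nonnegative")
    # plateau_size=(1, None) makes scipy report plateau edges; use the left one.
    idx, props = find_peaks(trace.y, prominence=(None, None), plateau_size=(1, None))
    apex = props["left_edges"]
    keep = props["prominences"] >= min_prominence
    apex = apex[keep]
    heights = trace.y[apex]

    if min_separation > 0 and len(apex) > 1:
        # greedy suppression: taller apexes win; ties broken by earlier time
        order = np.lexsort((trace.t[apex], -heights))
        kept: list[int] = []
        for i in order:
            ti = trace.t[apex[i]]
            if all(abs(ti - trace.t[apex[j]]) >= min_separation for j in kept):
                kept.append(i)
        apex = np.sort(apex[kept])
        heights = trace.y[apex]

    peaks = tuple(Peak(float(trace.t[i]), float(trace.y[i])) for i in apex)
    return PeakList(peaks, {})
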