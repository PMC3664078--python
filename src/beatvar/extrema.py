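"""Local-extrema analysis of beat-to-beat haemodynamic parameters.

The model treats a beat-indexed parameter (MAP, SBP, TPR, ...) as a
discrete sequence that oscillates between local peaks and troughs. A
point qualifies as a local maximum when it is strictly larger than both
neighbours, and a local minimum when strictly smaller than both; the
endpoints, having one neighbour, never qualify, and ties (plateaus)
yield no extremum. From consecutive extrema the analysis derives

* the inter-extrema interval ``t[i] = time[i+1] - time[i]`` in seconds,
  using the actual beat timestamps (beat spacing is irregular);
* the extrema frequency ``F = 1 / t`` in true Hz;
* the extrema amplitude ``a[i] = |value[i+1] - value[i]|`` in the
  parameter's units.

Intervals are taken between *all* consecutive extrema regardless of kind
(peak-to-trough and trough-to-peak alike), so for a clean sinusoid of
frequency ``f`` and amplitude ``A`` the extrema frequency is ``2f`` and
the extrema amplitude ``2A``.

Neighbour comparisons use exact floating-point inequality: no epsilon is
applied, so quantised signals may under-detect at plateaus. This is a
deliberate, documented convention rather than a tolerance choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .beat_io import PARAMETERS, BeatSeries

__all__ = [
    "ExtremumPoint",
    "ExtremaMetrics",
    "find_extrema",
    "inter_extrema_intervals",
    "extrema_frequencies",
    "extrema_amplitudes",
    "analyze_parameter",
    "flow_variation",
]

MAXIMUM = "maximum"
MINIMUM = "minimum"


@dataclass(frozen=True)
class ExtremumPoint:
    """A detected local maximum or minimum of a parameter sequence."""

    index: int    # 0-based position in the sequence (1 <= index <= n-2)
    time: float   # beat time at that index, seconds
    value: float  # parameter value at that index
    kind: str     # "maximum" or "minimum"


@dataclass(frozen=True)
class ExtremaMetrics:
    """Extrema of one parameter plus the per-transition metrics.

    ``intervals``, ``frequencies`` and ``amplitudes`` each have one entry
    per consecutive extrema pair (``len(extrema) - 1`` entries, empty
    when fewer than two extrema were found).
    """

    parameter: str
    extrema: tuple[ExtremumPoint, ...]
    intervals: np.ndarray = field(compare=False)    # seconds
    frequencies: np.ndarray = field(compare=False)  # Hz
    amplitudes: np.ndarray = field(compare=False)   # parameter units

    @property
    def n_extrema(self) -> int:
        return len(self.extrema)

    def to_frame(self) -> pd.DataFrame:
        """Per-pair metrics as a table (one row per consecutive pair)."""
        e = self.extrema
        return pd.DataFrame(
            {
                "parameter": self.parameter,
                "pair_index": np.arange(max(len(e) - 1, 0)),
                "t_start_s": [p.time for p in e[:-1]],
                "t_end_s": [p.time for p in e[1:]],
                "interval_s": self.intervals,
                "frequency_hz": self.frequencies,
                "amplitude": self.amplitudes,
            }
        )


def find_extrema(
    values: Sequence[float] | np.ndarray,
    times: Sequence[float] | np.ndarray,
    atol: float = 0.0,
) -> list[ExtremumPoint]:
    """Detect every strict local maximum and minimum of a sequence.

    An interior point is a maximum iff it strictly exceeds both
    neighbours and a minimum iff it is strictly below both; by default
    comparisons are exact (no tolerance), so equal neighbours never
    form an extremum.

    Parameters
    ----------
    values
        Parameter values, one per beat.
    times
        Strictly increasing beat times (seconds), same length.
    atol
        Optional absolute margin a point must clear over both
        neighbours to count as an extremum (0 = exact strict
        comparison, the default; useful for quantised signals where
        exact ties under-detect in one direction and measurement noise
        over-detects in the other).

    Returns
    -------
    list of ExtremumPoint in index order.

    Raises
    ------
    ValueError
        If lengths differ or times are not strictly increasing.

    Warns and returns an empty list when fewer than 3 points are given
    (no interior point exists).
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    if v.shape != t.shape or v.ndim != 1:
        raise ValueError("values and times must be 1-d sequences of equal length")
    if len(v) < 3:
        warnings.warn(
            "fewer than 3 points: no interior point can be an extremum",
            stacklevel=2,
        )
        return []
    if not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")

    if atol < 0:
        raise ValueError("atol must be non-negative")
    left, mid, right = v[:-2], v[1:-1], v[2:]
    is_max = (mid > left + atol) & (mid > right + atol)
    is_min = (mid < left - atol) & (mid < right - atol)
    idx = np.nonzero(is_max | is_min)[0] + 1
    return [
        ExtremumPoint(
            index=int(i),
            time=float(t[i]),
            value=float(v[i]),
            kind=MAXIMUM if is_max[i - 1] else MINIMUM,
        )
        for i in idx
    ]


def inter_extrema_intervals(extrema: Sequence[ExtremumPoint]) -> np.ndarray:
    """Elapsed time (s) between each consecutive pair of extrema.

    Fewer than two extrema yield an empty array (not an error).
    """
    times = np.array([e.time for e in extrema], dtype=float)
    if len(times) < 2:
        return np.empty(0)
    out = np.diff(times)
    if np.any(out <= 0):
        bad = int(np.nonzero(out <= 0)[0][0])
        raise ValueError(f"non-positive interval between extrema {bad} and {bad + 1}")
    return out


def extrema_frequencies(intervals: Sequence[float] | np.ndarray) -> np.ndarray:
    """Frequency of change between extrema: element-wise ``F = 1/t`` (Hz)."""
    t = np.asarray(intervals, dtype=float)
    if np.any(t <= 0):
        bad = int(np.nonzero(t <= 0)[0][0])
        raise ValueError(
            f"interval {bad} is not positive; duplicate beat times upstream?"
        )
    return 1.0 / t


def extrema_amplitudes(extrema: Sequence[ExtremumPoint]) -> np.ndarray:
    """Absolute value change between each consecutive pair of extrema.

    The signed peak-to-trough difference is recoverable from the extrema
    kinds; summaries conventionally use the magnitude.
    """
    values = np.array([e.value for e in extrema], dtype=float)
    if len(values) < 2:
        return np.empty(0)
    return np.abs(np.diff(values))


def analyze_parameter(series: BeatSeries, parameter: str) -> ExtremaMetrics:
    """Full extrema analysis of one parameter of a recording.

    Composes extrema detection with the interval, frequency and
    amplitude calculations into one :class:`ExtremaMetrics`.

    Raises
    ------
    ValueError
        Unknown parameter name (valid names are listed), or a parameter
        column with no data in this recording.
    """
    name = parameter.upper()
    if name not in PARAMETERS:
        raise ValueError(
            f"unknown parameter {parameter!r}; valid names: "
            f"{', '.join(sorted(PARAMETERS))}"
        )
    values = series.values(name)
    if len(values) and np.all(np.isnan(values)):
        raise ValueError(
            f"parameter {name} has no data in this recording "
            "(column absent and not derivable)"
        )
    if len(values) < 3:
        extrema: list[ExtremumPoint] = []
    else:
        extrema = find_extrema(values, series.times)
    intervals = inter_extrema_intervals(extrema)
    return ExtremaMetrics(
        parameter=name,
        extrema=tuple(extrema),
        intervals=intervals,
        frequencies=extrema_frequencies(intervals),
        amplitudes=extrema_amplitudes(extrema),
    )


def flow_variation(delta_p: float, resistance: float) -> float:
    """Blood flow from the haemodynamic form of Ohm's law, ``Q = ΔP / R``.

    ``delta_p`` is the arterio-venous pressure gradient (mmHg); venous
    pressure is treated as a constant 0, so the MAP itself can stand in
    for the gradient. A large pressure variation over a small resistance
    variation therefore implies a large flow variation.

    Raises
    ------
    ValueError
        If ``resistance`` is not positive.
    """
    if resistance <= 0:
        raise ValueError("resistance must be positive")
    return delta_p / resistance


def metrics_to_csv(metrics: ExtremaMetrics, path: str | Path) -> None:
    """Write per-pair metrics (interval, frequency, amplitude) as CSV."""
    metrics.to_frame().to_csv(path, index=False)
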