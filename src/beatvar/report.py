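"""Analysis and comparison reports over whole recordings.

An analysis report summarises, per haemodynamic parameter, the
distribution of extrema frequencies and amplitudes of one recording. A
comparison report puts two recordings side by side in the layout
clinical papers use: one row for frequency and one for amplitude, one
column group per parameter, each cell a "median (q1-q3)" with the
between-group P value. Display values are rounded to 3 significant
figures; full-precision numbers are always available in the long-format
table (``comparison_long``) and per-pair CSVs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .beat_io import BeatSeries
from .extrema import analyze_parameter
from .stats import ComparisonResult, GroupSummary, compare_groups, summarize

__all__ = [
    "DEFAULT_PARAMETERS",
    "ParameterSummary",
    "AnalysisReport",
    "analyze_series",
    "compare_series",
    "comparison_table",
    "comparison_long",
]

logger = logging.getLogger(__name__)

#: Parameters reported by default, in display order (the pressure
#: measures first, then resistance and the flow-side parameters).
DEFAULT_PARAMETERS = ("MAP", "SBP", "DBP", "TPR", "SV", "CO", "HR")

NOT_COMPUTABLE = "NC"  # cell marker when < 2 extrema exist


@dataclass(frozen=True)
class ParameterSummary:
    """Extrema metrics of one parameter reduced to summary statistics."""

    parameter: str
    n_extrema: int
    frequency: GroupSummary | None  # None when < 2 extrema
    amplitude: GroupSummary | None


@dataclass(frozen=True)
class AnalysisReport:
    """Per-parameter extrema summaries for one recording."""

    subject_id: str
    phase: str
    group: str
    n_beats: int
    duration: float
    parameters: tuple[ParameterSummary, ...]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.parameters:
            row: dict = {
                "parameter": p.parameter,
                "n_extrema": p.n_extrema,
            }
            for prefix, s in (("frequency", p.frequency), ("amplitude", p.amplitude)):
                for stat in ("n", "mean", "sd", "median", "q1", "q3"):
                    row[f"{prefix}_{stat}"] = (
                        getattr(s, stat) if s is not None else np.nan
                    )
            rows.append(row)
        return pd.DataFrame(rows)


def _summary_or_none(values: np.ndarray) -> GroupSummary | None:
    return summarize(values) if len(values) > 0 else None


def analyze_series(
    series: BeatSeries, parameters: Sequence[str] = DEFAULT_PARAMETERS
) -> AnalysisReport:
    """Run the extrema analysis for each requested parameter.

    Logs the beat count, rejected-row count and per-parameter extrema
    counts, the bookkeeping any serious reanalysis must surface.
    """
    logger.info(
        "analyzing %s/%s: %d beats over %.1f s (%d rows rejected on read)",
        series.subject_id, series.phase, len(series), series.duration,
        len(series.diagnostics),
    )
    summaries = []
    for name in parameters:
        metrics = analyze_parameter(series, name)
        logger.info(
            "  %s: %d extrema, %d consecutive pairs",
            metrics.parameter, metrics.n_extrema, len(metrics.intervals),
        )
        summaries.append(
            ParameterSummary(
                parameter=metrics.parameter,
                n_extrema=metrics.n_extrema,
                frequency=_summary_or_none(metrics.frequencies),
                amplitude=_summary_or_none(metrics.amplitudes),
            )
        )
    return AnalysisReport(
        subject_id=series.subject_id,
        phase=series.phase,
        group=series.group,
        n_beats=len(series),
        duration=series.duration,
        parameters=tuple(summaries),
    )


def compare_series(
    series_a: BeatSeries,
    series_b: BeatSeries,
    parameters: Sequence[str] = DEFAULT_PARAMETERS,
) -> dict[str, dict[str, ComparisonResult | None]]:
    """Compare extrema frequencies and amplitudes between two recordings.

    Returns ``{parameter: {"frequency": result, "amplitude": result}}``
    where a result is None when either recording has fewer than 2
    extrema pairs for that parameter (the comparison is marked
    not-computable and the run continues).
    """
    out: dict[str, dict[str, ComparisonResult | None]] = {}
    for name in parameters:
        ma = analyze_parameter(series_a, name)
        mb = analyze_parameter(series_b, name)
        cell: dict[str, ComparisonResult | None] = {}
        for measure in ("frequencies", "amplitudes"):
            va, vb = getattr(ma, measure), getattr(mb, measure)
            if len(va) < 2 or len(vb) < 2:
                logger.warning(
                    "%s %s: not computable (<2 extrema pairs in a recording)",
                    name, measure,
                )
                cell[measure] = None
            else:
                cell[measure] = compare_groups(va, vb)
        out[name] = {
            "frequency": cell["frequencies"],
            "amplitude": cell["amplitudes"],
        }
    return out


def _sig3(x: float) -> str:
    return f"{x:.3g}"


def _fmt_cell(s: GroupSummary) -> str:
    return f"{_sig3(s.median)} ({_sig3(s.q1)}-{_sig3(s.q3)})"


def _fmt_p(p: float) -> str:
    return "<0.0001" if p < 1e-4 else _sig3(p)


def comparison_table(
    results: dict[str, dict[str, ComparisonResult | None]],
    label_a: str = "A",
    label_b: str = "B",
) -> pd.DataFrame:
    """Wide display table: measure rows x per-parameter column groups.

    Cells are "median (q1-q3)" at 3 significant figures plus the P
    value; not-computable cells carry the :data:`NOT_COMPUTABLE` marker.
    """
    table: dict[str, dict[str, str]] = {"frequency": {}, "amplitude": {}}
    for parameter, cells in results.items():
        for measure in ("frequency", "amplitude"):
            res = cells[measure]
            row = table[measure]
            if res is None:
                row[f"{parameter} {label_a}"] = NOT_COMPUTABLE
                row[f"{parameter} {label_b}"] = NOT_COMPUTABLE
                row[f"{parameter} P"] = NOT_COMPUTABLE
            else:
                row[f"{parameter} {label_a}"] = _fmt_cell(res.group_a)
                row[f"{parameter} {label_b}"] = _fmt_cell(res.group_b)
                row[f"{parameter} P"] = _fmt_p(res.p_value)
    df = pd.DataFrame(table).T
    df.index.name = "measure"
    return df


def comparison_long(
    results: dict[str, dict[str, ComparisonResult | None]],
) -> pd.DataFrame:
    """Full-precision long-format companion of :func:`comparison_table`."""
    rows = []
    for parameter, cells in results.items():
        for measure in ("frequency", "amplitude"):
            res = cells[measure]
            row: dict = {"parameter": parameter, "measure": measure}
            if res is None:
                row["computable"] = False
            else:
                row.update(
                    computable=True,
                    test=res.test_name,
                    statistic=res.statistic,
                    p_value=res.p_value,
                    significant=res.significant,
                )
                for label, s in (("a", res.group_a), ("b", res.group_b)):
                    for stat in ("n", "mean", "sd", "median", "q1", "q3"):
                        row[f"{label}_{stat}"] = getattr(s, stat)
            rows.append(row)
    return pd.DataFrame(rows)
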