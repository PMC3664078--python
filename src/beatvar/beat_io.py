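"""Beat-by-beat haemodynamic recordings: data model and CSV I/O.

A recording is one row per heart beat with the beat time and the
haemodynamic state at that beat: heart rate (HR, beats/min), systolic and
diastolic blood pressure (SBP/DBP, mmHg), mean arterial pressure (MAP,
mmHg), stroke volume (SV, ml), cardiac output (CO, l/min) and total
peripheral resistance (TPR, "medical units", proportional to mmHg·min/l).
This mirrors the beat-indexed export of continuous finger-cuff monitors
such as the Finometer, but in a plain CSV dialect with explicit units in
the column names:

    time_s,hr_bpm,sbp_mmhg,dbp_mmhg,map_mmhg,sv_ml,co_lmin,tpr_mu

Composite parameters that are absent from an input file are derived in
the order MAP -> CO -> TPR (MAP from the clinical formula
``DBP + (SBP - DBP)/3``; CO = SV x HR / 1000; TPR = MAP / CO), the same
dependency order the device itself uses. Rows that violate physiological
invariants (e.g. SBP <= DBP) are dropped with a per-row diagnostic rather
than aborting the file: long recordings routinely contain artefact beats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "COLUMNS",
    "REQUIRED_COLUMNS",
    "PARAMETERS",
    "BeatRecord",
    "BeatSeries",
    "RowDiagnostic",
    "BeatFileError",
    "compute_map",
    "read_beats",
    "write_beats",
]

#: Canonical column order of the CSV dialect.
COLUMNS = (
    "time_s",
    "hr_bpm",
    "sbp_mmhg",
    "dbp_mmhg",
    "map_mmhg",
    "sv_ml",
    "co_lmin",
    "tpr_mu",
)

REQUIRED_COLUMNS = ("time_s", "sbp_mmhg", "dbp_mmhg")

#: Analysis parameter name -> CSV column.
PARAMETERS = {
    "HR": "hr_bpm",
    "SBP": "sbp_mmhg",
    "DBP": "dbp_mmhg",
    "MAP": "map_mmhg",
    "SV": "sv_ml",
    "CO": "co_lmin",
    "TPR": "tpr_mu",
}

MIN_BEATS_FOR_EXTREMA = 3


class BeatFileError(ValueError):
    """A beat CSV file is malformed (missing columns, non-monotone time)."""


@dataclass(frozen=True)
class BeatRecord:
    """Haemodynamic state at one heart beat.

    ``nan`` is permitted in an optional field only when the whole column
    was absent from the source file and could not be derived.
    """

    time: float  # seconds from recording start
    hr: float    # beats/min
    sbp: float   # mmHg
    dbp: float   # mmHg
    map: float   # mmHg
    sv: float    # ml
    co: float    # l/min
    tpr: float   # medical units (mmHg·min/l up to a device constant)


@dataclass(frozen=True)
class RowDiagnostic:
    """Why a row of an input file was rejected."""

    row: int  # 0-based data-row index in the source file
    message: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"row {self.row}: {self.message}"


@dataclass
class BeatSeries:
    """Time-ordered beat-by-beat recording for one subject and phase.

    The beat data live in a :class:`pandas.DataFrame` with the canonical
    columns of the CSV dialect; ``diagnostics`` records rows of the
    source file that were rejected during reading (it does not take part
    in equality).
    """

    data: pd.DataFrame
    subject_id: str = "unknown"
    phase: str = "rest"      # one of {rest, stress}
    group: str = "other"     # one of {HD, NC, other}
    diagnostics: list[RowDiagnostic] = field(default_factory=list, compare=False)

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"BeatSeries data missing columns: {missing}")
        self.data = self.data.loc[:, list(COLUMNS)].reset_index(drop=True)
        t = self.data["time_s"].to_numpy(float)
        if len(t) and not np.all(np.diff(t) > 0):
            bad = int(np.nonzero(~(np.diff(t) > 0))[0][0]) + 1
            raise BeatFileError(f"beat times not strictly increasing at index {bad}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def times(self) -> np.ndarray:
        return self.data["time_s"].to_numpy(float)

    @property
    def duration(self) -> float:
        t = self.times
        return float(t[-1] - t[0]) if len(t) >= 2 else 0.0

    def values(self, parameter: str) -> np.ndarray:
        """Values of one analysis parameter (``MAP``, ``SBP``, ...)."""
        column = PARAMETERS.get(parameter.upper())
        if column is None:
            raise ValueError(
                f"unknown parameter {parameter!r}; valid names: "
                f"{', '.join(sorted(PARAMETERS))}"
            )
        return self.data[column].to_numpy(float)

    @property
    def records(self) -> Iterator[BeatRecord]:
        for row in self.data.itertuples(index=False):
            yield BeatRecord(
                time=row.time_s, hr=row.hr_bpm, sbp=row.sbp_mmhg,
                dbp=row.dbp_mmhg, map=row.map_mmhg, sv=row.sv_ml,
                co=row.co_lmin, tpr=row.tpr_mu,
            )

    def equals(self, other: "BeatSeries") -> bool:
        return (
            self.subject_id == other.subject_id
            and self.phase == other.phase
            and self.group == other.group
            and self.data.equals(other.data)
        )


def compute_map(sbp: float, dbp: float) -> float:
    """Mean arterial pressure from the clinical one-third-pulse-pressure rule.

    MAP is not the arithmetic mean of SBP and DBP: the heart spends about
    two thirds of the cardiac cycle in diastole, so clinically
    ``MAP = DBP + (SBP - DBP) / 3``.

    Raises
    ------
    ValueError
        If ``sbp <= dbp`` or ``dbp <= 0`` (not a physiological beat).
    """
    sbp_arr = np.asarray(sbp, dtype=float)
    dbp_arr = np.asarray(dbp, dtype=float)
    if np.any(sbp_arr <= dbp_arr) or np.any(dbp_arr <= 0):
        raise ValueError("compute_map requires sbp > dbp > 0")
    out = dbp_arr + (sbp_arr - dbp_arr) / 3.0
    return float(out) if out.ndim == 0 else out


def _validate_rows(df: pd.DataFrame, present: set[str]) -> tuple[pd.DataFrame, list[RowDiagnostic]]:
    """Drop rows violating per-beat invariants; keep a diagnostic each.

    Invariants are only enforced on columns that are present in (or were
    derived for) the file; a wholly-absent optional column stays NaN.
    """
    diags: list[RowDiagnostic] = []
    bad = pd.Series(False, index=df.index)

    def flag(mask: pd.Series, message: str) -> None:
        nonlocal bad
        for idx in df.index[mask & ~bad]:
            diags.append(RowDiagnostic(int(idx), message))
        bad = bad | mask

    # NaN in a column that should have data means a corrupt row.
    for col in COLUMNS:
        if col in present:
            flag(df[col].isna(), f"missing value in {col}")
    flag(df["time_s"] < 0, "negative time")
    flag(~(df["sbp_mmhg"] > df["dbp_mmhg"]), "sbp <= dbp")
    flag(~(df["dbp_mmhg"] > 0), "dbp <= 0")
    if "map_mmhg" in present:
        flag(
            ~((df["dbp_mmhg"] <= df["map_mmhg"]) & (df["map_mmhg"] <= df["sbp_mmhg"])),
            "map outside [dbp, sbp]",
        )
    for col, name in (("hr_bpm", "hr"), ("sv_ml", "sv"), ("co_lmin", "co"), ("tpr_mu", "tpr")):
        if col in present:
            flag(~(df[col] > 0), f"{name} <= 0")

    diags.sort(key=lambda d: d.row)
    return df[~bad], diags


def read_beats(
    path: str | Path,
    subject_id: str = "unknown",
    phase: str = "rest",
    group: str = "other",
) -> BeatSeries:
    """Read a beat CSV file into a validated :class:`BeatSeries`.

    Required columns: ``time_s``, ``sbp_mmhg``, ``dbp_mmhg``. Optional
    columns are derived where possible (MAP from SBP/DBP, CO from SV and
    HR, TPR from MAP and CO) and left NaN otherwise. Invalid rows are
    dropped and reported in ``BeatSeries.diagnostics``.

    Raises
    ------
    BeatFileError
        Missing required column, or non-monotone beat times among the
        retained rows (the first offending index is named).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=float, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise BeatFileError(f"{path.name}: missing required column(s) {missing}")

    present = set(c for c in COLUMNS if c in df.columns)
    for col in COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df.loc[:, list(COLUMNS)]

    # Rows whose SBP/DBP already fail invariants must not poison the
    # derivation step, so validate the raw columns first.
    df, diags = _validate_rows(df, present)

    # Derived fills, each only when the source column was absent:
    # MAP -> CO -> TPR, mirroring the device's own dependency order.
    if "map_mmhg" not in present:
        df = df.assign(map_mmhg=compute_map(df["sbp_mmhg"].to_numpy(),
                                            df["dbp_mmhg"].to_numpy()))
        present.add("map_mmhg")
    if "co_lmin" not in present and {"sv_ml", "hr_bpm"} <= present:
        df = df.assign(co_lmin=df["sv_ml"] * df["hr_bpm"] / 1000.0)
        present.add("co_lmin")
    if "tpr_mu" not in present and "co_lmin" in present:
        df = df.assign(tpr_mu=df["map_mmhg"] / df["co_lmin"])
        present.add("tpr_mu")

    df, derived_diags = _validate_rows(df, present)
    diags = sorted(diags + derived_diags, key=lambda d: d.row)

    t = df["time_s"].to_numpy(float)
    not_increasing = ~(np.diff(t) > 0)
    if np.any(not_increasing):
        bad = int(df.index[np.nonzero(not_increasing)[0][0] + 1])
        raise BeatFileError(
            f"{path.name}: beat times not strictly increasing at row {bad}"
        )

    return BeatSeries(
        data=df.reset_index(drop=True),
        subject_id=subject_id,
        phase=phase,
        group=group,
        diagnostics=diags,
    )


def write_beats(series: BeatSeries, path: str | Path) -> None:
    """Write a :class:`BeatSeries` in the canonical CSV dialect.

    Floats are written in shortest round-trip representation, so
    ``read_beats(write_beats(s))`` reproduces every stored value exactly.
    """
    series.data.loc[:, list(COLUMNS)].to_csv(
        path, index=False, float_format=lambda x: repr(float(x))
    )
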