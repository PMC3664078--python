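"""Synthetic beat-to-beat haemodynamic recordings with known structure.

Real continuous-monitor recordings of the kind the analysis targets are
not publicly available, so this module generates them: beat times from a
truncated-normal RR-interval process, and per-beat pressures built from
a baseline plus slow sinusoidal oscillations plus white measurement
noise. Sinusoids are the point of the design — a parameter driven by a
single sinusoid of frequency ``f`` and amplitude ``A`` has an analytic
ground truth (extrema frequency ``2f``, extrema amplitude ``2A``)
against which the whole detection pipeline can be validated.

Derived parameters are kept physiologically self-consistent: MAP follows
the clinical one-third-pulse-pressure formula from the generated
SBP/DBP, CO = SV x HR / 1000, and TPR defaults to MAP / CO. A profile
may instead drive TPR with its own oscillations (plus noise around the
baseline MAP/CO ratio), which is how the dissociation seen clinically —
pressure varying fast while resistance varies slowly, or vice versa —
is emulated.

Two bundled profile families mirror the contrast the analysis is meant
to expose: an ``HD``-like subject (haemodialysis patient: faster MAP
oscillation, small TPR excursions — blunted baroreflex-style resistance
control) and an ``NC``-like subject (normal control: slower MAP
oscillation, five-fold larger TPR excursions).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .beat_io import COLUMNS, BeatSeries, compute_map, write_beats

__all__ = [
    "OscillationSpec",
    "SubjectProfile",
    "simulate_beat_times",
    "simulate_subject",
    "make_paired_dataset",
    "hd_profile",
    "nc_profile",
    "profile_from_dict",
    "load_profiles",
]

#: Hard floor on an RR interval (a 240 beats/min ceiling): prevents
#: degenerate, non-increasing beat times.
RR_FLOOR = 0.25

#: Oscillation frequencies must stay below this fraction of the mean
#: beat rate — a beat-sampled signal cannot carry oscillations near or
#: above the Nyquist rate.
NYQUIST_FRACTION = 0.45

#: Parameters that may carry oscillations or noise.
DRIVABLE = ("map", "sbp", "dbp", "sv", "tpr")

_MAX_RESAMPLE_ROUNDS = 100


@dataclass(frozen=True)
class OscillationSpec:
    """One sinusoidal component: ``amplitude * sin(2 pi f t + phase)``."""

    frequency: float          # Hz, > 0
    amplitude: float          # parameter units, >= 0
    phase: float = 0.0        # radians

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("oscillation frequency must be positive")
        if self.amplitude < 0:
            raise ValueError("oscillation amplitude must be non-negative")


@dataclass(frozen=True)
class SubjectProfile:
    """Everything needed to generate one subject/phase recording.

    ``oscillations`` maps a parameter name (``map``, ``sbp``, ``dbp``,
    ``sv``, ``tpr``) to its sinusoidal components; a ``map`` oscillation
    is added to SBP and DBP alike, shifting MAP by exactly that
    component. ``noise_sd`` maps a parameter name to the SD of its
    additive white noise (per beat). Presence of a ``tpr`` entry in
    either mapping switches TPR from the derived MAP/CO ratio to an
    independently oscillated signal around the baseline ratio.
    """

    mean_rr: float                       # seconds per beat
    rr_sd: float                         # seconds
    sbp_baseline: float                  # mmHg
    dbp_baseline: float                  # mmHg
    sv_baseline: float                   # ml
    oscillations: Mapping[str, tuple[OscillationSpec, ...]] = field(
        default_factory=dict
    )
    noise_sd: Mapping[str, float] = field(default_factory=dict)
    duration: float = 1800.0             # seconds
    seed: int = 0
    subject_id: str = "synthetic"
    phase: str = "rest"
    group: str = "other"

    def __post_init__(self) -> None:
        if self.sbp_baseline <= self.dbp_baseline or self.dbp_baseline <= 0:
            raise ValueError("baselines must satisfy sbp > dbp > 0")
        if self.sv_baseline <= 0:
            raise ValueError("sv_baseline must be positive")
        if self.mean_rr <= 0 or self.duration <= 0:
            raise ValueError("mean_rr and duration must be positive")
        if self.rr_sd < 0 or (self.rr_sd > 0 and self.mean_rr <= 3 * self.rr_sd):
            raise ValueError("need rr_sd >= 0 and mean_rr > 3 * rr_sd")
        limit = NYQUIST_FRACTION / self.mean_rr
        for name, specs in self.oscillations.items():
            if name not in DRIVABLE:
                raise ValueError(
                    f"cannot oscillate {name!r}; drivable: {DRIVABLE}"
                )
            for spec in specs:
                if spec.frequency > limit:
                    raise ValueError(
                        f"{name} oscillation at {spec.frequency} Hz exceeds "
                        f"{limit:.3f} Hz ({NYQUIST_FRACTION} x mean beat rate)"
                    )
        for name in self.noise_sd:
            if name not in DRIVABLE:
                raise ValueError(f"cannot add noise to {name!r}")


def simulate_beat_times(
    mean_rr: float, rr_sd: float, duration: float, seed: int
) -> np.ndarray:
    """Strictly increasing beat times on ``[0, duration]``.

    RR intervals are truncated-normal (lower bound 0.25 s); with
    ``rr_sd = 0`` the grid is exactly regular. Deterministic for a given
    seed.
    """
    if mean_rr <= 0 or duration <= 0:
        raise ValueError("mean_rr and duration must be positive")
    if rr_sd < 0:
        raise ValueError("rr_sd must be non-negative")
    if rr_sd == 0:
        n = int(np.floor(duration / mean_rr + 1e-9))
        return np.arange(n + 1) * mean_rr
    rng = np.random.default_rng(seed)
    n_guess = int(duration / mean_rr * 1.2) + 16
    rr = np.empty(0)
    while np.sum(rr) <= duration:
        block = rng.normal(mean_rr, rr_sd, n_guess)
        for _ in range(_MAX_RESAMPLE_ROUNDS):
            low = block < RR_FLOOR
            if not low.any():
                break
            block[low] = rng.normal(mean_rr, rr_sd, int(low.sum()))
        block = np.maximum(block, RR_FLOOR)
        rr = np.concatenate([rr, block])
    times = np.concatenate([[0.0], np.cumsum(rr)])
    return times[times <= duration]


def _oscillation_sum(
    specs: Sequence[OscillationSpec], t: np.ndarray
) -> np.ndarray:
    out = np.zeros_like(t)
    for s in specs:
        out += s.amplitude * np.sin(2 * np.pi * s.frequency * t + s.phase)
    return out


def simulate_subject(profile: SubjectProfile) -> BeatSeries:
    """Generate a complete beat-by-beat recording from a profile.

    Noise draws that would make a beat unphysiological (SBP <= DBP, or
    a non-positive SV/TPR) are redrawn for the offending beats; if the
    deterministic part itself is unphysiological no redraw can help and
    generation fails after a bounded number of rounds.
    """
    rng = np.random.default_rng(profile.seed)
    t = simulate_beat_times(
        profile.mean_rr, profile.rr_sd, profile.duration, profile.seed
    )
    n = len(t)
    if n < 2:
        raise ValueError("duration too short: fewer than 2 beats generated")

    rr = np.diff(t)
    rr = np.concatenate([[rr[0]], rr])  # first beat inherits the first interval
    hr = 60.0 / rr

    osc = {
        name: _oscillation_sum(specs, t)
        for name, specs in profile.oscillations.items()
    }
    noise = dict(profile.noise_sd)
    zeros = np.zeros(n)

    def draw(name: str, idx: np.ndarray | None = None) -> np.ndarray:
        sd = noise.get(name, 0.0)
        size = n if idx is None else len(idx)
        return rng.normal(0.0, sd, size) if sd > 0 else np.zeros(size)

    shared = osc.get("map", zeros)
    sbp_det = profile.sbp_baseline + osc.get("sbp", zeros) + shared
    dbp_det = profile.dbp_baseline + osc.get("dbp", zeros) + shared
    sbp = sbp_det + draw("sbp")
    dbp = dbp_det + draw("dbp")
    for round_ in range(_MAX_RESAMPLE_ROUNDS + 1):
        bad = np.nonzero((sbp <= dbp) | (dbp <= 0))[0]
        if len(bad) == 0:
            break
        if round_ == _MAX_RESAMPLE_ROUNDS:
            raise RuntimeError(
                "could not generate sbp > dbp > 0 for all beats; "
                "oscillation amplitudes exceed the pulse pressure"
            )
        sbp[bad] = sbp_det[bad] + draw("sbp", bad)
        dbp[bad] = dbp_det[bad] + draw("dbp", bad)

    map_ = compute_map(sbp, dbp)

    sv_det = profile.sv_baseline + osc.get("sv", zeros)
    sv = sv_det + draw("sv")
    for round_ in range(_MAX_RESAMPLE_ROUNDS + 1):
        bad = np.nonzero(sv <= 0)[0]
        if len(bad) == 0:
            break
        if round_ == _MAX_RESAMPLE_ROUNDS:
            raise RuntimeError("could not generate positive stroke volume")
        sv[bad] = sv_det[bad] + draw("sv", bad)

    co = sv * hr / 1000.0

    if "tpr" in profile.oscillations or "tpr" in noise:
        map_baseline = compute_map(profile.sbp_baseline, profile.dbp_baseline)
        co_baseline = profile.sv_baseline * (60.0 / profile.mean_rr) / 1000.0
        tpr_det = map_baseline / co_baseline + osc.get("tpr", zeros)
        tpr = tpr_det + draw("tpr")
        for round_ in range(_MAX_RESAMPLE_ROUNDS + 1):
            bad = np.nonzero(tpr <= 0)[0]
            if len(bad) == 0:
                break
            if round_ == _MAX_RESAMPLE_ROUNDS:
                raise RuntimeError("could not generate positive resistance")
            tpr[bad] = tpr_det[bad] + draw("tpr", bad)
    else:
        tpr = map_ / co

    data = pd.DataFrame(
        {
            "time_s": t,
            "hr_bpm": hr,
            "sbp_mmhg": sbp,
            "dbp_mmhg": dbp,
            "map_mmhg": map_,
            "sv_ml": sv,
            "co_lmin": co,
            "tpr_mu": tpr,
        },
        columns=list(COLUMNS),
    )
    return BeatSeries(
        data=data,
        subject_id=profile.subject_id,
        phase=profile.phase,
        group=profile.group,
    )


# --------------------------------------------------------------------------
# Bundled subject profiles
#
# Durations follow the study design the package emulates: ~25 min of rest
# for the dialysis patient, 30 min for the control, and a 3 h stress phase
# (a dialysis session vs an exercise bout). Baselines use each subject's
# cuff pressures (121/75 and 118/78 mmHg). MAP oscillation frequencies
# (0.38 vs 0.20 Hz) and the 5:1 NC:HD ratio of TPR oscillation amplitude
# encode the designed contrast: fast pressure swings with sluggish
# resistance control in the dialysis-like subject, the reverse in the
# control. Amplitudes (2.5 mmHg pressure, 0.3/1.5 MU resistance) and the
# RR process (0.8 s / 40 ms for HD — mild tachycardia with depressed HRV;
# 1.0 s / 50 ms for the control) are plausibility choices at textbook
# physiological scales.
# --------------------------------------------------------------------------

def hd_profile(phase: str = "rest", seed: int = 101) -> SubjectProfile:
    """Haemodialysis-patient-like profile (rest or stress phase)."""
    stress = phase == "stress"
    return SubjectProfile(
        mean_rr=0.8,
        rr_sd=0.04,
        sbp_baseline=121.0,
        dbp_baseline=75.0,
        sv_baseline=70.0,
        oscillations={
            "map": (OscillationSpec(frequency=0.38, amplitude=2.5),),
            "tpr": (OscillationSpec(frequency=0.42, amplitude=0.3),),
        },
        noise_sd={"sbp": 0.3, "dbp": 0.3, "sv": 0.5, "tpr": 0.015},
        duration=10800.0 if stress else 1500.0,
        seed=seed,
        subject_id="hd-like",
        phase="stress" if stress else "rest",
        group="HD",
    )


def nc_profile(phase: str = "rest", seed: int = 202) -> SubjectProfile:
    """Normal-control-like profile (rest, or stress = exercise)."""
    stress = phase == "stress"
    return SubjectProfile(
        mean_rr=0.75 if stress else 1.0,
        rr_sd=0.05,
        sbp_baseline=118.0,
        dbp_baseline=78.0,
        sv_baseline=80.0,
        oscillations={
            "map": (OscillationSpec(frequency=0.23 if stress else 0.20,
                                    amplitude=2.5),),
            "tpr": (OscillationSpec(frequency=0.40, amplitude=1.5),),
        },
        noise_sd={"sbp": 0.3, "dbp": 0.3, "sv": 0.5, "tpr": 0.075},
        duration=10800.0 if stress else 1800.0,
        seed=seed,
        subject_id="nc-like",
        phase="stress" if stress else "rest",
        group="NC",
    )


def make_paired_dataset(
    out_dir: str | Path,
    hd_rest: SubjectProfile | None = None,
    nc_rest: SubjectProfile | None = None,
    hd_stress: SubjectProfile | None = None,
    nc_stress: SubjectProfile | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write a rest + stress recording pair for both subjects.

    Any profile left as None falls back to the bundled defaults; a
    ``seed`` reseeds all four profiles deterministically (seed, seed+1,
    seed+2, seed+3). Returns the four CSV paths plus a JSON manifest
    recording every profile and seed used.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    profiles = {
        "hd_rest": hd_rest or hd_profile("rest"),
        "nc_rest": nc_rest or nc_profile("rest"),
        "hd_stress": hd_stress or hd_profile("stress", seed=303),
        "nc_stress": nc_stress or nc_profile("stress", seed=404),
    }
    if seed is not None:
        profiles = {
            name: replace(p, seed=seed + i)
            for i, (name, p) in enumerate(profiles.items())
        }

    paths: dict[str, Path] = {}
    for name, profile in profiles.items():
        series = simulate_subject(profile)
        path = out_dir / f"{name}.csv"
        write_beats(series, path)
        paths[name] = path

    manifest = out_dir / "manifest.json"
    manifest.write_text(
        json.dumps(
            {name: _profile_to_dict(p) for name, p in profiles.items()},
            indent=2,
        )
    )
    paths["manifest"] = manifest
    return paths


def _profile_to_dict(profile: SubjectProfile) -> dict:
    d = asdict(profile)
    d["oscillations"] = {
        name: [asdict(s) for s in specs]
        for name, specs in profile.oscillations.items()
    }
    d["noise_sd"] = dict(profile.noise_sd)
    return d


def profile_from_dict(raw: Mapping) -> SubjectProfile:
    """Build a profile from a plain mapping (parsed YAML/JSON config)."""
    raw = dict(raw)
    osc = {
        name: tuple(OscillationSpec(**spec) for spec in specs)
        for name, specs in raw.pop("oscillations", {}).items()
    }
    return SubjectProfile(oscillations=osc, **raw)


def load_profiles(path: str | Path) -> dict[str, SubjectProfile]:
    """Read a YAML/JSON config mapping dataset slots to profiles.

    Recognised top-level keys: ``hd_rest``, ``nc_rest``, ``hd_stress``,
    ``nc_stress`` — each a mapping of :class:`SubjectProfile` fields.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, Mapping):
        raise ValueError(f"{path.name}: config must be a mapping")
    known = {"hd_rest", "nc_rest", "hd_stress", "nc_stress"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(
            f"{path.name}: unknown config key(s) {sorted(unknown)}; "
            f"expected a subset of {sorted(known)}"
        )
    out = {}
    for name, body in raw.items():
        try:
            out[name] = profile_from_dict(body)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path.name}: invalid profile {name!r}: {exc}")
    return out
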