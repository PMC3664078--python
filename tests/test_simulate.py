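"""Synthetic beat-to-beat generator: determinism, consistency, recovery."""

import numpy as np
import pytest

from beatvar.beat_io import compute_map, read_beats
from beatvar.extrema import analyze_parameter
from beatvar.simulate import (
    OscillationSpec,
    SubjectProfile,
    hd_profile,
    load_profiles,
    make_paired_dataset,
    nc_profile,
    simulate_beat_times,
    simulate_subject,
)


def single_map_profile(f=0.2, amp=6.0, noise=0.3, duration=1800.0, seed=0):
    return SubjectProfile(
        mean_rr=1.0, rr_sd=0.05,
        sbp_baseline=120.0, dbp_baseline=80.0, sv_baseline=70.0,
        oscillations={"map": (OscillationSpec(frequency=f, amplitude=amp),)},
        noise_sd={"sbp": noise, "dbp": noise},
        duration=duration, seed=seed,
    )


class TestBeatTimes:
    def test_zero_jitter_gives_regular_grid(self):
        t = simulate_beat_times(1.0, 0.0, 10.0, seed=0)
        assert np.array_equal(t, np.arange(11.0))

    def test_same_seed_reproduces_sequence(self):
        a = simulate_beat_times(0.8, 0.05, 300.0, seed=5)
        b = simulate_beat_times(0.8, 0.05, 300.0, seed=5)
        assert np.array_equal(a, b)

    def test_different_seed_differs(self):
        a = simulate_beat_times(0.8, 0.05, 300.0, seed=5)
        b = simulate_beat_times(0.8, 0.05, 300.0, seed=6)
        assert not np.array_equal(a, b)

    def test_beat_count_tracks_expectation(self):
        counts = [
            len(simulate_beat_times(0.8, 0.05, 1800.0, seed=s))
            for s in range(100)
        ]
        assert abs(np.mean(counts) - 1800 / 0.8) / (1800 / 0.8) < 0.05

    def test_strictly_increasing_and_bounded(self):
        t = simulate_beat_times(0.5, 0.1, 120.0, seed=3)
        assert np.all(np.diff(t) > 0)
        assert np.all(np.diff(t) >= 0.25 - 1e-9)  # RR floor
        assert t[0] == 0 and t[-1] <= 120.0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate_beat_times(-1.0, 0.0, 10.0, seed=0)
        with pytest.raises(ValueError):
            simulate_beat_times(1.0, 0.0, 0.0, seed=0)


class TestProfileValidation:
    def test_oscillation_above_nyquist_guard_rejected(self):
        with pytest.raises(ValueError, match="Hz"):
            SubjectProfile(
                mean_rr=1.0, rr_sd=0.05, sbp_baseline=120, dbp_baseline=80,
                sv_baseline=70,
                oscillations={"map": (OscillationSpec(0.5, 1.0),)},
            )

    def test_inverted_baselines_rejected(self):
        with pytest.raises(ValueError):
            SubjectProfile(mean_rr=1.0, rr_sd=0.0, sbp_baseline=80,
                           dbp_baseline=120, sv_baseline=70)

    def test_excessive_rr_jitter_rejected(self):
        with pytest.raises(ValueError):
            SubjectProfile(mean_rr=0.6, rr_sd=0.3, sbp_baseline=120,
                           dbp_baseline=80, sv_baseline=70)

    def test_unknown_oscillation_target_rejected(self):
        with pytest.raises(ValueError, match="hr"):
            SubjectProfile(
                mean_rr=1.0, rr_sd=0.0, sbp_baseline=120, dbp_baseline=80,
                sv_baseline=70,
                oscillations={"hr": (OscillationSpec(0.1, 1.0),)},
            )


class TestSimulateSubject:
    def test_quiet_profile_is_constant_with_no_extrema(self):
        profile = SubjectProfile(
            mean_rr=1.0, rr_sd=0.0, sbp_baseline=120, dbp_baseline=80,
            sv_baseline=70, duration=100.0,
        )
        series = simulate_subject(profile)
        for name in ("MAP", "SBP", "DBP", "TPR", "SV", "CO"):
            assert analyze_parameter(series, name).n_extrema == 0

    def test_every_record_physiologically_consistent(self):
        series = simulate_subject(hd_profile())
        d = series.data
        assert np.all(d["sbp_mmhg"] > d["dbp_mmhg"])
        assert np.all(d["dbp_mmhg"] > 0)
        expected_map = compute_map(d["sbp_mmhg"].to_numpy(),
                                   d["dbp_mmhg"].to_numpy())
        assert np.all(np.abs(d["map_mmhg"] - expected_map) < 1e-9)
        assert np.allclose(d["co_lmin"], d["sv_ml"] * d["hr_bpm"] / 1000)
        for col in ("hr_bpm", "sv_ml", "co_lmin", "tpr_mu"):
            assert np.all(d[col] > 0)

    def test_oversized_oscillation_fails_cleanly(self):
        profile = SubjectProfile(
            mean_rr=1.0, rr_sd=0.0, sbp_baseline=120, dbp_baseline=110,
            sv_baseline=70, duration=60.0,
            oscillations={"sbp": (OscillationSpec(0.1, 40.0),)},
        )
        with pytest.raises(RuntimeError):
            simulate_subject(profile)

    def test_map_oscillation_frequency_recovered(self):
        # 0.2 Hz design -> 0.4 Hz extrema frequency; at one beat per
        # second this sits well inside the resolvable band
        medians_f, medians_a = [], []
        for seed in range(30):
            series = simulate_subject(single_map_profile(seed=seed))
            m = analyze_parameter(series, "MAP")
            medians_f.append(np.median(m.frequencies))
            medians_a.append(np.median(m.amplitudes))
        assert abs(np.median(medians_f) - 0.4) / 0.4 < 0.15
        assert abs(np.median(medians_a) - 12.0) / 12.0 < 0.15

    def test_noise_does_not_decrease_extrema_frequency(self):
        # white noise can only add turning points; the ensemble median
        # frequency is non-decreasing in the noise level (a small slack
        # absorbs Monte-Carlo wobble at nearly equal noise levels)
        med = []
        for noise in (0.0, 1.0, 3.0):
            vals = []
            for seed in range(10):
                series = simulate_subject(
                    single_map_profile(noise=noise, duration=600.0, seed=seed)
                )
                vals.append(np.median(
                    analyze_parameter(series, "MAP").frequencies))
            med.append(np.median(vals))
        assert med[1] >= med[0] * 0.98
        assert med[2] >= med[1] * 0.98
        assert med[2] > med[0]  # strong noise clearly adds extrema

    def test_determinism_of_full_series(self):
        p = hd_profile()
        a = simulate_subject(p)
        b = simulate_subject(p)
        assert a.data.equals(b.data)


class TestPairedDataset:
    def test_default_dataset_files_and_manifest(self, tmp_path):
        # scaled-down durations keep the fixture light
        import dataclasses
        short = {
            k: dataclasses.replace(v, duration=120.0)
            for k, v in {
                "hd_rest": hd_profile("rest"), "nc_rest": nc_profile("rest"),
                "hd_stress": hd_profile("stress", seed=303),
                "nc_stress": nc_profile("stress", seed=404),
            }.items()
        }
        paths = make_paired_dataset(tmp_path, **short, seed=9)
        assert set(paths) == {
            "hd_rest", "nc_rest", "hd_stress", "nc_stress", "manifest"
        }
        for name in ("hd_rest", "nc_rest", "hd_stress", "nc_stress"):
            series = read_beats(paths[name])
            assert len(series) > 100
        assert paths["manifest"].read_text().startswith("{")

    def test_byte_identical_regeneration(self, tmp_path):
        import dataclasses
        hd = dataclasses.replace(hd_profile(), duration=120.0)
        nc = dataclasses.replace(nc_profile(), duration=120.0)
        p1 = make_paired_dataset(tmp_path / "a", hd_rest=hd, nc_rest=nc,
                                 hd_stress=hd, nc_stress=nc, seed=11)
        p2 = make_paired_dataset(tmp_path / "b", hd_rest=hd, nc_rest=nc,
                                 hd_stress=hd, nc_stress=nc, seed=11)
        for name in ("hd_rest", "nc_rest", "hd_stress", "nc_stress"):
            assert p1[name].read_bytes() == p2[name].read_bytes()

    def test_seed_changes_contents_not_schema(self, tmp_path):
        import dataclasses
        hd = dataclasses.replace(hd_profile(), duration=120.0)
        nc = dataclasses.replace(nc_profile(), duration=120.0)
        kw = dict(hd_rest=hd, nc_rest=nc, hd_stress=hd, nc_stress=nc)
        p1 = make_paired_dataset(tmp_path / "a", **kw, seed=1)
        p2 = make_paired_dataset(tmp_path / "b", **kw, seed=2)
        assert p1["hd_rest"].read_bytes() != p2["hd_rest"].read_bytes()
        h1 = p1["hd_rest"].read_text().splitlines()[0]
        h2 = p2["hd_rest"].read_text().splitlines()[0]
        assert h1 == h2

    def test_default_durations_mirror_study_design(self):
        assert hd_profile("rest").duration == 1500.0
        assert nc_profile("rest").duration == 1800.0
        assert hd_profile("stress").duration == 10800.0
        assert nc_profile("stress").duration == 10800.0


class TestConfig:
    def test_yaml_profile_round_trip(self, tmp_path):
        cfg = tmp_path / "profiles.yaml"
        cfg.write_text(
            """
hd_rest:
  mean_rr: 0.9
  rr_sd: 0.04
  sbp_baseline: 121
  dbp_baseline: 75
  sv_baseline: 70
  duration: 60
  seed: 3
  oscillations:
    map:
      - {frequency: 0.3, amplitude: 2.0}
  noise_sd: {sbp: 0.2, dbp: 0.2}
"""
        )
        profiles = load_profiles(cfg)
        assert set(profiles) == {"hd_rest"}
        p = profiles["hd_rest"]
        assert p.mean_rr == 0.9
        assert p.oscillations["map"][0].frequency == 0.3
        simulate_subject(p)  # usable as-is

    def test_unknown_key_rejected_with_name(self, tmp_path):
        cfg = tmp_path / "bad.yaml"
        cfg.write_text("bogus: {mean_rr: 1}\n")
        with pytest.raises(ValueError, match="bogus"):
            load_profiles(cfg)

    def test_invalid_field_named_in_error(self, tmp_path):
        cfg = tmp_path / "bad2.yaml"
        cfg.write_text(
            "hd_rest: {mean_rr: 1.0, rr_sd: 0.0, sbp_baseline: 80,\n"
            "  dbp_baseline: 120, sv_baseline: 70}\n"
        )
        with pytest.raises(ValueError, match="hd_rest"):
            load_profiles(cfg)
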