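import numpy as np
import pytest

from ectopulse import simulate as sim
from ectopulse.beats import classify_beats, detect_r_peaks, find_eligible_ectopics
from ectopulse.io import resample_to_1khz, sv_response
from ectopulse.pipeline import RunConfig, analyze_record


class TestCohortTier:
    def test_schema_and_sizes(self):
        df = sim.simulate_cohort_summaries(seed=0)
        assert len(df) == 26
        assert (df["group"] == "responder").sum() == 6
        for var in ("sbp", "pep", "pp", "dpdt"):
            assert f"delta_abs_{var}" in df and f"delta_rel_{var}" in df
        # responder flags consistent with the drawn SV change
        assert (df["responder_10"] == (df["dsv_rel_pct"] >= 10)).all()
        np.testing.assert_allclose(
            (df["sv_post_ml"] / df["sv_baseline_ml"] - 1) * 100, df["dsv_rel_pct"], atol=1e-9
        )

    def test_seeded_determinism_byte_identical(self):
        a = sim.simulate_cohort_summaries(seed=42).to_csv()
        b = sim.simulate_cohort_summaries(seed=42).to_csv()
        assert a == b

    def test_group_mean_converges_to_configured_value(self):
        # non-responder SBP delta mean -0.1 mmHg
        ss = np.random.SeedSequence(2024)
        means = []
        for child in ss.spawn(1000):
            df = sim.simulate_cohort_summaries(seed=child)
            means.append(df.loc[df["group"] == "non-responder", "delta_abs_sbp"].mean())
        assert np.mean(means) == pytest.approx(-0.1, abs=0.2)

    def test_relative_delta_derived_from_baseline(self):
        df = sim.simulate_cohort_summaries(seed=3)
        np.testing.assert_allclose(
            df["delta_rel_sbp"], 100 * df["delta_abs_sbp"] / df["baseline_sbp"]
        )

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            sim.GroupParams(0.0, -1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            sim.CohortSimConfig(n_nonresp=0, n_resp=0)


class TestStarling:
    P = sim.StarlingParams(sv_max_ml=100.0, p50=1.0, slope_k=0.2)

    def test_midpoint(self):
        assert sim.starling_sv(1.0, self.P) == pytest.approx(50.0)

    def test_plateau_asymptote(self):
        assert sim.starling_sv(50.0, self.P) == pytest.approx(100.0)
        assert sim.starling_sv(-50.0, self.P) == pytest.approx(0.0, abs=1e-9)

    def test_monotone_nondecreasing(self):
        x = np.linspace(-2, 4, 200)
        sv = sim.starling_sv(x, self.P)
        assert (np.diff(sv) >= 0).all()

    def test_operating_points_set_responder_status(self):
        shift = sim.PatientSimConfig().fluid_bolus_preload_shift
        for cfg_fn, expect_resp in ((sim.responder_config, True), (sim.nonresponder_config, False)):
            st = cfg_fn().starling
            before = sim.starling_sv(1.0, st)
            after = sim.starling_sv(1.0 + shift, st)
            dsv = 100 * (after - before) / before
            assert (dsv >= 10) == expect_resp


class TestWaveformTier:
    def test_no_ectopics_means_not_applicable(self):
        cfg = sim.PatientSimConfig(duration_s=60.0, p_ectopic=0.0)
        rec, hemo, sv = sim.simulate_patient_waveforms(cfg, seed=2)
        assert (hemo["label"] == "ectopic").sum() == 0
        res = analyze_record(rec, sv, RunConfig())
        assert not res.applicable
        assert any("not applicable" in line for line in res.qc_log)

    def test_ventricular_full_compensatory_pause(self):
        # no jitter: post-ectopic RR must be exactly 2*RR - coupling
        cfg = sim.PatientSimConfig(duration_s=120.0, p_ectopic=0.05, es_type_mix=1.0,
                                   rr_sd_ms=0.0, resp_rr_mod_ms=0.0)
        _, hemo, _ = sim.simulate_patient_waveforms(cfg, seed=3)
        rr_nom = cfg.rr_nominal_ms
        ect = hemo.index[hemo["label"] == "ectopic"]
        assert len(ect) > 0
        for i in ect:
            coupling = hemo["rr_prev_ms"].iloc[i]
            post_rr = hemo["rr_prev_ms"].iloc[i + 1]
            assert coupling + post_rr == pytest.approx(2 * rr_nom, abs=1e-6)
            assert post_rr == pytest.approx(2 * rr_nom - coupling, abs=1e-6)

    def test_supraventricular_partial_pause(self):
        cfg = sim.PatientSimConfig(duration_s=120.0, p_ectopic=0.05, es_type_mix=0.0,
                                   rr_sd_ms=0.0, resp_rr_mod_ms=0.0)
        _, hemo, _ = sim.simulate_patient_waveforms(cfg, seed=3)
        rr_nom = cfg.rr_nominal_ms
        for i in hemo.index[hemo["label"] == "ectopic"]:
            coupling = hemo["rr_prev_ms"].iloc[i]
            post_rr = hemo["rr_prev_ms"].iloc[i + 1]
            assert post_rr > rr_nom  # some pause
            assert coupling + post_rr < 2 * rr_nom  # but not a full one

    def test_physiologic_bounds(self, sim_patient):
        _, rec, hemo, _ = sim_patient
        assert rec.abp.min() > 20 and rec.abp.max() < 300
        assert (hemo["rr_prev_ms"].dropna() > 0).all()
        assert (hemo["sv_ml"] > 0).all()

    def test_seeded_determinism(self):
        cfg = sim.PatientSimConfig(duration_s=30.0)
        a = sim.simulate_patient_waveforms(cfg, seed=9)
        b = sim.simulate_patient_waveforms(cfg, seed=9)
        np.testing.assert_array_equal(a[0].ecg, b[0].ecg)
        np.testing.assert_array_equal(a[0].abp, b[0].abp)
        assert a[1].equals(b[1])

    def test_rr_below_300ms_rejected(self):
        with pytest.raises(ValueError, match="300 ms"):
            sim.PatientSimConfig(hr_bpm=190.0)
        with pytest.raises(ValueError, match="coupling_range"):
            sim.PatientSimConfig(coupling_range=(0.5, 0.9))

    def test_responder_vs_nonresponder_sv_response(self):
        r = sim.simulate_patient_waveforms(
            sim.responder_config(duration_s=60.0, sv_noise_ml=0.5), seed=4)[2]
        n = sim.simulate_patient_waveforms(
            sim.nonresponder_config(duration_s=60.0, sv_noise_ml=0.5), seed=4)[2]
        assert sv_response(r) >= 10.0
        assert sv_response(n) < 10.0

    def test_long_record_ectopic_count_and_recovery(self):
        # ~22 expected ectopics in 30 min at 72 bpm with p_ectopic 0.01
        cfg = sim.PatientSimConfig(duration_s=1800.0, hr_bpm=72.0, p_ectopic=0.01)
        rec, hemo, _ = sim.simulate_patient_waveforms(cfg, seed=13)
        n_ect = int((hemo["label"] == "ectopic").sum())
        assert 10 <= n_ect <= 35
        beats = classify_beats(detect_r_peaks(resample_to_1khz(rec)))
        eligible = find_eligible_ectopics(beats)
        gt = sim.ground_truth_deltas(hemo)
        # every ground-truth-eligible ectopic with coupling clearly <= 0.8
        # is recovered within 10 ms by the pipeline
        det_times = np.array([e.ectopic.r_time_s for e in eligible])
        clear = hemo[(hemo["label"] == "ectopic") & (hemo["coupling_frac"] < 0.78)]
        recovered = [np.any(np.abs(det_times - t) < 0.01) for t in clear["time_s"]]
        assert np.mean(recovered) >= 0.9
        assert len(gt) >= len(clear)


class TestCalibration:
    def test_slope_calibrated_to_target_delta(self):
        cfg = sim.responder_config(duration_s=300.0, p_ectopic=0.03)
        cal = sim.calibrate_starling_slope(cfg, target_delta_sbp_mmHg=6.0, seed=5)
        # operating SV preserved, target met on an independent seed
        assert sim.starling_sv(1.0, cal.starling) == pytest.approx(
            sim.starling_sv(1.0, cfg.starling), rel=1e-6)
        rng = np.random.default_rng(99)
        hemo = sim._hemodynamics(cal, sim._beat_schedule(cal, rng), rng)
        mean_d = sim.ground_truth_deltas(hemo)["delta_abs_sbp"].mean()
        assert mean_d == pytest.approx(6.0, abs=1.5)

    def test_unattainable_target_rejected(self):
        cfg = sim.responder_config(duration_s=120.0, p_ectopic=0.03)
        with pytest.raises(ValueError, match="outside attainable"):
            sim.calibrate_starling_slope(cfg, target_delta_sbp_mmHg=500.0, seed=1)
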