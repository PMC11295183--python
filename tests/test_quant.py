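"""Quantification pipeline: corrections, isotope dilution, UV calibration,
mass balance."""

import numpy as np
import pandas as pd
import pytest

from glycoflow.network import reference_model
from glycoflow.reactor import InflowProtocol, Trajectory, simulate_cstr
from glycoflow.quant import (CorrectionModel, build_correction_model,
                             calibrate_nadh_uv, correct_and_normalize,
                             estimate_baseline, estimate_fragmentation,
                             mass_balance_report, quantify)
from glycoflow.synth import (DEFAULT_STANDARDS_MM, ObservationConfig,
                             default_channels, generate_scans)

CFG = ObservationConfig(standards_mM=DEFAULT_STANDARDS_MM)
NOISELESS = CFG.with_(noise_sigma=0.0, baseline_counts=0.0, baseline_sd=0.0,
                      uv_noise_sd=0.0, fragmentation={})


def flat_traj(model, levels, tau_s=240.0, t_end=600.0):
    conc = np.zeros((2, 18))
    traj = Trajectory(times=np.array([0.0, t_end]), conc=conc,
                      species_ids=model.species_ids,
                      residence_time_s=np.full(2, tau_s))
    for sp, c in levels.items():
        traj.conc[:, model.species_index(sp)] = c
    return traj


def pure_standard_stream(model, species, cfg=CFG, conc=0.5, seed=3):
    traj = flat_traj(model, {species: conc} if species else {})
    return generate_scans(traj, cfg.with_(standards_mM={}),
                          default_channels("full_glucose"), seed=seed)


class TestFragmentationEstimate:
    def test_recovers_configured_yield(self, model):
        cfg = CFG.with_(fragmentation={("FBP", "F6P"): 0.15})
        stream = pure_standard_stream(model, "FBP", cfg)
        phi = estimate_fragmentation(stream, "FBP", "F6P")
        assert phi == pytest.approx(0.15, abs=0.01)

    def test_zero_yield_estimates_near_zero(self, model):
        cfg = CFG.with_(fragmentation={})
        stream = pure_standard_stream(model, "FBP", cfg)
        phi = estimate_fragmentation(stream, "FBP", "F6P")
        assert phi < 0.01

    def test_refuses_impure_stream(self, model):
        cfg = CFG.with_(fragmentation={})
        traj = flat_traj(reference_model(), {"FBP": 0.5, "G": 0.5})
        stream = generate_scans(traj, cfg.with_(standards_mM={}),
                                default_channels("full_glucose"), seed=3)
        with pytest.raises(ValueError, match="not a pure"):
            estimate_fragmentation(stream, "FBP", "F6P")

    def test_refuses_parent_below_floor(self, model):
        stream = pure_standard_stream(model, None)
        with pytest.raises(ValueError, match="below detection floor"):
            estimate_fragmentation(stream, "FBP", "F6P")


class TestCorrectAndNormalize:
    def test_exact_cancellation_noiseless(self, model):
        """With the estimator handed the generator's own yield and no noise,
        the corrected F6P channel equals its fragmentation-free value."""
        levels = {"FBP": 0.5, "F6P": 0.2}
        chans = default_channels("full_glucose")
        with_frag = NOISELESS.with_(fragmentation={("FBP", "F6P"): 0.15})
        s_frag = generate_scans(flat_traj(model, levels), with_frag, chans,
                                seed=1)
        s_clean = generate_scans(flat_traj(model, levels), NOISELESS, chans,
                                 seed=1)
        corr = CorrectionModel(phi={("FBP", "F6P"): 0.15})
        c_frag = correct_and_normalize(s_frag, corr)
        c_clean = correct_and_normalize(s_clean, CorrectionModel())
        # TICs differ slightly (the leak adds counts), so compare ratios
        r1 = c_frag.norm["F6P[a]"] / c_frag.norm["FBP[a]"]
        r2 = c_clean.norm["F6P[a]"] / c_clean.norm["FBP[a]"]
        np.testing.assert_allclose(r1, r2, rtol=1e-9)

    def test_nadh_unchanged_without_nad(self, model):
        levels = {"NADH": 0.3}
        chans = default_channels("full_glucose")
        stream = generate_scans(flat_traj(model, levels), NOISELESS, chans,
                                seed=1)
        corr = build_correction_model({})
        out = correct_and_normalize(stream, corr)
        expected = stream.intensities["NADH[a]"].to_numpy() / stream.tic
        np.testing.assert_allclose(out.norm["NADH[a]"], expected, rtol=1e-12)

    def test_zero_tic_scan_dropped(self, model):
        chans = default_channels("full_glucose")
        stream = generate_scans(flat_traj(model, {"G": 1.0}), NOISELESS,
                                chans, seed=1)
        stream.tic[3] = 0.0
        out = correct_and_normalize(stream, CorrectionModel())
        assert out.dropped_scans == 1
        assert out.times.size == stream.times.size - 1

    def test_negative_corrections_floored_and_flagged(self, model):
        chans = default_channels("full_glucose")
        stream = generate_scans(flat_traj(model, {"FBP": 0.5}), NOISELESS,
                                chans, seed=1)
        corr = CorrectionModel(phi={("FBP", "F6P"): 0.5})   # overcorrect
        out = correct_and_normalize(stream, corr)
        assert np.all(out.norm["F6P[a]"] >= 0.0)
        assert out.floored["F6P[a]"].any()


class TestQuantify:
    def test_unit_ratio_identity(self, model):
        """Equal analyte/standard intensities at Q_d = Q_r give C = C_std."""
        levels = {"G": DEFAULT_STANDARDS_MM["G"] * 1.0}
        cfg = NOISELESS.with_(q_dilution_ul_min=25.0)   # Q_r = 25 too
        chans = default_channels("full_glucose")
        stream = generate_scans(flat_traj(model, levels), cfg, chans, seed=1)
        out = correct_and_normalize(stream, CorrectionModel())
        series = quantify(out, cfg.standards_mM, cfg.q_dilution_ul_min)
        assert series.conc["G"].iloc[2] == pytest.approx(
            DEFAULT_STANDARDS_MM["G"], rel=1e-9)

    def test_noiseless_roundtrip_below_tenth_percent(self, model, ref_params,
                                                     full_loadings,
                                                     subsystem_step_protocol):
        traj = simulate_cstr(model, ref_params, full_loadings,
                             subsystem_step_protocol)
        chans = default_channels("full_glucose")
        stream = generate_scans(traj, NOISELESS, chans, seed=1)
        out = correct_and_normalize(stream, CorrectionModel())
        series = quantify(out, NOISELESS.standards_mM,
                          NOISELESS.q_dilution_ul_min)
        truth = traj.interp(series.bin_time_s - NOISELESS.dead_time_s)
        for sp in ("G", "G6P", "FBP", "PYR"):
            tr = truth[:, model.species_index(sp)]
            est = series.conc[sp].to_numpy()
            ok = (~series.masked[sp].to_numpy()) & (tr > 0.05)
            if ok.sum() < 5:
                continue
            rel = np.abs(est[ok] - tr[ok]) / tr[ok]
            assert np.median(rel) < 1e-3, sp

    def test_species_without_standard_is_monitor_only(self, model):
        stream = generate_scans(flat_traj(model, {"G": 1.0, "PGL6": 0.5}),
                                NOISELESS, default_channels("full_glucose"),
                                seed=1)
        out = correct_and_normalize(stream, CorrectionModel())
        series = quantify(out, NOISELESS.standards_mM,
                          NOISELESS.q_dilution_ul_min)
        assert "PGL6" not in series.conc.columns
        assert "PGL6" in series.unquantified
        assert {"ADP", "NAD"} <= set(series.unquantified)

    def test_below_floor_masked(self, model):
        stream = generate_scans(flat_traj(model, {"G": 1.0, "PYR": 0.005}),
                                NOISELESS, default_channels("full_glucose"),
                                seed=1)
        out = correct_and_normalize(stream, CorrectionModel())
        series = quantify(out, NOISELESS.standards_mM,
                          NOISELESS.q_dilution_ul_min)
        assert series.masked["PYR"].all()
        assert not series.masked["G"].any()

    def test_bin_then_average_equals_average_then_bin_for_constant(self,
                                                                   model):
        stream = generate_scans(flat_traj(model, {"G": 1.0}), NOISELESS,
                                default_channels("full_glucose"), seed=1)
        out = correct_and_normalize(stream, CorrectionModel())
        series = quantify(out, NOISELESS.standards_mM,
                          NOISELESS.q_dilution_ul_min)
        np.testing.assert_allclose(series.rolling["G"], series.conc["G"],
                                   rtol=1e-9)

    def test_global_gain_invariance(self, model, ref_params, full_loadings,
                                    subsystem_step_protocol):
        """Quantified concentrations are unchanged under a global detector
        gain factor (TIC-normalization property)."""
        traj = simulate_cstr(model, ref_params, full_loadings,
                             subsystem_step_protocol,
                             t_eval=np.arange(0.0, 1800.0, 5.0))
        chans = default_channels("full_glucose")
        base = CFG.with_(baseline_counts=0.0, baseline_sd=0.0)
        a = generate_scans(traj, base, chans, seed=6)
        b = generate_scans(traj, base.with_(global_gain=3.0), chans, seed=6)
        qa = quantify(correct_and_normalize(a, CorrectionModel(
            phi={("FBP", "F6P"): 0.15, ("G", "LAC"): 0.05})),
            CFG.standards_mM, CFG.q_dilution_ul_min)
        qb = quantify(correct_and_normalize(b, CorrectionModel(
            phi={("FBP", "F6P"): 0.15, ("G", "LAC"): 0.05})),
            CFG.standards_mM, CFG.q_dilution_ul_min)
        pd.testing.assert_frame_equal(qa.conc, qb.conc, rtol=1e-9)


class TestCorrectionBias:
    def test_corrections_remove_configured_bias(self, model, ref_params,
                                                full_loadings,
                                                subsystem_step_protocol):
        """Turning corrections off while the generator applies them biases
        F6P by about phi times the FBP/F6P signal ratio; on/on removes it."""
        traj = simulate_cstr(model, ref_params, full_loadings,
                             subsystem_step_protocol)
        chans = default_channels("full_glucose")
        stream = generate_scans(traj, CFG, chans, seed=2)
        phi_true = CFG.fragmentation[("FBP", "F6P")]
        base = estimate_baseline(pure_standard_stream(model, None, CFG,
                                                      seed=8))
        on = build_correction_model({("FBP", "F6P"): phi_true,
                                     ("G", "LAC"): 0.05},
                                    baseline_counts=base)
        off = build_correction_model({}, baseline_counts=base,
                                     overlap_pairs=())
        q_on = quantify(correct_and_normalize(stream, on),
                        CFG.standards_mM, CFG.q_dilution_ul_min)
        q_off = quantify(correct_and_normalize(stream, off),
                         CFG.standards_mM, CFG.q_dilution_ul_min)
        truth = traj.interp(q_on.bin_time_s - CFG.dead_time_s)
        tr = truth[:, model.species_index("F6P")]
        ok = tr > 0.05
        bias_on = np.median((q_on.conc["F6P"].to_numpy()[ok] - tr[ok])
                            / tr[ok])
        bias_off = np.median((q_off.conc["F6P"].to_numpy()[ok] - tr[ok])
                             / tr[ok])
        fbp = truth[:, model.species_index("FBP")]
        expected_bias = phi_true * np.median(fbp[ok] / tr[ok])
        assert abs(bias_on) < 0.02
        assert bias_off == pytest.approx(expected_bias, rel=0.35)
        assert bias_off > 5 * abs(bias_on)


class TestNadhUv:
    def _corrected(self, model, protocol, ref_params, loadings, cfg, seed=5):
        traj = simulate_cstr(model, ref_params, loadings, protocol)
        stream = generate_scans(traj, cfg,
                                default_channels("subsystem_glucose"),
                                seed=seed)
        # the correction model includes the NAD M+2 -> NADH overlap
        return traj, correct_and_normalize(stream, build_correction_model({}))

    def test_noiseless_slope_identity(self, model, ref_params, sub_loadings,
                                      subsystem_step_protocol):
        _, out = self._corrected(model, subsystem_step_protocol, ref_params,
                                 sub_loadings, NOISELESS)
        series = quantify(out, NOISELESS.standards_mM,
                          NOISELESS.q_dilution_ul_min)
        slope = calibrate_nadh_uv(
            out, series, uv_epsilon_l=NOISELESS.uv_epsilon_l,
            q_dilution_ul_min=NOISELESS.q_dilution_ul_min)
        # with TIC and dilution divided out, the slope is 1/response-factor
        assert slope == pytest.approx(
            1.0 / NOISELESS.default_response_factor, rel=1e-3)

    def test_noisy_recovery_within_five_percent(self, model, ref_params,
                                                sub_loadings,
                                                subsystem_step_protocol):
        traj, out = self._corrected(model, subsystem_step_protocol,
                                    ref_params, sub_loadings, CFG)
        series = quantify(out, CFG.standards_mM, CFG.q_dilution_ul_min)
        calibrate_nadh_uv(out, series, uv_epsilon_l=CFG.uv_epsilon_l,
                          q_dilution_ul_min=CFG.q_dilution_ul_min)
        truth = traj.interp(series.bin_time_s - CFG.dead_time_s)
        tr = truth[:, model.species_index("NADH")]
        est = series.conc["NADH"].to_numpy()
        ok = tr > 0.05
        rms = np.sqrt(np.mean(((est[ok] - tr[ok]) / tr[ok]) ** 2))
        assert rms < 0.05

    def test_flat_uv_refused(self, model):
        stream = generate_scans(flat_traj(model, {"G": 1.0}), CFG,
                                default_channels("subsystem_glucose"),
                                seed=1)
        out = correct_and_normalize(stream, CorrectionModel())
        series = quantify(out, CFG.standards_mM, CFG.q_dilution_ul_min)
        with pytest.raises(ValueError, match="flat|noise"):
            calibrate_nadh_uv(out, series, uv_epsilon_l=CFG.uv_epsilon_l)


class TestMassBalance:
    def test_subsystem_balance_near_unity(self, model, ref_params,
                                          sub_loadings,
                                          subsystem_step_protocol):
        traj = simulate_cstr(model, ref_params, sub_loadings,
                             subsystem_step_protocol)
        stream = generate_scans(traj, NOISELESS,
                                default_channels("subsystem_glucose"),
                                seed=1)
        out = correct_and_normalize(stream, CorrectionModel())
        series = quantify(out, NOISELESS.standards_mM,
                          NOISELESS.q_dilution_ul_min)
        calibrate_nadh_uv(out, series, uv_epsilon_l=NOISELESS.uv_epsilon_l,
                          q_dilution_ul_min=NOISELESS.q_dilution_ul_min)
        mb = mass_balance_report(series, subsystem_step_protocol,
                                 model=model,
                                 dead_time_s=NOISELESS.dead_time_s)
        # steady stretches: skip the first bins after each step
        ratio = mb["balance_ratio"].to_numpy()
        steady = ratio[np.isfinite(ratio)][-10:]
        np.testing.assert_allclose(steady, 1.0, atol=0.01)

    def test_unobserved_pools_push_ratio_below_one(self, model, ref_params,
                                                   full_loadings,
                                                   subsystem_step_protocol):
        """With the full network running, unquantified 6PGL/XAP pools make
        the summed observables fall short of the feed."""
        traj = simulate_cstr(model, ref_params, full_loadings,
                             subsystem_step_protocol)
        stream = generate_scans(traj, NOISELESS,
                                default_channels("full_glucose"), seed=1)
        out = correct_and_normalize(stream, CorrectionModel())
        series = quantify(out, NOISELESS.standards_mM,
                          NOISELESS.q_dilution_ul_min)
        mb = mass_balance_report(series, subsystem_step_protocol,
                                 model=model, nadh_as_pgl6=False,
                                 dead_time_s=NOISELESS.dead_time_s)
        ratio = mb["balance_ratio"].to_numpy()
        assert np.nanmedian(ratio) < 0.95

    def test_zero_feed_ratio_is_masked(self, model):
        stream = generate_scans(flat_traj(model, {"ATP": 1.0}), NOISELESS,
                                default_channels("full_glucose"), seed=1)
        out = correct_and_normalize(stream, CorrectionModel())
        series = quantify(out, NOISELESS.standards_mM,
                          NOISELESS.q_dilution_ul_min)
        prot = InflowProtocol(
            segments=((0.0, {"buf": 25.0}),), stocks={"buf": {}},
            duration_s=700.0)
        mb = mass_balance_report(series, prot, model=model)
        assert np.all(np.isnan(mb["balance_ratio"]))
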