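"""Loss, multistart fitting, ensembles and prediction bands."""

import numpy as np
import pandas as pd
import pytest

from glycoflow.fitting import (FitResult, default_bounds, fit,
                               laplace_ensemble, loss, predict)
from glycoflow.network import parameters_for_reactions
from glycoflow.quant import QuantSeries
from glycoflow.reactor import InflowProtocol, simulate_cstr

DEAD = 60.0


@pytest.fixture(scope="module")
def short_protocol():
    segments = ((0.0, {"G": 3.0, "ATP": 4.0, "NAD": 2.0, "buf": 15.0}),
                (900.0, {"G": 5.0, "ATP": 2.0, "NAD": 2.0, "buf": 15.0}))
    return InflowProtocol(
        segments=segments,
        stocks={"G": {"G": 40.0}, "ATP": {"ATP": 40.0},
                "NAD": {"NAD": 20.0}, "buf": {}},
        duration_s=1800.0, equilibration_s=3600.0)


def quant_from_simulation(model, params, loadings, protocol, species,
                          noise_sd=0.0, seed=0):
    """Noise-free (or Gaussian-noised) QuantSeries straight from the ODE."""
    bins = np.arange(22.5, protocol.duration_s, 45.0) + DEAD
    traj = simulate_cstr(model, params, loadings, protocol,
                         t_eval=np.clip(bins - DEAD, 0, None))
    sim = traj.interp(bins - DEAD)
    rng = np.random.default_rng(seed)
    cols = {}
    for sp in species:
        y = sim[:, model.species_index(sp)].copy()
        if noise_sd:
            y = y * np.exp(rng.normal(0.0, noise_sd, y.size))
        cols[sp] = y
    conc = pd.DataFrame(cols)
    masked = pd.DataFrame(False, index=conc.index, columns=conc.columns)
    return QuantSeries(bin_time_s=bins, conc=conc,
                       rolling=conc.copy(), masked=masked)


SPECIES = ("G", "G6P", "F6P", "ATP", "NADH")


class TestLoss:
    def test_zero_at_generating_parameters(self, model, ref_params,
                                           sub_loadings, short_protocol):
        data = quant_from_simulation(model, ref_params, sub_loadings,
                                     short_protocol, SPECIES)
        scalar, rmse = loss(model, ref_params, sub_loadings, short_protocol,
                            data, dead_time_s=DEAD, species=SPECIES)
        assert scalar < 1e-4
        assert all(v < 1e-5 for v in rmse.values())

    def test_constant_offset_gives_rmse_delta(self, model, ref_params,
                                              sub_loadings, short_protocol):
        data = quant_from_simulation(model, ref_params, sub_loadings,
                                     short_protocol, SPECIES)
        data.conc["G6P"] += 0.25
        _, rmse = loss(model, ref_params, sub_loadings, short_protocol,
                       data, dead_time_s=DEAD, species=SPECIES)
        assert rmse["G6P"] == pytest.approx(0.25, rel=1e-3)

    def test_kcat_perturbation_increases_loss(self, model, ref_params,
                                              sub_loadings, short_protocol):
        data = quant_from_simulation(model, ref_params, sub_loadings,
                                     short_protocol, SPECIES)
        perturbed = dict(ref_params)
        perturbed["HK_G.kcat"] *= 2.0
        base, _ = loss(model, ref_params, sub_loadings, short_protocol,
                       data, dead_time_s=DEAD, species=SPECIES)
        worse, _ = loss(model, perturbed, sub_loadings, short_protocol,
                        data, dead_time_s=DEAD, species=SPECIES)
        assert worse > base + 0.01

    def test_invariant_to_species_ordering(self, model, ref_params,
                                           sub_loadings, short_protocol):
        data = quant_from_simulation(model, ref_params, sub_loadings,
                                     short_protocol, SPECIES, noise_sd=0.05)
        a, _ = loss(model, ref_params, sub_loadings, short_protocol, data,
                    dead_time_s=DEAD, species=SPECIES)
        b, _ = loss(model, ref_params, sub_loadings, short_protocol, data,
                    dead_time_s=DEAD, species=tuple(reversed(SPECIES)))
        assert a == pytest.approx(b, rel=1e-12)

    def test_all_masked_species_excluded(self, model, ref_params,
                                         sub_loadings, short_protocol):
        data = quant_from_simulation(model, ref_params, sub_loadings,
                                     short_protocol, SPECIES)
        data.masked["F6P"] = True
        _, rmse = loss(model, ref_params, sub_loadings, short_protocol,
                       data, dead_time_s=DEAD, species=SPECIES)
        assert "F6P" not in rmse


class TestFit:
    def test_zero_starts_rejected(self, model, ref_params, sub_loadings,
                                  short_protocol):
        data = quant_from_simulation(model, ref_params, sub_loadings,
                                     short_protocol, SPECIES)
        with pytest.raises(ValueError):
            fit(model, short_protocol, sub_loadings, data, ("HK_G.kcat",),
                fixed_params=ref_params, n_starts=0)

    def test_truth_start_on_noiseless_data_stays_at_truth(
            self, model, ref_params, sub_loadings, short_protocol):
        names = parameters_for_reactions(model, ("HK_G",))
        data = quant_from_simulation(model, ref_params, sub_loadings,
                                     short_protocol, SPECIES)
        fixed = {k: v for k, v in ref_params.items() if k not in names}
        res = fit(model, short_protocol, sub_loadings, data, names,
                  fixed_params=fixed, n_starts=1, seed=0,
                  dead_time_s=DEAD, species=SPECIES,
                  include_truth_start=ref_params, max_nfev=60)
        for n in names:
            assert res.best[n] == pytest.approx(ref_params[n], rel=1e-3)

    def test_deterministic_given_seed(self, model, ref_params, sub_loadings,
                                      short_protocol):
        names = parameters_for_reactions(model, ("HK_G",))
        data = quant_from_simulation(model, ref_params, sub_loadings,
                                     short_protocol, SPECIES, noise_sd=0.05)
        fixed = {k: v for k, v in ref_params.items() if k not in names}
        kw = dict(fixed_params=fixed, n_starts=2, seed=7, dead_time_s=DEAD,
                  species=SPECIES, max_nfev=25)
        a = fit(model, short_protocol, sub_loadings, data, names, **kw)
        b = fit(model, short_protocol, sub_loadings, data, names, **kw)
        np.testing.assert_array_equal(a.ensemble, b.ensemble)
        np.testing.assert_array_equal(a.losses, b.losses)

    def test_noise_degrades_recovery_monotonically(self, model, ref_params,
                                                   sub_loadings,
                                                   short_protocol):
        """Median recovered-parameter error grows with observation noise."""
        names = parameters_for_reactions(model, ("HK_G",))
        fixed = {k: v for k, v in ref_params.items() if k not in names}
        errs = []
        for sigma in (0.0, 0.04, 0.08, 0.16):
            per_rep = []
            for rep in (0, 1):
                data = quant_from_simulation(model, ref_params, sub_loadings,
                                             short_protocol, SPECIES,
                                             noise_sd=sigma, seed=10 + rep)
                res = fit(model, short_protocol, sub_loadings, data, names,
                          fixed_params=fixed, n_starts=1, seed=0,
                          dead_time_s=DEAD, species=SPECIES,
                          include_truth_start=ref_params, max_nfev=40)
                per_rep.append(np.median([abs(np.log(res.best[n]
                                                     / ref_params[n]))
                                          for n in names]))
            errs.append(float(np.mean(per_rep)))
        assert errs == sorted(errs)
        assert errs[0] < 1e-4 < errs[-1]


class TestPredict:
    def _fitresult(self, names, members, ref_params):
        fixed = {k: v for k, v in ref_params.items() if k not in names}
        arr = np.array([[m[n] for n in names] for m in members])
        return FitResult(param_names=tuple(names), ensemble=arr,
                         losses=np.zeros(len(members)), top_k=len(members),
                         per_species_rmse={}, seed=0, fixed_params=fixed)

    def test_identical_members_give_zero_width_bands(self, model,
                                                     ref_params,
                                                     sub_loadings,
                                                     short_protocol):
        names = parameters_for_reactions(model, ("HK_G",))
        fr = self._fitresult(names, [ref_params] * 3, ref_params)
        band = predict(fr, model, short_protocol, sub_loadings,
                       t_eval=np.arange(0.0, 1800.0, 90.0), species=SPECIES)
        assert np.max(band.sd) < 1e-12
        lo, hi = band.band("G", 2.0)
        np.testing.assert_allclose(lo, hi, atol=1e-11)

    def test_empty_ensemble_rejected(self, model, ref_params, sub_loadings,
                                     short_protocol):
        names = parameters_for_reactions(model, ("HK_G",))
        fr = self._fitresult(names, [ref_params], ref_params)
        fr.ensemble = np.empty((0, len(names)))
        with pytest.raises(ValueError):
            predict(fr, model, short_protocol, sub_loadings)

    def test_unidentified_low_species_predicted_below_floor(
            self, model, ref_params, full_loadings, short_protocol):
        """Species the instrument cannot see (BPG, 2/3-PG, PEP) sit below
        the ~20 uM floor in both truth and prediction."""
        names = parameters_for_reactions(model, ("HK_G",))
        fr = self._fitresult(names, [ref_params] * 2, ref_params)
        grid = np.arange(0.0, 1800.0, 90.0)
        band = predict(fr, model, short_protocol, full_loadings,
                       t_eval=grid, species=("BPG", "PG3", "PG2", "PEP"))
        truth = simulate_cstr(model, ref_params, full_loadings,
                              short_protocol, t_eval=grid)
        for j, sp in enumerate(band.species):
            if np.all(truth[sp] < 0.02):
                assert np.all(band.mean[:, j] < 0.02)


class TestLaplaceEnsemble:
    def test_band_widens_and_stays_sorted(self, model, ref_params,
                                          sub_loadings, short_protocol):
        names = parameters_for_reactions(model, ("HK_G",))
        data = quant_from_simulation(model, ref_params, sub_loadings,
                                     short_protocol, SPECIES, noise_sd=0.05)
        fixed = {k: v for k, v in ref_params.items() if k not in names}
        base = fit(model, short_protocol, sub_loadings, data, names,
                   fixed_params=fixed, n_starts=1, seed=0,
                   dead_time_s=DEAD, species=SPECIES,
                   include_truth_start=ref_params, max_nfev=40)
        le = laplace_ensemble(base, model, short_protocol, sub_loadings,
                              data, n_samples=15, seed=1, species=SPECIES)
        assert le.ensemble.shape[0] == 16
        assert np.all(np.diff(le.losses) >= 0)
        grid = np.arange(0.0, 1800.0, 90.0)
        band = predict(le, model, short_protocol, sub_loadings,
                       t_eval=grid, species=("G6P",))
        assert band.sd.max() > 0.0


def test_default_bounds_cover_all_classes(model):
    bounds = default_bounds(model.parameter_names)
    assert set(bounds) == set(model.parameter_names)
    assert all(lo > 0 and hi > lo for lo, hi in bounds.values())
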