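"""Ensemble parameter estimation from quantified time series.

Kinetic parameters are fitted in log space by bounded multistart local
least squares (scipy trust-region reflective), started from log-uniform
draws within the per-class bounds.  The objective stacks, over species
and unmasked bins, the residual between simulated and quantified
concentrations divided by that species' data standard deviation, so the
scalar loss is commensurate across species with very different
concentration scales; raw per-species RMSE is reported alongside.

The ensemble of all multistart solutions, ordered by loss, supports
prediction with uncertainty: simulating the fittest-k subset (default 10
of 100) on a new protocol gives a mean trajectory with 1-SD and 2-SD
envelopes.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .network import (NetworkModel, PARAMETER_BOUNDS, parameter_class)
from .quant import QuantSeries
from .reactor import InflowProtocol, simulate_cstr

__all__ = [
    "FitResult",
    "PredictionBand",
    "loss",
    "fit",
    "predict",
    "laplace_ensemble",
    "default_bounds",
]


def default_bounds(param_names: Sequence[str]
                   ) -> dict[str, tuple[float, float]]:
    """Per-parameter (lo, hi) bounds from the parameter-class table."""
    return {name: PARAMETER_BOUNDS[parameter_class(name)]
            for name in param_names}


@dataclass
class FitResult:
    """Multistart ensemble, losses ascending, fittest-k subset."""

    param_names: tuple[str, ...]
    ensemble: np.ndarray              # (n_starts, P), sorted by loss
    losses: np.ndarray                # ascending
    top_k: int
    per_species_rmse: dict[str, float]   # for the best member
    seed: int
    fixed_params: dict[str, float] = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.losses) < 0):
            raise ValueError("losses must be sorted ascending")
        if not 1 <= self.top_k <= len(self.losses):
            raise ValueError("top_k must lie within the ensemble")

    @property
    def best(self) -> dict[str, float]:
        return self.member(0)

    def member(self, i: int) -> dict[str, float]:
        p = dict(self.fixed_params)
        p.update(zip(self.param_names, self.ensemble[i]))
        return p

    def fittest(self) -> list[dict[str, float]]:
        return [self.member(i) for i in range(self.top_k)]

    def to_dict(self) -> dict:
        return {
            "param_names": list(self.param_names),
            "ensemble": self.ensemble.tolist(),
            "losses": self.losses.tolist(),
            "top_k": self.top_k,
            "per_species_rmse": dict(self.per_species_rmse),
            "seed": self.seed,
            "fixed_params": dict(self.fixed_params),
        }


@dataclass
class PredictionBand:
    """Per-species ensemble mean with 1-SD and 2-SD envelopes."""

    times: np.ndarray
    species: tuple[str, ...]
    mean: np.ndarray                  # (time, species)
    sd: np.ndarray

    def band(self, sp: str, k: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
        j = self.species.index(sp)
        lo = np.maximum(self.mean[:, j] - k * self.sd[:, j], 0.0)
        return lo, self.mean[:, j] + k * self.sd[:, j]

    def coverage(self, sp: str, truth: np.ndarray, k: float = 2.0) -> float:
        lo, hi = self.band(sp, k)
        return float(np.mean((truth >= lo) & (truth <= hi)))


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def _residual_blocks(model: NetworkModel, params: Mapping[str, float],
                     loadings: Mapping[str, float],
                     protocol: InflowProtocol, data: QuantSeries,
                     dead_time_s: float, rtol: float, species: Sequence[str]
                     ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-species (data, simulated) value pairs on unmasked bins."""
    t_sim = np.clip(data.bin_time_s - dead_time_s, 0.0, protocol.duration_s)
    traj = simulate_cstr(model, params, loadings, protocol,
                         t_eval=np.unique(t_sim), rtol=rtol,
                         atol=max(1e-10, rtol * 1e-2))
    sim = traj.interp(t_sim)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for sp in species:
        mask = ~data.masked[sp].to_numpy()
        if not mask.any():
            continue
        y = data.conc[sp].to_numpy()[mask]
        s = sim[mask, model.species_index(sp)]
        out[sp] = (y, s)
    return out


def loss(model: NetworkModel, params: Mapping[str, float],
         loadings: Mapping[str, float], protocol: InflowProtocol,
         data: QuantSeries, *, dead_time_s: float = 60.0,
         rtol: float = 1e-6, species: Sequence[str] | None = None
         ) -> tuple[float, dict[str, float]]:
    """Scalar loss and per-species RMSE of a parameter set against data.

    Per-species RMSE is computed over unmasked bins; the scalar loss is
    the mean of per-species RMSE each normalized by that species' data
    standard deviation.  Species masked everywhere are excluded.
    """
    species = tuple(species or data.species)
    blocks = _residual_blocks(model, params, loadings, protocol, data,
                              dead_time_s, rtol, species)
    rmse: dict[str, float] = {}
    scaled: list[float] = []
    for sp, (y, s) in blocks.items():
        r = float(np.sqrt(np.mean((y - s) ** 2)))
        rmse[sp] = r
        sd = float(np.std(y))
        scaled.append(r / sd if sd > 0 else r)
    if not scaled:
        raise ValueError("no unmasked data in any species")
    return float(np.mean(scaled)), rmse


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _make_objective(model, protocol, loadings, data, param_names, fixed,
                    species, dead_time_s, rtol):
    """Residual function on log-parameters (noise-normalized, stacked)."""
    sd_map = {sp: max(float(np.std(
        data.conc[sp].to_numpy()[~data.masked[sp].to_numpy()])), 1e-9)
        for sp in species if (~data.masked[sp].to_numpy()).any()}
    n_resid = int(sum((~data.masked[sp].to_numpy()).sum() for sp in sd_map))

    def residuals(logx: np.ndarray) -> np.ndarray:
        params = dict(fixed)
        params.update(zip(param_names, np.exp(logx)))
        try:
            blocks = _residual_blocks(model, params, loadings, protocol,
                                      data, dead_time_s, rtol, species)
        except RuntimeError:
            return np.full(n_resid, 1e3)
        out = [(y - s) / sd_map[sp] for sp, (y, s) in blocks.items()]
        return np.concatenate(out) if out else np.full(n_resid, 1e3)

    return residuals, n_resid


def fit(model: NetworkModel, protocol: InflowProtocol,
        loadings: Mapping[str, float], data: QuantSeries,
        param_names: Sequence[str], *,
        fixed_params: Mapping[str, float] | None = None,
        bounds: Mapping[str, tuple[float, float]] | None = None,
        n_starts: int = 100, top_k: int = 10, seed: int = 0,
        dead_time_s: float = 60.0, rtol: float = 1e-6,
        max_nfev: int = 150, species: Sequence[str] | None = None,
        include_truth_start: Mapping[str, float] | None = None
        ) -> FitResult:
    """Multistart bounded least squares on log-parameters.

    ``param_names`` are the free parameters; all other model parameters
    must be supplied in ``fixed_params``.  Starts are log-uniform draws
    within bounds (``include_truth_start`` replaces the first start, for
    initialization-at-optimum checks).  Deterministic given ``seed``.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    top_k = min(top_k, n_starts)
    param_names = tuple(param_names)
    fixed = dict(fixed_params or {})
    bounds = dict(bounds or default_bounds(param_names))
    lo = np.log(np.array([bounds[p][0] for p in param_names]))
    hi = np.log(np.array([bounds[p][1] for p in param_names]))
    species = tuple(species or data.species)
    residuals, n_resid = _make_objective(model, protocol, loadings, data,
                                         param_names, fixed, species,
                                         dead_time_s, rtol)

    rng = np.random.default_rng(seed)
    starts = np.exp(rng.uniform(lo, hi, size=(n_starts, len(param_names))))
    if include_truth_start is not None:
        starts[0] = [include_truth_start[p] for p in param_names]

    sols: list[np.ndarray] = []
    losses: list[float] = []
    failures: list[str] = []
    for x0 in starts:
        try:
            res = least_squares(residuals, np.log(x0), bounds=(lo, hi),
                                method="trf", max_nfev=max_nfev,
                                x_scale="jac")
            sols.append(np.exp(res.x))
            losses.append(float(np.sqrt(2.0 * res.cost / max(res.fun.size, 1))))
        except Exception as exc:  # solver blow-up on a pathological start
            failures.append(str(exc))
    if not sols:
        raise RuntimeError(
            f"all {n_starts} starts failed; first error: {failures[0]}")

    order = np.argsort(losses)
    ensemble = np.array(sols)[order]
    losses_arr = np.array(losses)[order]
    best = dict(fixed)
    best.update(zip(param_names, ensemble[0]))
    _, rmse = loss(model, best, loadings, protocol, data,
                   dead_time_s=dead_time_s, rtol=rtol, species=species)
    return FitResult(param_names=param_names, ensemble=ensemble,
                     losses=losses_arr, top_k=min(top_k, len(sols)),
                     per_species_rmse=rmse, seed=seed, fixed_params=fixed,
                     diagnostics={"failures": failures})


def laplace_ensemble(fitres: FitResult, model: NetworkModel,
                     protocol: InflowProtocol,
                     loadings: Mapping[str, float], data: QuantSeries, *,
                     n_samples: int = 50, seed: int = 0,
                     bounds: Mapping[str, tuple[float, float]] | None = None,
                     dead_time_s: float = 60.0, rtol: float = 1e-6,
                     species: Sequence[str] | None = None,
                     fd_step: float = 1e-4) -> FitResult:
    """Expand a fit into a parameter-uncertainty ensemble (Laplace draws).

    Multistart members of a well-identified problem collapse onto one
    optimum, so their spread underestimates predictive uncertainty.  This
    builds the linearized (Gaussian) approximation of the parameter
    distribution at the best fit — covariance ``s^2 (J^T J)^-1`` in log
    space, with ``J`` the finite-difference residual Jacobian and ``s^2``
    the residual variance — draws ``n_samples`` parameter sets from it
    (clipped to bounds), and returns them as a new :class:`FitResult`
    sorted by loss, ready for :func:`predict`.
    """
    param_names = fitres.param_names
    fixed = dict(fitres.fixed_params)
    bounds = dict(bounds or default_bounds(param_names))
    species = tuple(species or data.species)
    residuals, n_resid = _make_objective(model, protocol, loadings, data,
                                         param_names, fixed, species,
                                         dead_time_s, rtol)
    x0 = np.log(fitres.ensemble[0])
    r0 = residuals(x0)
    J = np.empty((n_resid, len(param_names)))
    for j in range(len(param_names)):
        xp = x0.copy(); xp[j] += fd_step
        xm = x0.copy(); xm[j] -= fd_step
        J[:, j] = (residuals(xp) - residuals(xm)) / (2.0 * fd_step)
    dof = max(n_resid - len(param_names), 1)
    s2 = float(r0 @ r0) / dof
    cov = s2 * np.linalg.pinv(J.T @ J, rcond=1e-12)
    # symmetrize and factor robustly (pinv can leave tiny asymmetries)
    cov = 0.5 * (cov + cov.T)
    w, v = np.linalg.eigh(cov)
    root = v @ np.diag(np.sqrt(np.maximum(w, 0.0)))
    rng = np.random.default_rng(seed)
    draws = x0 + rng.standard_normal((n_samples, len(param_names))) @ root.T
    lo = np.log([bounds[p][0] for p in param_names])
    hi = np.log([bounds[p][1] for p in param_names])
    draws = np.clip(draws, lo, hi)
    members = np.vstack([x0, draws])
    losses = np.array([float(np.sqrt(np.mean(residuals(x) ** 2)))
                       for x in members])
    order = np.argsort(losses)
    return FitResult(param_names=param_names,
                     ensemble=np.exp(members[order]),
                     losses=losses[order], top_k=members.shape[0],
                     per_species_rmse=dict(fitres.per_species_rmse),
                     seed=seed, fixed_params=fixed,
                     diagnostics={"residual_variance": s2,
                                  "parent_seed": fitres.seed})


def predict(fitres: FitResult, model: NetworkModel,
            protocol: InflowProtocol, loadings: Mapping[str, float], *,
            t_eval: np.ndarray | None = None, use_top: bool = True,
            rtol: float = 1e-6, species: Sequence[str] | None = None
            ) -> PredictionBand:
    """Simulate ensemble members on a new protocol; mean and SD envelopes."""
    if fitres.ensemble.shape[0] == 0:
        raise ValueError("empty ensemble")
    members = fitres.fittest() if use_top else [
        fitres.member(i) for i in range(fitres.ensemble.shape[0])]
    species = tuple(species or model.species_ids)
    idx = [model.species_index(sp) for sp in species]
    sims = []
    for params in members:
        traj = simulate_cstr(model, params, loadings, protocol,
                             t_eval=t_eval, rtol=rtol,
                             atol=max(1e-10, rtol * 1e-2))
        sims.append(traj.conc[:, idx])
        times = traj.times
    arr = np.stack(sims)
    return PredictionBand(times=times, species=species,
                          mean=arr.mean(axis=0), sd=arr.std(axis=0))
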