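"""Optimal experimental design of inflow pulse protocols.

Candidate protocols switch syringe flow rates every 15 minutes (the
hardware's practical switching period) among a small set of discrete
levels per input — the four network inputs are ATP, glucose (or
fructose), NAD and ADP — while the total flow steps through a configured
number of residence-time regimes (default 4) across the experiment, a
carrier syringe making up the balance.

Candidates are scored by D-optimality on log-parameters: the Fisher
information matrix is assembled from finite-difference sensitivities of
the observed species' concentrations at the measurement bins,

    FIM = sum_t J_t^T W J_t,   J = d c_obs / d log theta,
    W = diag(noise sd)^-2,     score = log det(FIM + 1e-8 I),

where the small ridge regularizes structurally non-identifiable
directions (e.g. parameters of an enzyme with zero loading).  The search
is plain random sampling over the discrete design space, deterministic
per seed; the first candidate of a seeded stream doubles as the matched
"random protocol" control in utility comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .network import NetworkModel
from .reactor import InflowProtocol, simulate_cstr

__all__ = [
    "DesignSpace",
    "DesignResult",
    "information_score",
    "design",
    "sample_candidate",
]

RIDGE = 1e-8
FD_LOG_STEP = 1e-3


@dataclass(frozen=True)
class DesignSpace:
    """Discrete space of admissible pulse protocols.

    ``input_levels`` maps each input syringe to its allowed flow levels
    (uL/min, at most 4 plus the implicit option of keeping the previous
    level); ``stocks`` gives each syringe's reservoir composition.  The
    carrier syringe absorbs the difference between the summed input flows
    and the active total-flow regime, so every total-flow level must
    exceed the largest possible input sum.
    """

    input_levels: Mapping[str, Sequence[float]]
    stocks: Mapping[str, Mapping[str, float]]
    total_flow_levels: Sequence[float]           # one per regime, uL/min
    duration_s: float
    switching_period_s: float = 900.0
    n_regimes: int = 4
    carrier: str = "buf"
    volume_ul: float = 100.0
    equilibration_s: float = 7200.0

    def __post_init__(self) -> None:
        if self.duration_s % self.switching_period_s:
            raise ValueError("duration must be a multiple of the switching "
                             "period")
        if any(len(lv) == 0 or min(lv) < 0
               for lv in self.input_levels.values()):
            raise ValueError("input levels must be non-empty and >= 0")
        if any(len(lv) > 4 for lv in self.input_levels.values()):
            raise ValueError("at most 4 discrete levels per syringe")
        if len(self.total_flow_levels) < self.n_regimes:
            raise ValueError("need at least one total-flow level per regime")
        max_inputs = sum(max(lv) for lv in self.input_levels.values())
        if min(self.total_flow_levels) <= max_inputs:
            raise ValueError("total-flow levels must exceed the largest "
                             "possible summed input flow")
        object.__setattr__(self, "input_levels",
                           {k: tuple(v) for k, v in self.input_levels.items()})
        object.__setattr__(self, "stocks",
                           {k: dict(v) for k, v in self.stocks.items()})
        object.__setattr__(self, "total_flow_levels",
                           tuple(self.total_flow_levels))

    @property
    def n_slots(self) -> int:
        return int(self.duration_s / self.switching_period_s)


@dataclass
class DesignResult:
    protocol: InflowProtocol
    score: float
    all_scores: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        finite = self.all_scores[np.isfinite(self.all_scores)]
        if finite.size and self.score < finite.max() - 1e-9:
            raise ValueError("chosen protocol must carry the best score")


def sample_candidate(space: DesignSpace,
                     rng: np.random.Generator) -> InflowProtocol:
    """Draw one admissible protocol uniformly from the design space."""
    n = space.n_slots
    # contiguous equal blocks of total flow, regimes in random order
    regimes = rng.permutation(np.asarray(space.total_flow_levels,
                                         dtype=float)[: space.n_regimes])
    slot_total = np.repeat(regimes, int(np.ceil(n / space.n_regimes)))[:n]
    flows_per_slot: list[dict[str, float]] = []
    for k in range(n):
        flows = {syr: float(rng.choice(lv))
                 for syr, lv in space.input_levels.items()}
        flows[space.carrier] = float(slot_total[k]) - sum(flows.values())
        flows_per_slot.append(flows)
    segments = tuple((k * space.switching_period_s, flows_per_slot[k])
                     for k in range(n))
    return InflowProtocol(segments=segments, stocks=space.stocks,
                          duration_s=space.duration_s,
                          volume_ul=space.volume_ul,
                          equilibration_s=space.equilibration_s)


def information_score(protocol: InflowProtocol, model: NetworkModel,
                      params: Mapping[str, float],
                      loadings: Mapping[str, float],
                      observables: Sequence[str],
                      noise_sd: Mapping[str, float] | float, *,
                      scored_params: Sequence[str] | None = None,
                      bin_s: float = 45.0, dead_time_s: float = 60.0,
                      rtol: float = 1e-8, fd_step: float = FD_LOG_STEP,
                      ridge: float = RIDGE,
                      return_fim: bool = False):
    """D-optimality score (log det FIM) of a protocol at a parameter guess.

    Sensitivities of the observable concentrations with respect to log
    parameters are taken by central finite differences (step ``fd_step``
    in log space); measurements are assumed at every ``bin_s`` over the
    protocol with independent noise ``noise_sd`` per species.
    """
    scored = tuple(scored_params or model.parameter_names)
    obs_idx = [model.species_index(sp) for sp in observables]
    t_eval = np.arange(bin_s / 2, protocol.duration_s, bin_s)

    def sim(p: Mapping[str, float]) -> np.ndarray:
        traj = simulate_cstr(model, p, loadings, protocol, t_eval=t_eval,
                             rtol=rtol)
        return traj.conc[:, obs_idx]

    if isinstance(noise_sd, Mapping):
        w = np.array([1.0 / noise_sd[sp] for sp in observables])
    else:
        w = np.full(len(observables), 1.0 / float(noise_sd))

    cols = []
    for name in scored:
        p_hi = dict(params); p_hi[name] = params[name] * np.exp(fd_step)
        p_lo = dict(params); p_lo[name] = params[name] * np.exp(-fd_step)
        dc = (sim(p_hi) - sim(p_lo)) / (2.0 * fd_step)
        cols.append((dc * w).ravel())       # weighted sensitivity column
    J = np.column_stack(cols)
    if not np.all(np.isfinite(J)):
        raise FloatingPointError("non-finite sensitivities")
    fim = J.T @ J
    sign, logdet = np.linalg.slogdet(fim + ridge * np.eye(fim.shape[0]))
    if sign <= 0:  # pragma: no cover - ridge keeps the matrix PD
        raise FloatingPointError("FIM not positive definite")
    if return_fim:
        return float(logdet), fim
    return float(logdet)


def design(space: DesignSpace, model: NetworkModel,
           params: Mapping[str, float], loadings: Mapping[str, float],
           observables: Sequence[str],
           noise_sd: Mapping[str, float] | float, *,
           budget: int = 50, seed: int = 0,
           scored_params: Sequence[str] | None = None,
           bin_s: float = 45.0, rtol: float = 1e-8) -> DesignResult:
    """Random search for the most informative protocol in the space.

    Evaluates ``budget`` seeded candidates and returns the best by
    D-optimality together with the full score trace.  Candidates whose
    sensitivities fail to evaluate are recorded with score -inf.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    best: tuple[float, InflowProtocol] | None = None
    scores = np.full(budget, -np.inf)
    for i in range(budget):
        cand = sample_candidate(space, rng)
        try:
            s = information_score(cand, model, params, loadings,
                                  observables, noise_sd,
                                  scored_params=scored_params, bin_s=bin_s,
                                  rtol=rtol)
        except (FloatingPointError, RuntimeError):
            continue
        scores[i] = s
        if best is None or s > best[0]:
            best = (s, cand)
    if best is None:
        raise RuntimeError("no candidate could be scored")
    return DesignResult(protocol=best[1], score=best[0],
                        all_scores=scores, seed=seed)
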