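"""Experiment presets and the end-to-end pipeline.

Presets bundle the pieces of one monitoring experiment: the enzyme
loadings in the reactor, the inflow protocol (or a design space for the
optimally designed training run), the observation configuration and the
set of species the experiment quantifies.

* ``subsystem_glucose`` — 3-enzyme upper-glycolysis subsystem (HK, GPI,
  G6PDH), 8 input steps of glucose/ATP, quantifies G, G6P, F6P, ATP, NADH.
* ``full_glucose`` — full 12-enzyme network fed 13C6-glucose, a 4 x 4
  grid of glucose/ATP feeds = 16 distinct input steps, quantifies 8
  species (ATP, G, FBP, F6P, G6P, Lac, NADH, Pyr).
* ``full_fructose`` — as above from 13C6-fructose; lactate rides near the
  detection floor in this experiment and is flagged accordingly.
* ``oed_training`` — full network driven by an optimally designed pulse
  sequence of the four inputs (ATP, G, NAD, ADP), 15-min switching, total
  flow stepping through 4 residence-time regimes (2, 4, 8, 16 min).

``run_pipeline`` chains the stages — simulate, observe, estimate
corrections, quantify, optionally fit and predict — writing one artifact
per stage into a run directory; each stage reads only files the previous
stages wrote, so the CLI subcommands compose to the same result.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import quant as q_
from .network import (NetworkModel, reference_loadings, reference_model,
                      reference_parameters, subsystem_loadings,
                      parameters_for_enzymes)
from .oed import DesignSpace, design
from .quant import (build_correction_model, calibrate_nadh_uv,
                    correct_and_normalize, estimate_baseline,
                    estimate_fragmentation, mass_balance_report, quantify)
from .reactor import InflowProtocol, Trajectory, simulate_cstr
from .synth import (DEFAULT_STANDARDS_MM, ObservationConfig, ScanStream,
                    default_channels, generate_scans, quantified_species)

__all__ = [
    "ExperimentPreset",
    "get_preset",
    "available_presets",
    "run_pipeline",
    "derive_seeds",
]

TAU_REGIMES_MIN = (2.0, 4.0, 8.0, 16.0)


@dataclass(frozen=True)
class ExperimentPreset:
    name: str
    experiment_kind: str                   # channel-table preset key
    loadings: Mapping[str, float]
    protocol: InflowProtocol | None
    design_space: DesignSpace | None
    observation: ObservationConfig
    quantified: tuple[str, ...]
    near_floor: tuple[str, ...] = ()
    fit_enzymes: tuple[str, ...] = ()      # enzymes whose params a fit frees

    def __post_init__(self) -> None:
        channel_species = {c.species for c in
                           default_channels(self.experiment_kind)}
        missing = set(self.quantified) - channel_species
        if missing:
            raise ValueError(f"preset {self.name}: no channels for {missing}")
        if (self.protocol is None) == (self.design_space is None):
            raise ValueError("exactly one of protocol/design_space required")

    def channels(self, model: NetworkModel | None = None):
        return default_channels(self.experiment_kind, model)


def _grid_protocol(levels_a: Sequence[float], levels_b: Sequence[float],
                   syr_a: str, syr_b: str, fixed: Mapping[str, float],
                   stocks: Mapping[str, Mapping[str, float]],
                   total: float = 25.0, period_s: float = 900.0
                   ) -> InflowProtocol:
    """Step protocol scanning the full grid of two syringes' flow levels."""
    segments = []
    k = 0
    for qa in levels_a:
        for qb in levels_b:
            flows = {syr_a: qa, syr_b: qb, **fixed}
            flows["buf"] = total - sum(flows.values())
            if flows["buf"] < 0:
                raise ValueError("input flows exceed total flow")
            segments.append((k * period_s, flows))
            k += 1
    return InflowProtocol(segments=tuple(segments), stocks=stocks,
                          duration_s=k * period_s)


def _subsystem_glucose() -> ExperimentPreset:
    stocks = {"G": {"G": 40.0}, "ATP": {"ATP": 40.0}, "NAD": {"NAD": 20.0},
              "buf": {}}
    protocol = _grid_protocol((1.0, 2.0, 3.0, 4.0), (2.0, 4.0), "G", "ATP",
                              {"NAD": 2.0}, stocks)
    return ExperimentPreset(
        name="subsystem_glucose", experiment_kind="subsystem_glucose",
        loadings=subsystem_loadings(), protocol=protocol, design_space=None,
        observation=ObservationConfig(standards_mM=DEFAULT_STANDARDS_MM),
        quantified=quantified_species("subsystem_glucose"),
        fit_enzymes=("HK", "GPI", "G6PDH"))


def _full_hexose(hexose: str) -> ExperimentPreset:
    kind = "full_glucose" if hexose == "G" else "full_fructose"
    stocks = {hexose: {hexose: 40.0}, "ATP": {"ATP": 40.0},
              "NAD": {"NAD": 20.0}, "ADP": {"ADP": 20.0}, "buf": {}}
    protocol = _grid_protocol((1.0, 2.0, 3.0, 4.0), (1.0, 2.0, 3.0, 4.0),
                              hexose, "ATP", {"NAD": 2.0, "ADP": 2.0}, stocks)
    return ExperimentPreset(
        name=kind, experiment_kind=kind,
        loadings=reference_loadings(), protocol=protocol, design_space=None,
        observation=ObservationConfig(standards_mM=DEFAULT_STANDARDS_MM),
        quantified=quantified_species(kind),
        near_floor=("LAC",) if hexose == "F" else (),
        fit_enzymes=tuple(reference_loadings()))


def _oed_training() -> ExperimentPreset:
    totals = tuple(100.0 * 60.0 / (tau * 60.0) for tau in TAU_REGIMES_MIN)
    space = DesignSpace(
        input_levels={"ATP": (0.0, 0.4, 0.8, 1.2),
                      "G": (0.0, 0.4, 0.8, 1.2),
                      "NAD": (0.0, 0.4, 0.8),
                      "ADP": (0.0, 0.4, 0.8)},
        stocks={"ATP": {"ATP": 100.0}, "G": {"G": 100.0},
                "NAD": {"NAD": 50.0}, "ADP": {"ADP": 50.0}, "buf": {}},
        total_flow_levels=totals, duration_s=14400.0)
    return ExperimentPreset(
        name="oed_training", experiment_kind="full_glucose",
        loadings=reference_loadings(), protocol=None, design_space=space,
        observation=ObservationConfig(standards_mM=DEFAULT_STANDARDS_MM),
        quantified=quantified_species("full_glucose"),
        fit_enzymes=tuple(reference_loadings()))


def available_presets() -> tuple[str, ...]:
    return ("subsystem_glucose", "full_glucose", "full_fructose",
            "oed_training")


def get_preset(name: str) -> ExperimentPreset:
    if name == "subsystem_glucose":
        return _subsystem_glucose()
    if name == "full_glucose":
        return _full_hexose("G")
    if name == "full_fructose":
        return _full_hexose("F")
    if name == "oed_training":
        return _oed_training()
    raise ValueError(f"unknown preset {name!r}; "
                     f"choose from {available_presets()}")


def derive_seeds(seed: int) -> dict[str, int]:
    """Stable per-stage seeds derived from one run seed (all < 2**31)."""
    state = np.random.SeedSequence(seed).generate_state(4)
    names = ("scans", "blank", "std_fbp", "std_hexose")
    return {n: int(s % (2 ** 31)) for n, s in zip(names, state)}


# ---------------------------------------------------------------------------
# Pipeline stages (file-based, composable)
# ---------------------------------------------------------------------------

def _write_trajectory(traj: Trajectory, path: Path) -> None:
    df = traj.to_frame()
    df["residence_time_s"] = np.repeat(traj.residence_time_s,
                                       len(traj.species_ids))
    df.to_csv(path, index=False)


def _read_trajectory(path: Path) -> Trajectory:
    df = pd.read_csv(path)
    wide = df.pivot(index="time_s", columns="species", values="conc_mM")
    tau = df.drop_duplicates("time_s").set_index("time_s")[
        "residence_time_s"].reindex(wide.index)
    species = tuple(reference_model().species_ids)
    return Trajectory(times=wide.index.to_numpy(),
                      conc=wide[list(species)].to_numpy(),
                      species_ids=species,
                      residence_time_s=tau.to_numpy())


def stage_simulate(preset: ExperimentPreset, seed: int, outdir: Path, *,
                   model: NetworkModel | None = None,
                   params: Mapping[str, float] | None = None,
                   design_budget: int = 8) -> Trajectory:
    """Resolve the protocol (running the design search for OED presets),
    simulate the reactor, and write protocol.yaml + trajectory.csv."""
    model = model or reference_model()
    params = params or reference_parameters()
    if preset.protocol is not None:
        protocol = preset.protocol
    else:
        res = design(preset.design_space, model, params, preset.loadings,
                     observables=[s for s in preset.quantified],
                     noise_sd=0.05, budget=design_budget, seed=seed,
                     scored_params=parameters_for_enzymes(
                         model, preset.fit_enzymes))
        protocol = res.protocol
    (outdir / "protocol.yaml").write_text(protocol.to_yaml())
    traj = simulate_cstr(model, params, preset.loadings, protocol)
    _write_trajectory(traj, outdir / "trajectory.csv")
    return traj


def _standard_stream(species: str, preset: ExperimentPreset, seed: int,
                     model: NetworkModel, conc_mM: float = 0.5
                     ) -> ScanStream:
    """Synthetic single-compound infusion run for fragmentation estimation."""
    tau = 240.0
    times = np.array([0.0, 600.0])
    conc = np.zeros((2, len(model.species_ids)))
    traj = Trajectory(times=times, conc=conc, species_ids=model.species_ids,
                      residence_time_s=np.full(2, tau))
    if species is not None:
        traj.conc[:, model.species_index(species)] = conc_mM
    cfg = preset.observation.with_(standards_mM={})
    return generate_scans(traj, cfg, preset.channels(model), seed=seed)


def stage_corrections(preset: ExperimentPreset, seed: int, outdir: Path, *,
                      model: NetworkModel | None = None) -> dict:
    """Estimate the detector baseline and fragmentation yields from blank
    and single-standard runs; write corrections.json."""
    model = model or reference_model()
    seeds = derive_seeds(seed)
    blank = _standard_stream(None, preset, seeds["blank"], model)
    baseline = estimate_baseline(blank)
    hexose = "F" if preset.experiment_kind == "full_fructose" else "G"
    phi: dict[str, float] = {}
    pairs = [("FBP", "F6P", seeds["std_fbp"]), (hexose, "LAC",
                                                seeds["std_hexose"])]
    for parent, fragment, s in pairs:
        kinds = {c.species for c in preset.channels(model)}
        if parent not in kinds or fragment not in kinds:
            continue
        stream = _standard_stream(parent, preset, s, model)
        phi[f"{parent}->{fragment}"] = estimate_fragmentation(
            stream, parent, fragment)
    out = {"baseline_counts": baseline, "fragmentation": phi}
    (outdir / "corrections.json").write_text(json.dumps(out, indent=2))
    return out


def stage_synth(preset: ExperimentPreset, seed: int, outdir: Path, *,
                model: NetworkModel | None = None) -> ScanStream:
    """Generate the raw scan stream from trajectory.csv; write scans.csv."""
    model = model or reference_model()
    traj = _read_trajectory(outdir / "trajectory.csv")
    stream = generate_scans(traj, preset.observation,
                            preset.channels(model),
                            seed=derive_seeds(seed)["scans"])
    stream.to_table().to_csv(outdir / "scans.csv", index=False)
    pd.DataFrame({"time_s": stream.times,
                  "q_reactor_ul_min": stream.q_reactor_ul_min}).to_csv(
        outdir / "flows.csv", index=False)
    return stream


def _read_stream(preset: ExperimentPreset, outdir: Path,
                 model: NetworkModel) -> ScanStream:
    table = pd.read_csv(outdir / "scans.csv")
    wide = table.pivot(index="time_s", columns="channel_id",
                       values="intensity")
    per_scan = table.drop_duplicates("time_s").set_index("time_s")
    flows = pd.read_csv(outdir / "flows.csv").set_index("time_s")
    channels = preset.channels(model)
    wide = wide[[c.channel_id for c in channels]]
    return ScanStream(times=wide.index.to_numpy(), intensities=wide.reset_index(drop=True),
                      tic=per_scan["tic"].to_numpy(),
                      uv_au=per_scan["uv_au"].to_numpy(),
                      channels=channels,
                      q_reactor_ul_min=flows["q_reactor_ul_min"].reindex(
                          wide.index).to_numpy())


def stage_quantify(preset: ExperimentPreset, seed: int, outdir: Path, *,
                   model: NetworkModel | None = None) -> q_.QuantSeries:
    """Correct, normalize and quantify scans.csv; write quant.csv."""
    model = model or reference_model()
    stream = _read_stream(preset, outdir, model)
    corr_info = json.loads((outdir / "corrections.json").read_text())
    phi = {tuple(k.split("->")): v
           for k, v in corr_info["fragmentation"].items()}
    corr = build_correction_model(
        phi, baseline_counts=corr_info["baseline_counts"], model=model)
    corrected = correct_and_normalize(stream, corr)
    series = quantify(corrected, preset.observation.standards_mM,
                      preset.observation.q_dilution_ul_min,
                      floor_mM=preset.observation.floor_mM)
    if "NADH" in preset.quantified:
        calibrate_nadh_uv(
            corrected, series,
            uv_epsilon_l=preset.observation.uv_epsilon_l,
            q_dilution_ul_min=preset.observation.q_dilution_ul_min)
    series.to_frame().to_csv(outdir / "quant.csv", index=False)
    return series


def stage_report(preset: ExperimentPreset, outdir: Path, *,
                 model: NetworkModel | None = None,
                 rmse: Mapping[str, float] | None = None) -> dict:
    """Mass-balance table and summary statistics; write report.json +
    mass_balance.csv."""
    model = model or reference_model()
    protocol = InflowProtocol.from_yaml((outdir / "protocol.yaml").read_text())
    series = _read_quant(outdir)
    mb = mass_balance_report(series, protocol, model=model,
                             dead_time_s=preset.observation.dead_time_s)
    mb.to_csv(outdir / "mass_balance.csv", index=False)
    steady = mb["balance_ratio"].to_numpy()
    report = {
        "preset": preset.name,
        "quantified_species": list(series.species),
        "unquantified_monitors": [c.species for c in preset.channels(model)
                                  if c.role == "monitor"],
        "near_floor": list(preset.near_floor),
        "n_bins": int(series.bin_time_s.size),
        "mass_balance_ratio_median": float(np.nanmedian(steady)),
        "per_species_rmse": dict(rmse) if rmse else None,
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return report


def _read_quant(outdir: Path) -> q_.QuantSeries:
    df = pd.read_csv(outdir / "quant.csv")
    conc = df.pivot(index="bin_time_s", columns="species", values="conc_mM")
    roll = df.pivot(index="bin_time_s", columns="species",
                    values="conc_rolling")
    masked = df.pivot(index="bin_time_s", columns="species", values="masked")
    return q_.QuantSeries(bin_time_s=conc.index.to_numpy(),
                          conc=conc.reset_index(drop=True),
                          rolling=roll.reset_index(drop=True),
                          masked=masked.astype(bool).reset_index(drop=True))


def stage_oed(preset: ExperimentPreset, seed: int, outdir: Path, *,
              model: NetworkModel | None = None,
              params: Mapping[str, float] | None = None,
              budget: int = 8) -> None:
    """Run the design search for a design-space preset; write
    protocol.yaml and design.json (score trace)."""
    if preset.design_space is None:
        raise ValueError(f"preset {preset.name} has a fixed protocol; "
                         "nothing to design")
    model = model or reference_model()
    params = params or reference_parameters()
    res = design(preset.design_space, model, params, preset.loadings,
                 observables=list(preset.quantified), noise_sd=0.05,
                 budget=budget, seed=seed,
                 scored_params=parameters_for_enzymes(model,
                                                      preset.fit_enzymes))
    (outdir / "protocol.yaml").write_text(res.protocol.to_yaml())
    (outdir / "design.json").write_text(json.dumps(
        {"score": res.score, "all_scores": res.all_scores.tolist(),
         "seed": res.seed}, indent=2))


def stage_fit(preset: ExperimentPreset, seed: int, outdir: Path, *,
              model: NetworkModel | None = None, n_starts: int = 4,
              max_nfev: int = 150):
    """Fit the preset's free parameters to quant.csv; write fit.json."""
    from .fitting import fit
    model = model or reference_model()
    protocol = InflowProtocol.from_yaml((outdir / "protocol.yaml").read_text())
    series = _read_quant(outdir)
    names = parameters_for_enzymes(model, preset.fit_enzymes)
    ref = reference_parameters()
    fixed = {k: v for k, v in ref.items() if k not in names}
    result = fit(model, protocol, preset.loadings, series, names,
                 fixed_params=fixed, n_starts=n_starts, seed=seed,
                 max_nfev=max_nfev,
                 dead_time_s=preset.observation.dead_time_s,
                 species=[s for s in preset.quantified
                          if s in series.conc.columns])
    (outdir / "fit.json").write_text(json.dumps(result.to_dict(), indent=2))
    return result


def stage_predict(preset: ExperimentPreset, outdir: Path, *,
                  model: NetworkModel | None = None,
                  protocol: InflowProtocol | None = None) -> pd.DataFrame:
    """Simulate the fitted ensemble on a protocol (default: the run's
    own); write prediction.csv with per-species mean and SD envelopes."""
    from .fitting import FitResult, predict
    model = model or reference_model()
    info = json.loads((outdir / "fit.json").read_text())
    fres = FitResult(param_names=tuple(info["param_names"]),
                     ensemble=np.asarray(info["ensemble"]),
                     losses=np.asarray(info["losses"]),
                     top_k=info["top_k"],
                     per_species_rmse=info["per_species_rmse"],
                     seed=info["seed"],
                     fixed_params=info["fixed_params"])
    if protocol is None:
        protocol = InflowProtocol.from_yaml(
            (outdir / "protocol.yaml").read_text())
    band = predict(fres, model, protocol, preset.loadings,
                   species=preset.quantified)
    rows = []
    for j, sp in enumerate(band.species):
        rows.append(pd.DataFrame({
            "time_s": band.times, "species": sp,
            "mean_mM": band.mean[:, j], "sd_mM": band.sd[:, j]}))
    df = pd.concat(rows, ignore_index=True)
    df.to_csv(outdir / "prediction.csv", index=False)
    return df


def run_pipeline(preset_name: str, seed: int, outdir: str | Path, *,
                 do_fit: bool = False, n_starts: int = 4,
                 design_budget: int = 8) -> dict:
    """Run the full pipeline for a preset; returns the report dict.

    Artifacts written to ``outdir``: protocol.yaml, trajectory.csv,
    corrections.json, scans.csv, flows.csv, quant.csv, mass_balance.csv,
    report.json (+ fit.json, prediction.csv when fitting).  Deterministic
    per seed.
    """
    preset = get_preset(preset_name)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = reference_model()
    stage_simulate(preset, seed, outdir, model=model,
                   design_budget=design_budget)
    stage_corrections(preset, seed, outdir, model=model)
    stage_synth(preset, seed, outdir, model=model)
    stage_quantify(preset, seed, outdir, model=model)
    rmse = None
    if do_fit:
        result = stage_fit(preset, seed, outdir, model=model,
                           n_starts=n_starts)
        stage_predict(preset, outdir, model=model)
        rmse = result.per_species_rmse
    return stage_report(preset, outdir, model=model, rmse=rmse)
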