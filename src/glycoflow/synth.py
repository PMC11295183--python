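"""Forward observation model: reactor trajectory -> raw IMS-MS scan stream.

Emulates the instrument chain between the reactor outlet and the data
file.  The reactor outflow passes an inline UV flow cell (340-360 nm,
reads NADH by Beer-Lambert before any dilution), is then diluted by a
standards line carrying unlabeled internal standards (default 87.5
uL/min), and is electrosprayed.  Every 550 ms the instrument produces one
scan: per-channel ion counts for extracted m/z (+/- 0.005 Da) and inverse
ion-mobility windows, plus the total ion current.

Artifacts included, in the order applied (the quantification pipeline
must undo all of them):

* isotope-dilution plumbing: analytes reach the source at
  C_out * Q_r/(Q_r + Q_d) while standards arrive at C_std * Q_d/(Q_r + Q_d);
* multiplicative lognormal shot-to-shot noise (sigma default 0.08) plus an
  additive detector baseline;
* in-flight fragmentation cross-talk: a fraction phi of a parent channel's
  signal lands on its fragment's channel (FBP loses neutral HPO3 and
  appears at the F6P m/z; the labeled hexose produces a lactate-channel
  isobar), in both label states;
* natural-abundance isotope overlap: the M+2 isotopologue of NAD falls
  onto the NADH channel (fraction computed from the NAD formula);
* a detection floor around 20 uM: below it, channel signal is not
  distinguishable from the baseline;
* transport dead time from reactor to detector (MS default 60 s, UV 5 s).

Everything is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import chem
from .chem import AdductSpec, LabeledFormula, adduct_mz
from .network import NetworkModel, reference_model
from .reactor import Trajectory

__all__ = [
    "ChannelDef",
    "ObservationConfig",
    "ScanStream",
    "default_channels",
    "quantified_species",
    "generate_scans",
    "SCAN_PERIOD_S",
    "MZ_RANGE",
    "MOBILITY_RANGE",
]

SCAN_PERIOD_S = 0.55
MZ_RANGE = (50.0, 1050.0)
MOBILITY_RANGE = (0.35, 1.3)   # inverse reduced mobility, V s cm^-2

#: mobility windows separating the hexose-phosphate isomers (V s cm^-2)
F6P_MOBILITY = (0.655, 0.665)
G6P_MOBILITY = (0.675, 0.685)

ATP_ADDUCT = AdductSpec(protons_removed=3, cations_added={"Na": 1}, charge=-2)


@dataclass(frozen=True)
class ChannelDef:
    """One extracted ion channel (m/z window, optional mobility window)."""

    channel_id: str
    species: str                      # model species id, or "GLU" reference
    labeled: bool                     # 13C/15N isotopologue vs unlabeled
    mz_center: float
    half_width_da: float = chem.MZ_WINDOW_HALF_WIDTH
    mobility_window: tuple[float, float] | None = None
    role: str = "analyte"             # analyte | standard | monitor | reference

    def __post_init__(self) -> None:
        if not (MZ_RANGE[0] <= self.mz_center <= MZ_RANGE[1]):
            raise ValueError(
                f"channel {self.channel_id}: m/z {self.mz_center} outside "
                f"instrument range {MZ_RANGE}")
        if self.mobility_window is not None:
            lo, hi = self.mobility_window
            if not (MOBILITY_RANGE[0] <= lo < hi <= MOBILITY_RANGE[1]):
                raise ValueError(
                    f"channel {self.channel_id}: mobility window outside "
                    f"instrument range {MOBILITY_RANGE}")


@dataclass(frozen=True)
class ObservationConfig:
    """Knobs of the forward observation model (defaults documented above)."""

    response_factors: Mapping[str, float] = field(default_factory=dict)
    default_response_factor: float = 1000.0      # counts per mM at source
    fragmentation: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {("FBP", "F6P"): 0.15, ("G", "LAC"): 0.05})
    noise_sigma: float = 0.08                    # lognormal sigma
    baseline_counts: float = 10.0
    baseline_sd: float = 2.5
    floor_mM: float = 0.02
    q_dilution_ul_min: float = 87.5
    standards_mM: Mapping[str, float] = field(default_factory=dict)
    uv_epsilon_l: float = 1.244                  # AU per mM NADH (eps*path)
    uv_noise_sd: float = 0.002                   # AU
    dead_time_s: float = 60.0
    uv_dead_time_s: float = 5.0
    tic_matrix_counts: float = 5e4               # constant chemical background
    global_gain: float = 1.0                     # overall detector gain
    scan_period_s: float = SCAN_PERIOD_S

    def __post_init__(self) -> None:
        for pair, phi in self.fragmentation.items():
            if not 0.0 <= phi < 1.0:
                raise ValueError(f"fragmentation yield {pair} outside [0,1)")
        if any(rf <= 0 for rf in self.response_factors.values()):
            raise ValueError("response factors must be > 0")
        if self.q_dilution_ul_min <= 0:
            raise ValueError("dilution flow must be > 0")
        object.__setattr__(self, "response_factors",
                           dict(self.response_factors))
        object.__setattr__(self, "fragmentation", dict(self.fragmentation))
        object.__setattr__(self, "standards_mM", dict(self.standards_mM))

    def response_factor(self, species: str) -> float:
        return self.response_factors.get(species,
                                         self.default_response_factor)

    def with_(self, **kw) -> "ObservationConfig":
        return replace(self, **kw)


@dataclass
class ScanStream:
    """Raw synthetic observables: per-scan channel counts, TIC and UV."""

    times: np.ndarray                     # s, one entry per scan
    intensities: pd.DataFrame             # scans x channels, counts
    tic: np.ndarray
    uv_au: np.ndarray
    channels: tuple[ChannelDef, ...]
    q_reactor_ul_min: np.ndarray          # programmed reactor outflow at scan
    meta: dict = field(default_factory=dict)

    def channel(self, channel_id: str) -> np.ndarray:
        return self.intensities[channel_id].to_numpy()

    def channel_def(self, channel_id: str) -> ChannelDef:
        for c in self.channels:
            if c.channel_id == channel_id:
                return c
        raise KeyError(channel_id)

    def to_table(self) -> pd.DataFrame:
        """Long-format export (time_s, channel_id, intensity, tic, uv_au)."""
        n_t = self.times.size
        chans = list(self.intensities.columns)
        return pd.DataFrame({
            "time_s": np.repeat(self.times, len(chans)),
            "channel_id": np.tile(chans, n_t),
            "intensity": self.intensities.to_numpy().ravel(),
            "tic": np.repeat(self.tic, len(chans)),
            "uv_au": np.repeat(self.uv_au, len(chans)),
        })


# ---------------------------------------------------------------------------
# Channel presets
# ---------------------------------------------------------------------------

#: standards co-infused through the dilution line (mM), unlabeled except the
#: 13C10-labeled ATP standard; the 15N-glutamate channel is an inert
#: reference exported for drift monitoring.
DEFAULT_STANDARDS_MM: dict[str, float] = {
    "G": 0.5, "F": 0.5, "G6P": 0.5, "F6P": 0.5, "FBP": 0.5,
    "PYR": 0.5, "LAC": 0.5, "ATP": 0.5, "GLU": 0.2,
}

GLU_FORMULA = LabeledFormula.parse("C5H9NO4")

_QUANTIFIED = {
    "subsystem_glucose": ("G", "G6P", "F6P", "ATP", "NADH"),
    "full_glucose": ("ATP", "G", "FBP", "F6P", "G6P", "LAC", "NADH", "PYR"),
    "full_fructose": ("ATP", "F", "FBP", "F6P", "G6P", "LAC", "NADH", "PYR"),
}
_MONITORS = {
    "subsystem_glucose": ("PGL6", "ADP", "NAD"),
    "full_glucose": ("PGL6", "ADP", "NAD", "XAP"),
    "full_fructose": ("PGL6", "ADP", "NAD", "XAP"),
}


def quantified_species(kind: str) -> tuple[str, ...]:
    try:
        return _QUANTIFIED[kind]
    except KeyError:
        raise ValueError(f"unknown experiment kind {kind!r}") from None


def _mz(model: NetworkModel, sid: str, labeled: bool) -> float:
    if sid == "XAP":
        f = model.species_def("DHAP").formula
        f = f.with_label(C=3) if labeled else f
        return adduct_mz(f)
    if sid == "GLU":
        return adduct_mz(GLU_FORMULA.with_label(N=1) if labeled
                         else GLU_FORMULA)
    sd = model.species_def(sid)
    f = sd.formula
    if labeled:
        if sid == "ATP":
            f = f.with_label(C=10)    # 13C10-ATP standard
        else:
            f = f.with_label(C=sd.label_count)
    adduct = ATP_ADDUCT if sid == "ATP" else chem.DEPROTONATED
    return adduct_mz(f, adduct)


def _mobility(sid: str) -> tuple[float, float] | None:
    return {"G6P": G6P_MOBILITY, "F6P": F6P_MOBILITY}.get(sid)


def default_channels(kind: str,
                     model: NetworkModel | None = None
                     ) -> tuple[ChannelDef, ...]:
    """Channel table for an experiment preset.

    Analyte channels track the in-situ species (13C-labeled for the
    carbon-carrying metabolites, unlabeled for the cofactors ATP and NADH);
    standard channels track the co-infused isotopically distinct standards.
    Monitor channels (6PGL, ADP, NAD and the unresolved triose-phosphate
    pair XAP) have no standard and stay unquantified; the 15N-glutamate
    channel is an inert reference.
    """
    model = model or reference_model()
    quant = quantified_species(kind)
    chans: list[ChannelDef] = []
    for sid in quant:
        analyte_labeled = sid not in ("ATP", "NADH")
        chans.append(ChannelDef(
            channel_id=f"{sid}[a]", species=sid, labeled=analyte_labeled,
            mz_center=_mz(model, sid, analyte_labeled),
            mobility_window=_mobility(sid), role="analyte"))
        if sid == "NADH":
            continue   # NADH is quantified through the UV calibration
        std_labeled = sid == "ATP"   # the ATP standard is the 13C10 isotopologue
        chans.append(ChannelDef(
            channel_id=f"{sid}[s]", species=sid, labeled=std_labeled,
            mz_center=_mz(model, sid, std_labeled),
            mobility_window=_mobility(sid), role="standard"))
    for sid in _MONITORS[kind]:
        labeled = sid in ("PGL6", "XAP")
        chans.append(ChannelDef(
            channel_id=f"{sid}[m]", species=sid, labeled=labeled,
            mz_center=_mz(model, sid, labeled), role="monitor"))
    chans.append(ChannelDef(
        channel_id="GLU[r]", species="GLU", labeled=True,
        mz_center=_mz(model, "GLU", True), role="reference"))
    return tuple(chans)


# ---------------------------------------------------------------------------
# Scan generation
# ---------------------------------------------------------------------------

def _source_concentration(ch: ChannelDef, conc_at: Mapping[str, np.ndarray],
                          cfg: ObservationConfig, d_analyte: np.ndarray,
                          d_standard: np.ndarray) -> np.ndarray:
    """ESI-side concentration feeding channel ``ch`` (mM)."""
    if ch.role in ("standard", "reference"):
        return cfg.standards_mM.get(ch.species, 0.0) * d_standard
    if ch.species == "XAP":
        return (conc_at["DHAP"] + conc_at["GAP"]) * d_analyte
    return conc_at[ch.species] * d_analyte


def generate_scans(traj: Trajectory, cfg: ObservationConfig,
                   channels: Sequence[ChannelDef], seed: int) -> ScanStream:
    """Generate a raw scan stream from a reactor trajectory.

    ``seed`` is required; generation is bit-reproducible for a fixed seed.
    Scan times start once the transport dead time has elapsed and end at
    the trajectory's last time point.
    """
    if seed is None:
        raise ValueError("seed is required for scan generation")
    rng = np.random.default_rng(seed)
    ids = [c.channel_id for c in channels]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate channel ids")

    t0 = traj.times[0] + cfg.dead_time_s
    times = np.arange(t0, traj.times[-1] + 1e-9, cfg.scan_period_s)
    t_react = times - cfg.dead_time_s
    conc = traj.interp(t_react)
    conc_at = {sid: conc[:, j] for j, sid in enumerate(traj.species_ids)}

    if traj.residence_time_s is None:
        raise ValueError("trajectory carries no flow information")
    q_r = np.interp(t_react, traj.times, traj.total_flow_ul_min())
    q_d = cfg.q_dilution_ul_min
    d_analyte = q_r / (q_r + q_d)
    d_standard = q_d / (q_r + q_d)

    sig = cfg.noise_sigma
    signal: dict[str, np.ndarray] = {}
    for ch in channels:
        c_src = _source_concentration(ch, conc_at, cfg, d_analyte, d_standard)
        rf = cfg.response_factor(ch.species)
        noise = np.exp(rng.normal(0.0, sig, times.size) - 0.5 * sig * sig) \
            if sig > 0 else 1.0
        signal[ch.channel_id] = rf * c_src * noise

    # in-flight fragmentation: parent signal leaks into the fragment channel
    # of the matching role/label state
    leak: dict[str, np.ndarray] = {i: np.zeros(times.size) for i in ids}
    by_key = {(c.species, c.role): c.channel_id for c in channels}
    for (parent, fragment), phi in cfg.fragmentation.items():
        if phi <= 0:
            continue
        for role in ("analyte", "standard"):
            src = by_key.get((parent, role))
            dst = by_key.get((fragment, role))
            if src and dst:
                leak[dst] = leak[dst] + phi * signal[src]

    # natural-isotope overlap: NAD M+2 onto the NADH channel
    nad_ch = next((c.channel_id for c in channels
                   if c.species == "NAD" and not c.labeled), None)
    nadh_ch = next((c.channel_id for c in channels
                    if c.species == "NADH"), None)
    if nad_ch and nadh_ch:
        ovl = chem.isotope_overlap_fraction(
            reference_model().species_def("NAD").formula, 2)
        leak[nadh_ch] = leak[nadh_ch] + ovl * signal[nad_ch]

    cols = {}
    for ch in channels:
        cid = ch.channel_id
        base = cfg.baseline_counts + (
            rng.normal(0.0, cfg.baseline_sd, times.size)
            if cfg.baseline_sd > 0 else 0.0)
        cols[cid] = np.maximum(
            cfg.global_gain * (signal[cid] + leak[cid] + base), 0.0)
    intens = pd.DataFrame(cols, columns=ids)

    tic = intens.to_numpy().sum(axis=1) + cfg.global_gain * cfg.tic_matrix_counts

    # UV cell sits on the undiluted reactor outflow, just ahead of the
    # dilution tee, so it leads the MS channels by dead_time - uv_dead_time
    t_uv = times - cfg.uv_dead_time_s
    if "NADH" in traj.species_ids:
        nadh_react = np.interp(np.clip(t_uv, traj.times[0], traj.times[-1]),
                               traj.times, traj["NADH"])
    else:
        nadh_react = np.zeros(times.size)
    uv = cfg.uv_epsilon_l * nadh_react
    if cfg.uv_noise_sd > 0:
        uv = uv + rng.normal(0.0, cfg.uv_noise_sd, times.size)

    return ScanStream(times=times, intensities=intens, tic=tic, uv_au=uv,
                      channels=tuple(channels), q_reactor_ul_min=q_r,
                      meta={"seed": seed, "config": cfg})
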