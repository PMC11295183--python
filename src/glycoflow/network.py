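"""The 18-species, 13-reaction glycolysis + G6PDH reaction network.

The network couples the "upper" glycolysis (hexose + 2 ATP -> FBP), the
"lower" glycolysis (FBP -> 2 pyruvate, regenerating 4 ATP), the pentose
phosphate entry reaction G6PDH (competing with GPI for G6P and producing
NADH), and lactate dehydrogenase.  Allosteric crosstalk between the two
halves is explicit: FBP activates pyruvate kinase and PEP inhibits
phosphofructokinase.  Hexokinase phosphorylates both glucose and fructose
with independent kinetic constants (fructose with lower affinity), so the
13 reactions are catalyzed by 12 distinct enzymes.

Enzymes are immobilized on beads inside the reactor and therefore appear
as fixed effective concentrations (loadings), never as ODE states.

Rate-law forms
--------------
* irreversible multi-substrate saturation:  v = kcat E prod_i S_i/(Km_i+S_i)
  (HK on each hexose, G6PDH, LDH)
* reversible one-substrate:  v = kcat E (A - B/Keq) / (Km_A + A + (Km_A/Km_B) B)
  (GPI, TPI, PGM, ENO)
* reversible uni-bi (ALD):  v = kcat E (A - P Q/Keq) /
  (Km_A + A + (Km_A/Km_P) P + (Km_A/Km_Q) Q + (Km_A/(Km_P Km_Q)) P Q)
* reversible difference-of-saturations, two substrates / two products
  (GAPDH, PGK):  v = kcat E [ A B /((Km_A+A)(Km_B+B))
                              - (1/Keq) P Q /((Km_P+P)(Km_Q+Q)) ]
* PFK: irreversible MM product gated by a Hill inhibition term
  1/(1 + (PEP/Ki)^n)
* PK: irreversible MM product scaled by a Hill activation term
  (1 + beta (FBP/Ka)^h)/(1 + (FBP/Ka)^h); the rate ratio between
  saturating and absent FBP is beta.

Inorganic phosphate and water are buffered and are not state variables;
the GAPDH law omits Pi, but its consumption is recorded in the reaction's
``implicit`` stoichiometry so that phosphorus bookkeeping stays closed.
6-phosphogluconolactone is a terminal sink (no lactonase in the network);
its concentration is inferred from NADH downstream.

The reference parameter set counts exactly 56 free kinetic parameters:
HK-glc 3, HK-fru 3, GPI 4, G6PDH 3, PFK 5, ALD 5, TPI 4, GAPDH 6, PGK 6,
PGM 4, ENO 4, PK 6, LDH 3.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml

from .chem import LabeledFormula

__all__ = [
    "SpeciesDef",
    "ReactionDef",
    "NetworkModel",
    "reference_model",
    "reference_parameters",
    "reference_loadings",
    "subsystem_loadings",
    "reaction_rates",
    "stoichiometric_matrix",
    "parameters_for_enzymes",
    "parameter_class",
    "compile_rates",
    "PARAMETER_BOUNDS",
    "SPECIES_ORDER",
    "ENZYMES",
]

SPECIES_ORDER = (
    "G", "F", "G6P", "F6P", "FBP", "DHAP", "GAP", "BPG", "PG3", "PG2",
    "PEP", "PYR", "LAC", "PGL6", "ATP", "ADP", "NAD", "NADH",
)

ENZYMES = (
    "HK", "GPI", "G6PDH", "PFK", "ALD", "TPI",
    "GAPDH", "PGK", "PGM", "ENO", "PK", "LDH",
)


@dataclass(frozen=True)
class SpeciesDef:
    id: str
    formula: LabeledFormula
    carbon_count: int
    labeled: bool    # carries 13C from the labeled hexose input
    observable: bool

    @property
    def label_count(self) -> int:
        return self.carbon_count if self.labeled else 0


@dataclass(frozen=True)
class ReactionDef:
    """One enzyme-catalyzed reaction with its rate-law kind and parameters.

    ``substrates``/``products`` fix the order in which Km parameters are
    interpreted; ``modifier`` names the allosteric effector for the
    inhibited/activated kinds.  ``params`` are the reaction's free kinetic
    parameter names, globally unique (``"<reaction id>.<name>"``).
    ``implicit`` records stoichiometry of buffered, non-state species.
    """

    id: str
    enzyme: str
    kind: str
    stoichiometry: Mapping[str, int]
    substrates: tuple[str, ...]
    products: tuple[str, ...] = ()
    modifier: str | None = None
    implicit: Mapping[str, int] = field(default_factory=dict)

    @property
    def params(self) -> tuple[str, ...]:
        p = [f"{self.id}.kcat"]
        if self.kind == "first_order":
            return (f"{self.id}.k",)
        for s in self.substrates:
            p.append(f"{self.id}.Km_{s}")
        if self.kind in ("reversible_uni", "reversible_uni_bi",
                         "reversible_bi_bi"):
            for s in self.products:
                p.append(f"{self.id}.Km_{s}")
            p.append(f"{self.id}.Keq")
        elif self.kind == "mm_inhibited":
            p += [f"{self.id}.Ki_{self.modifier}", f"{self.id}.n"]
        elif self.kind == "mm_activated":
            p += [f"{self.id}.Ka_{self.modifier}", f"{self.id}.beta",
                  f"{self.id}.h"]
        elif self.kind != "irreversible_mm":
            raise ValueError(f"unknown rate-law kind {self.kind!r}")
        return tuple(p)


@dataclass(frozen=True)
class NetworkModel:
    species: tuple[SpeciesDef, ...]
    reactions: tuple[ReactionDef, ...]

    @property
    def species_ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.species)

    @property
    def parameter_names(self) -> tuple[str, ...]:
        out: list[str] = []
        for r in self.reactions:
            out.extend(r.params)
        return tuple(out)

    @property
    def enzymes(self) -> tuple[str, ...]:
        seen: list[str] = []
        for r in self.reactions:
            if r.enzyme not in seen:
                seen.append(r.enzyme)
        return tuple(seen)

    def species_index(self, sid: str) -> int:
        return self.species_ids.index(sid)

    def species_def(self, sid: str) -> SpeciesDef:
        return self.species[self.species_index(sid)]

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "species": [
                {"id": s.id, "formula": str(s.formula),
                 "carbon_count": s.carbon_count, "labeled": s.labeled,
                 "observable": s.observable}
                for s in self.species
            ],
            "reactions": [
                {"id": r.id, "enzyme": r.enzyme, "kind": r.kind,
                 "stoichiometry": dict(r.stoichiometry),
                 "substrates": list(r.substrates),
                 "products": list(r.products),
                 "modifier": r.modifier,
                 "implicit": dict(r.implicit)}
                for r in self.reactions
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkModel":
        species = tuple(
            SpeciesDef(s["id"], LabeledFormula.parse(s["formula"]),
                       s["carbon_count"], s["labeled"], s["observable"])
            for s in d["species"]
        )
        reactions = tuple(
            ReactionDef(r["id"], r["enzyme"], r["kind"],
                        dict(r["stoichiometry"]), tuple(r["substrates"]),
                        tuple(r["products"]), r.get("modifier"),
                        dict(r.get("implicit", {})))
            for r in d["reactions"]
        )
        return cls(species, reactions)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "NetworkModel":
        return cls.from_dict(yaml.safe_load(io.StringIO(text)))


# ---------------------------------------------------------------------------
# Reference network
# ---------------------------------------------------------------------------

_FORMULAS = {
    "G": "C6H12O6", "F": "C6H12O6",
    "G6P": "C6H13O9P", "F6P": "C6H13O9P",
    "FBP": "C6H14O12P2",
    "DHAP": "C3H7O6P", "GAP": "C3H7O6P",
    "BPG": "C3H8O10P2",
    "PG3": "C3H7O7P", "PG2": "C3H7O7P",
    "PEP": "C3H5O6P",
    "PYR": "C3H4O3", "LAC": "C3H6O3",
    "PGL6": "C6H11O9P",
    "ATP": "C10H16N5O13P3", "ADP": "C10H15N5O10P2",
    "NAD": "C21H27N7O14P2", "NADH": "C21H29N7O14P2",
}

# species the instrument cannot see at all are none; "observable" here means
# detected in at least one experiment class (BPG/PG3/PG2/PEP sit below the
# detection floor in practice but have channels)
_UNOBSERVED = {"BPG", "PG3", "PG2", "PEP"}


def _species_defs() -> tuple[SpeciesDef, ...]:
    out = []
    for sid in SPECIES_ORDER:
        carbons = 6 if sid in ("G", "F", "G6P", "F6P", "FBP", "PGL6") else 3
        labeled = sid not in ("ATP", "ADP", "NAD", "NADH")
        if sid in ("ATP", "ADP"):
            carbons = 10
        elif sid in ("NAD", "NADH"):
            carbons = 21
        out.append(SpeciesDef(
            id=sid,
            formula=LabeledFormula.parse(_FORMULAS[sid]),
            carbon_count=carbons,
            labeled=labeled,
            observable=sid not in _UNOBSERVED,
        ))
    return tuple(out)


def _reaction_defs() -> tuple[ReactionDef, ...]:
    R = ReactionDef
    return (
        R("HK_G", "HK", "irreversible_mm",
          {"G": -1, "ATP": -1, "G6P": 1, "ADP": 1}, ("G", "ATP")),
        R("HK_F", "HK", "irreversible_mm",
          {"F": -1, "ATP": -1, "F6P": 1, "ADP": 1}, ("F", "ATP")),
        R("GPI", "GPI", "reversible_uni",
          {"G6P": -1, "F6P": 1}, ("G6P",), ("F6P",)),
        R("G6PDH", "G6PDH", "irreversible_mm",
          {"G6P": -1, "NAD": -1, "PGL6": 1, "NADH": 1}, ("G6P", "NAD")),
        R("PFK", "PFK", "mm_inhibited",
          {"F6P": -1, "ATP": -1, "FBP": 1, "ADP": 1}, ("F6P", "ATP"),
          modifier="PEP"),
        R("ALD", "ALD", "reversible_uni_bi",
          {"FBP": -1, "DHAP": 1, "GAP": 1}, ("FBP",), ("DHAP", "GAP")),
        R("TPI", "TPI", "reversible_uni",
          {"DHAP": -1, "GAP": 1}, ("DHAP",), ("GAP",)),
        R("GAPDH", "GAPDH", "reversible_bi_bi",
          {"GAP": -1, "NAD": -1, "BPG": 1, "NADH": 1}, ("GAP", "NAD"),
          ("BPG", "NADH"), implicit={"Pi": -1}),
        R("PGK", "PGK", "reversible_bi_bi",
          {"BPG": -1, "ADP": -1, "PG3": 1, "ATP": 1}, ("BPG", "ADP"),
          ("PG3", "ATP")),
        R("PGM", "PGM", "reversible_uni",
          {"PG3": -1, "PG2": 1}, ("PG3",), ("PG2",)),
        R("ENO", "ENO", "reversible_uni",
          {"PG2": -1, "PEP": 1}, ("PG2",), ("PEP",), implicit={"H2O": 1}),
        R("PK", "PK", "mm_activated",
          {"PEP": -1, "ADP": -1, "PYR": 1, "ATP": 1}, ("PEP", "ADP"),
          modifier="FBP"),
        R("LDH", "LDH", "irreversible_mm",
          {"PYR": -1, "NADH": -1, "LAC": 1, "NAD": 1}, ("PYR", "NADH")),
    )


def reference_model() -> NetworkModel:
    """The fixed reference network: 18 species, 13 reactions, 12 enzymes."""
    return NetworkModel(_species_defs(), _reaction_defs())


#: Documented "truth" parameter set used for synthetic studies.  Values are
#: plausible for the yeast/muscle enzymes in the network (turnovers 1-100
#: s^-1, Km in the 0.01-5 mM range, fructose affinity of HK well below its
#: glucose affinity); they are the package's fixed reference, not literature
#: constants.
_REFERENCE_PARAMS: dict[str, float] = {
    "HK_G.kcat": 50.0, "HK_G.Km_G": 0.12, "HK_G.Km_ATP": 0.40,
    "HK_F.kcat": 30.0, "HK_F.Km_F": 1.50, "HK_F.Km_ATP": 0.40,
    "GPI.kcat": 80.0, "GPI.Km_G6P": 0.50, "GPI.Km_F6P": 0.30,
    "GPI.Keq": 0.36,
    "G6PDH.kcat": 25.0, "G6PDH.Km_G6P": 0.10, "G6PDH.Km_NAD": 0.08,
    "PFK.kcat": 40.0, "PFK.Km_F6P": 0.10, "PFK.Km_ATP": 0.15,
    "PFK.Ki_PEP": 0.50, "PFK.n": 2.0,
    "ALD.kcat": 20.0, "ALD.Km_FBP": 0.30, "ALD.Km_DHAP": 2.00,
    "ALD.Km_GAP": 1.00, "ALD.Keq": 0.10,
    "TPI.kcat": 100.0, "TPI.Km_DHAP": 1.20, "TPI.Km_GAP": 0.40,
    "TPI.Keq": 0.045,
    "GAPDH.kcat": 60.0, "GAPDH.Km_GAP": 0.40, "GAPDH.Km_NAD": 0.10,
    "GAPDH.Km_BPG": 0.20, "GAPDH.Km_NADH": 0.05, "GAPDH.Keq": 0.50,
    "PGK.kcat": 80.0, "PGK.Km_BPG": 0.05, "PGK.Km_ADP": 0.20,
    "PGK.Km_PG3": 0.60, "PGK.Km_ATP": 0.30, "PGK.Keq": 50.0,
    "PGM.kcat": 70.0, "PGM.Km_PG3": 0.50, "PGM.Km_PG2": 0.15,
    "PGM.Keq": 0.18,
    "ENO.kcat": 50.0, "ENO.Km_PG2": 0.10, "ENO.Km_PEP": 0.30,
    "ENO.Keq": 4.6,
    "PK.kcat": 60.0, "PK.Km_PEP": 0.30, "PK.Km_ADP": 0.30,
    "PK.Ka_FBP": 0.20, "PK.beta": 8.0, "PK.h": 2.0,
    "LDH.kcat": 90.0, "LDH.Km_PYR": 0.30, "LDH.Km_NADH": 0.03,
}

#: Default bounds for fitting / log-uniform sampling, by parameter class.
PARAMETER_BOUNDS = {
    "kcat": (1.0, 100.0),     # s^-1
    "Km": (0.01, 5.0),        # mM
    "Ki": (0.01, 5.0),
    "Ka": (0.01, 5.0),
    "Keq": (0.01, 100.0),
    "beta": (1.0, 20.0),
    "n": (1.0, 4.0),
    "h": (1.0, 4.0),
    "k": (1e-4, 10.0),        # s^-1, first-order test laws
}


def parameter_class(name: str) -> str:
    stem = name.split(".", 1)[1]
    return stem.split("_", 1)[0]


def reference_parameters() -> dict[str, float]:
    return dict(_REFERENCE_PARAMS)


#: Effective enzyme loadings in the reactor, uM active sites; these are set
#: by the bead volumes pipetted into the reactor and are configurable, never
#: fitted.
_REFERENCE_LOADINGS = {
    "HK": 1.0, "GPI": 0.8, "G6PDH": 1.0, "PFK": 0.8, "ALD": 1.5,
    "TPI": 0.5, "GAPDH": 2.0, "PGK": 1.0, "PGM": 1.0, "ENO": 1.0,
    "PK": 1.0, "LDH": 1.0,
}


def reference_loadings() -> dict[str, float]:
    return dict(_REFERENCE_LOADINGS)


def subsystem_loadings() -> dict[str, float]:
    """Loadings for the 3-enzyme upper-glycolysis subsystem (HK, GPI, G6PDH)."""
    return {e: (_REFERENCE_LOADINGS[e] if e in ("HK", "GPI", "G6PDH") else 0.0)
            for e in ENZYMES}


def parameters_for_enzymes(model: NetworkModel,
                           enzymes: Sequence[str]) -> tuple[str, ...]:
    """Parameter names belonging to reactions of the given enzymes."""
    return tuple(p for r in model.reactions if r.enzyme in enzymes
                 for p in r.params)


def parameters_for_reactions(model: NetworkModel,
                             reaction_ids: Sequence[str]) -> tuple[str, ...]:
    """Parameter names of the given reactions (e.g. the glucose-side HK
    reaction only, excluding the fructose one)."""
    return tuple(p for r in model.reactions if r.id in reaction_ids
                 for p in r.params)


# ---------------------------------------------------------------------------
# Rate evaluation
# ---------------------------------------------------------------------------

def _rate_fn(r: ReactionDef, idx: Mapping[str, int],
             params: Mapping[str, float], e_mM: float
             ) -> Callable[[np.ndarray], float]:
    """Build a closure computing reaction ``r``'s rate (mM/s) from the state."""
    p = {name.split(".", 1)[1]: params[name] for name in r.params}
    if r.kind == "first_order":
        i = idx[r.substrates[0]]
        k = p["k"] * e_mM if e_mM else 0.0
        return lambda y: k * y[i]
    kcat_e = p["kcat"] * e_mM
    si = [idx[s] for s in r.substrates]
    skm = [p[f"Km_{s}"] for s in r.substrates]
    if r.kind == "irreversible_mm":
        def v(y):
            out = kcat_e
            for i, km in zip(si, skm):
                out *= y[i] / (km + y[i]) if y[i] > 0 else 0.0
            return out
        return v
    if r.kind == "reversible_uni":
        ia, ib = si[0], idx[r.products[0]]
        ka, kb = skm[0], p[f"Km_{r.products[0]}"]
        keq = p["Keq"]
        return lambda y: kcat_e * (y[ia] - y[ib] / keq) / (
            ka + y[ia] + (ka / kb) * y[ib])
    if r.kind == "reversible_uni_bi":
        ia = si[0]
        ip_, iq = (idx[s] for s in r.products)
        ka = skm[0]
        kp, kq = (p[f"Km_{s}"] for s in r.products)
        keq = p["Keq"]
        return lambda y: kcat_e * (y[ia] - y[ip_] * y[iq] / keq) / (
            ka + y[ia] + (ka / kp) * y[ip_] + (ka / kq) * y[iq]
            + (ka / (kp * kq)) * y[ip_] * y[iq])
    if r.kind == "reversible_bi_bi":
        ia, ib = si
        ip_, iq = (idx[s] for s in r.products)
        ka, kb = skm
        kp, kq = (p[f"Km_{s}"] for s in r.products)
        keq = p["Keq"]
        return lambda y: kcat_e * (
            y[ia] * y[ib] / ((ka + y[ia]) * (kb + y[ib]))
            - (y[ip_] * y[iq] / ((kp + y[ip_]) * (kq + y[iq]))) / keq)
    if r.kind == "mm_inhibited":
        im = idx[r.modifier]
        ki, n = p[f"Ki_{r.modifier}"], p["n"]
        def v(y):
            out = kcat_e
            for i, km in zip(si, skm):
                out *= y[i] / (km + y[i]) if y[i] > 0 else 0.0
            return out / (1.0 + (y[im] / ki) ** n if y[im] > 0 else 1.0)
        return v
    if r.kind == "mm_activated":
        im = idx[r.modifier]
        kact, beta, h = p[f"Ka_{r.modifier}"], p["beta"], p["h"]
        def v(y):
            out = kcat_e
            for i, km in zip(si, skm):
                out *= y[i] / (km + y[i]) if y[i] > 0 else 0.0
            x = (y[im] / kact) ** h if y[im] > 0 else 0.0
            return out * (1.0 + beta * x) / (1.0 + x)
        return v
    raise ValueError(f"unknown rate-law kind {r.kind!r}")


def compile_rates(model: NetworkModel, params: Mapping[str, float],
                  loadings: Mapping[str, float]
                  ) -> Callable[[np.ndarray], np.ndarray]:
    """Compile a fast state -> per-reaction-rate function.

    Reactions whose enzyme loading is zero are compiled out (their rate is
    identically zero).  Loadings are in uM active sites and converted to mM
    here; rates come out in mM/s.
    """
    idx = {sid: i for i, sid in enumerate(model.species_ids)}
    fns: list[tuple[int, Callable]] = []
    for j, r in enumerate(model.reactions):
        e_mM = loadings.get(r.enzyme, 0.0) * 1e-3
        if e_mM < 0:
            raise ValueError(f"negative loading for {r.enzyme}")
        if e_mM > 0:
            fns.append((j, _rate_fn(r, idx, params, e_mM)))
    n_rxn = len(model.reactions)

    def rates(y: np.ndarray) -> np.ndarray:
        v = np.zeros(n_rxn)
        for j, f in fns:
            v[j] = f(y)
        return v

    return rates


def reaction_rates(state, params: Mapping[str, float],
                   loadings: Mapping[str, float],
                   model: NetworkModel | None = None) -> np.ndarray:
    """Per-reaction rates (mM/s) at the given concentrations (mM).

    ``state`` may be a mapping species -> mM or an array in species order.
    Negative concentrations are rejected.
    """
    model = model or reference_model()
    if isinstance(state, Mapping):
        y = np.array([state.get(s, 0.0) for s in model.species_ids])
    else:
        y = np.asarray(state, dtype=float)
    if np.any(y < 0):
        raise ValueError("negative concentration in state")
    v = compile_rates(model, params, loadings)(y)
    if not np.all(np.isfinite(v)):
        raise FloatingPointError("non-finite reaction rate")
    return v


def stoichiometric_matrix(model: NetworkModel | None = None) -> np.ndarray:
    """Signed integer species x reactions stoichiometric matrix."""
    model = model or reference_model()
    S = np.zeros((len(model.species), len(model.reactions)), dtype=int)
    idx = {sid: i for i, sid in enumerate(model.species_ids)}
    for j, r in enumerate(model.reactions):
        for sid, coef in r.stoichiometry.items():
            S[idx[sid], j] = coef
    return S
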