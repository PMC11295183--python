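"""Elemental-formula arithmetic for mass-spectrometric channel definitions.

Monoisotopic masses, adduct m/z, isotopologue mass shifts and
natural-abundance isotope distributions.  All m/z channels used by the
observation model and the quantification pipeline are derived here, as is
the natural-isotope overlap correction (e.g. the M+2 isotopologue of NAD
falling onto the NADH channel).

Atomic masses and isotopic abundances are hard-coded from the IUPAC 2021
tables in a single table below; there is no other source of these numbers
in the package.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "LabeledFormula",
    "AdductSpec",
    "IsotopeDistribution",
    "monoisotopic_mass",
    "adduct_mz",
    "natural_isotope_distribution",
    "isotope_overlap_fraction",
    "MZ_WINDOW_HALF_WIDTH",
    "PROTON_MASS",
    "C13_SHIFT",
]

# IUPAC 2021 monoisotopic masses of the most abundant isotope, Da.
ATOMIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.98976928,
    "K": 38.96370649,
}

# Mass shift of the heavy label isotope relative to the principal isotope.
HEAVY_SHIFT: dict[str, float] = {
    "C": 1.0033548378,   # 13C - 12C
    "N": 0.9970348934,   # 15N - 14N
    "H": 1.0062767458,   # 2H - 1H
}

C13_SHIFT = HEAVY_SHIFT["C"]

# Relative isotopic abundances by nominal mass offset from the principal
# isotope (IUPAC 2021 representative values).  Index = integer mass offset.
ISOTOPE_ABUNDANCE: dict[str, tuple[float, ...]] = {
    "H": (0.999885, 0.000115),
    "C": (0.9893, 0.0107),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "P": (1.0,),
    "S": (0.9499, 0.0075, 0.0425, 0.0, 0.0001),
    "Na": (1.0,),
    "K": (0.932581, 0.000117, 0.067302),
}

#: Mass of the proton; deprotonation removes H+ (not an H atom), so the
#: electron stays with the ion.
PROTON_MASS = 1.00727646688

#: Half-width of extracted-ion channels in Da (channel matching uses this
#: window, never rounding of m/z values).
MZ_WINDOW_HALF_WIDTH = 0.005

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")
_LABEL_TOKEN = re.compile(r"\{(\d+)([A-Z][a-z]?)(\d*)\}")


def _validate_element(symbol: str) -> None:
    if symbol not in ATOMIC_MASS:
        raise ValueError(f"unknown element symbol: {symbol!r}")


@dataclass(frozen=True)
class LabeledFormula:
    """Elemental composition plus heavy-isotope label specification.

    ``counts`` maps element symbol to the total atom count; ``label`` maps
    element symbol to the number of those atoms carrying the heavy label
    (e.g. ``{"C": 6}`` for a uniformly 13C-labeled hexose).
    """

    counts: Mapping[str, int]
    label: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sym, n in self.counts.items():
            _validate_element(sym)
            if n < 0:
                raise ValueError(f"negative count for {sym}")
        for sym, n in self.label.items():
            _validate_element(sym)
            if sym not in HEAVY_SHIFT:
                raise ValueError(f"no heavy-label isotope defined for {sym}")
            if n < 0:
                raise ValueError(f"negative label count for {sym}")
            if n > self.counts.get(sym, 0):
                raise ValueError(
                    f"label count {n} exceeds atom count for {sym}"
                )
        object.__setattr__(self, "counts", dict(self.counts))
        object.__setattr__(self, "label", dict(self.label))

    @classmethod
    def parse(cls, text: str) -> "LabeledFormula":
        """Parse Hill-notation text with an optional label suffix.

        ``"C6H13O9P"`` is unlabeled fructose-6-phosphate;
        ``"C6H13O9P{13C6}"`` is its uniformly 13C-labeled isotopologue.
        """
        label: dict[str, int] = {}
        for m in _LABEL_TOKEN.finditer(text):
            nominal, sym, n = m.groups()
            _validate_element(sym)
            expected = round(ATOMIC_MASS[sym]) + 1
            if int(nominal) != expected:
                raise ValueError(
                    f"unsupported label isotope {nominal}{sym}; only +1 "
                    f"heavy isotopes are supported"
                )
            label[sym] = label.get(sym, 0) + (int(n) if n else 1)
        plain = _LABEL_TOKEN.sub("", text)
        counts: dict[str, int] = {}
        consumed = 0
        for m in _FORMULA_TOKEN.finditer(plain):
            sym, n = m.groups()
            if not sym:
                continue
            consumed += len(m.group(0))
            _validate_element(sym)
            counts[sym] = counts.get(sym, 0) + (int(n) if n else 1)
        if consumed != len(plain):
            raise ValueError(f"cannot parse formula {text!r}")
        return cls(counts, label)

    def __str__(self) -> str:
        def hill_order(syms):
            # Hill convention: C first, H second, rest alphabetical
            rest = sorted(s for s in syms if s not in ("C", "H"))
            head = [s for s in ("C", "H") if s in syms]
            return head + rest

        body = "".join(
            f"{s}{self.counts[s] if self.counts[s] != 1 else ''}"
            for s in hill_order(self.counts)
            if self.counts[s] > 0
        )
        lab = "".join(
            f"{{{round(ATOMIC_MASS[s]) + 1}{s}{n if n != 1 else ''}}}"
            for s, n in sorted(self.label.items())
            if n > 0
        )
        return body + lab

    def with_label(self, **label: int) -> "LabeledFormula":
        return LabeledFormula(self.counts, label)

    def unlabeled(self) -> "LabeledFormula":
        return LabeledFormula(self.counts, {})


@dataclass(frozen=True)
class AdductSpec:
    """Ionization adduct: protons removed, cations added, net charge.

    The net charge must equal the summed cation charge (all supported
    cations are +1) minus the number of protons removed, and may not be
    zero.  ``[M-H]-`` is ``AdductSpec(1, {}, -1)``; the doubly charged
    sodiated ATP ion ``[M-3H+Na]2-`` is ``AdductSpec(3, {"Na": 1}, -2)``.
    """

    protons_removed: int
    cations_added: Mapping[str, int] = field(default_factory=dict)
    charge: int = -1

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("adduct charge may not be zero")
        for sym, n in self.cations_added.items():
            _validate_element(sym)
            if n < 0:
                raise ValueError(f"negative cation count for {sym}")
        net = sum(self.cations_added.values()) - self.protons_removed
        if net != self.charge:
            raise ValueError(
                f"inconsistent adduct: cations-protons gives charge {net}, "
                f"declared {self.charge}"
            )
        object.__setattr__(self, "cations_added", dict(self.cations_added))


DEPROTONATED = AdductSpec(protons_removed=1, charge=-1)


@dataclass(frozen=True)
class IsotopeDistribution:
    """Relative abundances of isotopologues by nominal mass offset.

    ``offsets`` is an ordered list of ``(integer offset, fraction)`` pairs
    starting at offset 0.  ``truncated`` records whether offsets beyond the
    requested maximum were dropped, and ``renormalized`` whether the kept
    fractions were rescaled to sum to one afterwards.
    """

    offsets: tuple[tuple[int, float], ...]
    truncated: bool = False
    renormalized: bool = False

    def __post_init__(self) -> None:
        offs = [o for o, _ in self.offsets]
        if offs and (offs[0] != 0 or any(b <= a for a, b in zip(offs, offs[1:]))):
            raise ValueError("offsets must increase strictly from 0")
        if not self.truncated or self.renormalized:
            total = sum(a for _, a in self.offsets)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"abundances sum to {total}, not 1")

    def abundance(self, offset: int) -> float:
        for o, a in self.offsets:
            if o == offset:
                return a
        return 0.0


def monoisotopic_mass(f: LabeledFormula) -> float:
    """Monoisotopic mass in Da: principal-isotope masses plus label shifts."""
    mass = sum(ATOMIC_MASS[s] * n for s, n in f.counts.items())
    mass += sum(HEAVY_SHIFT[s] * n for s, n in f.label.items())
    return mass


def adduct_mz(f: LabeledFormula, a: AdductSpec = DEPROTONATED) -> float:
    """m/z of the adduct ion of ``f`` under adduct ``a``."""
    m = monoisotopic_mass(f)
    m -= a.protons_removed * PROTON_MASS
    m += sum(ATOMIC_MASS[s] * n for s, n in a.cations_added.items())
    return m / abs(a.charge)


def _element_power(sym: str, n: int) -> np.ndarray:
    """Isotopologue distribution of ``n`` identical atoms (polynomial power)."""
    base = np.asarray(ISOTOPE_ABUNDANCE[sym], dtype=float)
    out = np.array([1.0])
    for _ in range(n):
        out = np.convolve(out, base)
    return out


def natural_isotope_distribution(
    f: LabeledFormula, max_offset: int, *, renormalize: bool = False
) -> IsotopeDistribution:
    """Natural-abundance isotopologue distribution of ``f`` up to M+max_offset.

    The distribution is the convolution over all atoms of their single-atom
    isotope distributions.  Atoms at labeled positions are isotopically pure
    by construction and contribute no natural spread (their mass shift is in
    the monoisotopic mass, not here).  The full distribution sums to one
    before truncation; pass ``renormalize=True`` to rescale the kept
    offsets after truncation.
    """
    if max_offset < 0:
        raise ValueError("max_offset must be >= 0")
    dist = np.array([1.0])
    for sym, n in f.counts.items():
        free = n - f.label.get(sym, 0)
        dist = np.convolve(dist, _element_power(sym, free))
    total = dist.sum()
    if abs(total - 1.0) > 1e-9:  # pragma: no cover - defensive
        raise AssertionError("distribution lost normalization")
    truncated = dist.size - 1 > max_offset
    kept = dist[: max_offset + 1]
    if truncated and renormalize:
        kept = kept / kept.sum()
    return IsotopeDistribution(
        offsets=tuple((i, float(a)) for i, a in enumerate(kept)),
        truncated=truncated,
        renormalized=truncated and renormalize,
    )


def isotope_overlap_fraction(interferer: LabeledFormula, offset: int) -> float:
    """Intensity of the M+``offset`` isotopologue relative to M+0.

    This is the fraction of an interfering compound's *channel* intensity
    (which tracks its M+0 ion) that leaks into a channel ``offset`` nominal
    masses higher — e.g. NAD M+2 onto the NADH channel.
    """
    d = natural_isotope_distribution(interferer, offset)
    return d.abundance(offset) / d.abundance(0)
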