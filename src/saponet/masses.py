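"""Exact monoisotopic-mass arithmetic for saponin dereplication.

Everything downstream (neutral-loss decomposition, ladder generation,
adduct assignment) reduces to sums and differences of a small set of
monoisotopic masses, so those constants are pinned here rather than taken
from an external library: electrospray ion species of steroidal saponins
are singly or doubly charged and built from C, H, O, N and Na only.

Conventions
-----------
* m/z of an ion species is ``(M + delta) / |z|`` where ``delta`` is the
  electron-corrected mass added to the neutral molecule M.  Using the
  proton mass (1.007276 Da) rather than the hydrogen atom mass is what
  makes calculated values agree with QToF reference tables to 4 decimals.
* ppm error is signed as ``(theoretical - observed) / theoretical * 1e6``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping

__all__ = [
    "ELEMENT_MASSES",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "Formula",
    "FormulaError",
    "parse_formula",
    "monoisotopic_mass",
    "AdductSpec",
    "ADDUCTS",
    "adduct_mz",
    "neutral_mass_from_mz",
    "ppm_error",
    "NEUTRAL_LOSSES",
    "neutral_loss_mass",
]

# NIST most-abundant-isotope masses (Da).  Pinned so results do not depend
# on the installed version of any mass library.
ELEMENT_MASSES: Dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "O": 15.99491461956,
    "N": 14.0030740048,
    "Na": 22.9897692809,
}

ELECTRON_MASS = 0.00054857990907
PROTON_MASS = ELEMENT_MASSES["H"] - ELECTRON_MASS  # 1.00727645216

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed or unsupported elemental formula strings."""


@dataclass(frozen=True)
class Formula:
    """An elemental composition (element symbol -> non-negative count)."""

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for el, n in self.counts.items():
            if el not in ELEMENT_MASSES:
                raise FormulaError(f"unsupported element symbol: {el!r}")
            if n < 0:
                raise FormulaError(f"negative count for {el}: {n}")
            if n:
                clean[el] = int(n)
        object.__setattr__(self, "counts", clean)

    @property
    def mass(self) -> float:
        """Monoisotopic mass in Da."""
        return sum(ELEMENT_MASSES[el] * n for el, n in self.counts.items())

    def hill(self) -> str:
        """Canonical Hill-order formula string (C, H, then alphabetical)."""
        parts = []
        order = [el for el in ("C", "H") if el in self.counts]
        order += sorted(el for el in self.counts if el not in ("C", "H"))
        for el in order:
            n = self.counts[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def __add__(self, other: "Formula") -> "Formula":
        counts = dict(self.counts)
        for el, n in other.counts.items():
            counts[el] = counts.get(el, 0) + n
        return Formula(counts)

    def __sub__(self, other: "Formula") -> "Formula":
        counts = dict(self.counts)
        for el, n in other.counts.items():
            counts[el] = counts.get(el, 0) - n
        return Formula(counts)

    def __mul__(self, k: int) -> "Formula":
        return Formula({el: n * k for el, n in self.counts.items()})

    __rmul__ = __mul__

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


def parse_formula(text: str) -> Formula:
    """Parse a Hill-style formula string such as ``"C27H42O4"``.

    Raises :class:`FormulaError` for empty input, unknown element symbols
    or stray characters.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: Dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaError(f"cannot parse formula {text!r} at {text[pos:]!r}")
        if not m.group(0):
            break
        el, digits = m.group(1), m.group(2)
        if el not in ELEMENT_MASSES:
            raise FormulaError(f"unsupported element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
    if pos != len(text):
        raise FormulaError(f"cannot parse formula {text!r} at {text[pos:]!r}")
    return Formula(counts)


def monoisotopic_mass(f: Formula | str) -> float:
    """Monoisotopic mass (Da) of a formula or formula string."""
    if isinstance(f, str):
        f = parse_formula(f)
    return f.mass


@dataclass(frozen=True)
class AdductSpec:
    """A named electrospray ion species.

    ``delta_mass`` is added to the neutral monoisotopic mass before
    dividing by ``|charge|``; it is electron-corrected (ions are not
    neutral-atom sums).
    """

    name: str
    delta_mass: float
    charge: int
    polarity: str  # "positive" | "negative"

    def mz(self, neutral_mass: float) -> float:
        if neutral_mass <= 0:
            raise ValueError("neutral mass must be positive")
        return (neutral_mass + self.delta_mass) / abs(self.charge)

    def neutral_mass(self, mz: float) -> float:
        return mz * abs(self.charge) - self.delta_mass


_H2O = 2 * ELEMENT_MASSES["H"] + ELEMENT_MASSES["O"]
_NH4 = ELEMENT_MASSES["N"] + 4 * ELEMENT_MASSES["H"]
_HCOO = ELEMENT_MASSES["C"] + ELEMENT_MASSES["H"] + 2 * ELEMENT_MASSES["O"]

#: The seven ion species observed for steroidal saponins in ESI.
ADDUCTS: Dict[str, AdductSpec] = {
    a.name: a
    for a in (
        AdductSpec("[M+H]+", PROTON_MASS, 1, "positive"),
        AdductSpec("[M+Na]+", ELEMENT_MASSES["Na"] - ELECTRON_MASS, 1, "positive"),
        AdductSpec("[M+NH4]+", _NH4 - ELECTRON_MASS, 1, "positive"),
        AdductSpec("[M+H-H2O]+", PROTON_MASS - _H2O, 1, "positive"),
        AdductSpec("[M-H]-", -PROTON_MASS, -1, "negative"),
        AdductSpec("[M+HCOO]-", _HCOO + ELECTRON_MASS, -1, "negative"),
        AdductSpec("[M+2HCOO]2-", 2 * (_HCOO + ELECTRON_MASS), -2, "negative"),
    )
}


def _get_adduct(adduct: AdductSpec | str) -> AdductSpec:
    if isinstance(adduct, AdductSpec):
        return adduct
    try:
        return ADDUCTS[adduct]
    except KeyError:
        raise KeyError(f"unknown adduct name {adduct!r}; known: {sorted(ADDUCTS)}")


def adduct_mz(neutral_mass: float, adduct: AdductSpec | str) -> float:
    """Theoretical m/z of the given ion species for a neutral mass (Da)."""
    return _get_adduct(adduct).mz(neutral_mass)


def neutral_mass_from_mz(mz: float, adduct: AdductSpec | str) -> float:
    """Invert :func:`adduct_mz`: neutral monoisotopic mass implied by an ion."""
    return _get_adduct(adduct).neutral_mass(mz)


def ppm_error(theoretical: float, observed: float) -> float:
    """Signed mass error in ppm: ``(theoretical - observed)/theoretical * 1e6``."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (theoretical - observed) / theoretical * 1e6


#: Neutral losses of the saponin fragment ladder.  Glc/Ara are the
#: dehydrated glycosyl residues; EF144/EF142 are the retro-cleavage of the
#: E/F rings (C8H16O2 for CH3-substituted, C8H14O2 for the 27-hydroxy
#: series, whose quoted 160 Da loss EF160 equals EF142 + H2O in mass).
NEUTRAL_LOSSES: Dict[str, Formula] = {
    "Glc": parse_formula("C6H10O5"),
    "Ara": parse_formula("C5H8O4"),
    "H2O": parse_formula("H2O"),
    "EF144": parse_formula("C8H16O2"),
    "EF142": parse_formula("C8H14O2"),
    "EF160": parse_formula("C8H16O3"),
}


def neutral_loss_mass(label: str) -> float:
    """Monoisotopic mass of a named neutral loss."""
    try:
        return NEUTRAL_LOSSES[label].mass
    except KeyError:
        raise KeyError(f"unknown neutral loss {label!r}; known: {sorted(NEUTRAL_LOSSES)}")


def formulas_total_mass(losses: Iterable[str]) -> float:
    """Total mass of an iterable of neutral-loss labels."""
    return sum(neutral_loss_mass(x) for x in losses)
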