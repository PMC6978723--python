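"""Elemental bookkeeping: formulas, molar masses and degrees of reduction.

Every balance check in the package (per-reaction element closure, chemostat
carbon/electron recoveries) reduces to linear algebra over elemental
formulas. Formulas are real-valued per element so that the per-C-mol biomass
composition CH1.8O0.5N0.2 is a first-class citizen.

The degree of reduction gamma counts electron equivalents per mole relative
to the reference species CO2, H2O and NH3 (Roels convention): 4 per C, 1 per
H, -2 per O, -3 per N, +5 per P, +6 per S. CO2, H2O, NH3, H+ and inorganic
phosphate all have gamma = 0, which is what makes gamma-weighted reaction
sums a pure redox check.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

__all__ = [
    "ElementalFormula",
    "CompoundSpec",
    "CompoundRegistry",
    "FormulaError",
    "parse_formula",
    "degree_of_reduction",
    "molar_mass",
    "load_default_registry",
    "ATOMIC_MASS",
    "GAMMA_PER_ATOM",
]

ELEMENTS = ("C", "H", "O", "N", "P", "S")

# CODATA-consistent standard atomic weights, g/mol
ATOMIC_MASS = {
    "C": 12.011,
    "H": 1.008,
    "O": 15.999,
    "N": 14.007,
    "P": 30.974,
    "S": 32.06,
}

# electron equivalents contributed per atom, reference species CO2/H2O/NH3
GAMMA_PER_ATOM = {"C": 4.0, "H": 1.0, "O": -2.0, "N": -3.0, "P": 5.0, "S": 6.0}


class FormulaError(ValueError):
    """Raised for malformed or empty formula strings."""


@dataclass(frozen=True)
class ElementalFormula:
    """Per-element atom counts; real-valued to admit C-molar biomass formulas."""

    counts: Mapping[str, float]

    def __post_init__(self) -> None:
        clean = {}
        for el, n in self.counts.items():
            if el not in ELEMENTS:
                raise FormulaError(f"unknown element symbol {el!r}")
            if n < 0:
                raise FormulaError(f"negative count for element {el}")
            if n != 0:
                clean[el] = float(n)
        if not clean:
            raise FormulaError("formula has no atoms")
        object.__setattr__(self, "counts", clean)

    def __getitem__(self, el: str) -> float:
        return self.counts.get(el, 0.0)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = {el: self[el] + other[el] for el in ELEMENTS}
        return ElementalFormula(merged)

    def scaled(self, factor: float) -> dict[str, float]:
        """Element counts multiplied by a stoichiometric coefficient (plain dict;
        may be negative, so not an ElementalFormula)."""
        return {el: factor * n for el, n in self.counts.items()}

    def __str__(self) -> str:
        parts = []
        for el in ELEMENTS:
            n = self[el]
            if n == 0:
                continue
            if n == 1:
                parts.append(el)
            elif n == int(n):
                parts.append(f"{el}{int(n)}")
            else:
                parts.append(f"{el}{n:g}")
        return "".join(parts)


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-style formula string such as ``C6H10O7`` or ``CH1.8O0.5N0.2``.

    Subscripts may be real numbers; an omitted subscript means 1; unlisted
    elements are 0. Raises :class:`FormulaError` for empty strings or symbols
    outside C/H/O/N/P/S.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, float] = {}
    pos = 0
    for m in _TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaError(f"cannot parse formula {text!r} at {text[pos:]!r}")
        pos = m.end()
        el, sub = m.group(1), m.group(2)
        if el not in ELEMENTS:
            raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0.0) + (float(sub) if sub else 1.0)
    if pos != len(text):
        raise FormulaError(f"cannot parse formula {text!r} at {text[pos:]!r}")
    return ElementalFormula(counts)


def degree_of_reduction(f: ElementalFormula) -> float:
    """Electron equivalents per mole: 4C + H - 2O - 3N + 5P + 6S."""
    return sum(GAMMA_PER_ATOM[el] * n for el, n in f.counts.items())


def molar_mass(f: ElementalFormula) -> float:
    """Molar mass in g/mol from standard atomic weights."""
    return sum(ATOMIC_MASS[el] * n for el, n in f.counts.items())


@dataclass(frozen=True)
class CompoundSpec:
    """A chemical species: id, name and formula, with derived quantities.

    Organic acids are represented as the neutral, fully protonated species
    (acetic acid C2H4O2, lactic acid C3H6O3, galacturonic acid C6H10O7);
    molar yields are protonation-invariant so no charge bookkeeping is done.
    """

    id: str
    name: str
    formula: ElementalFormula
    pseudo: bool = field(default=False, compare=False)

    @property
    def carbon_count(self) -> float:
        return self.formula["C"]

    @property
    def gamma(self) -> float:
        return degree_of_reduction(self.formula)

    @property
    def molar_mass(self) -> float:
        return molar_mass(self.formula)


class CompoundRegistry:
    """Compound lookup table, loaded from a delimited text file.

    The shipped registry covers every species of the encoded pathway variants
    plus the reference species; users may register additional compounds at
    run time or load an extended file.
    """

    def __init__(self) -> None:
        self._compounds: dict[str, CompoundSpec] = {}

    def add(self, spec: CompoundSpec) -> None:
        if spec.id in self._compounds:
            raise ValueError(f"duplicate compound id {spec.id!r}")
        self._compounds[spec.id] = spec

    def __contains__(self, cid: str) -> bool:
        return cid in self._compounds

    def __getitem__(self, cid: str) -> CompoundSpec:
        try:
            return self._compounds[cid]
        except KeyError:
            raise KeyError(f"compound {cid!r} is not registered") from None

    def __iter__(self) -> Iterator[CompoundSpec]:
        return iter(self._compounds.values())

    def __len__(self) -> int:
        return len(self._compounds)

    @classmethod
    def from_file(cls, path: str | Path) -> "CompoundRegistry":
        """Load a tab-separated registry file: id, name, formula[, pseudo].

        Lines starting with '#' are comments. The 'pseudo' flag marks species
        whose formula is an effective moiety (the acetyl unit of acetyl-CoA)
        rather than a free molecule.
        """
        reg = cls()
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split("\t")]
            if len(parts) < 3:
                raise ValueError(f"registry line needs id, name, formula: {line!r}")
            cid, name, formula = parts[:3]
            pseudo = len(parts) > 3 and parts[3].lower() in {"1", "true", "pseudo"}
            reg.add(CompoundSpec(cid, name, parse_formula(formula), pseudo=pseudo))
        return reg


def load_default_registry() -> CompoundRegistry:
    """The packaged compound registry (all pathway species + references)."""
    path = resources.files("galuferm.data").joinpath("compounds.tsv")
    with resources.as_file(path) as p:
        return CompoundRegistry.from_file(p)
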