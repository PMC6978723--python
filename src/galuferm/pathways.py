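"""Reaction networks for the candidate D-galacturonate fermentation routes.

Four variants are shipped as human-readable definition files:

``canonical_isomerase``
    adapted Entner-Doudoroff route through KDPG and lower glycolysis to
    lactate (12 reactions);
``canonical_isomerase_plus_pdh``
    the same plus a hypothetical PDH/PTA/AckA branch that could couple
    lactate and acetate formation 1:1 at the pyruvate node;
``hybrid_isomerase_pk``
    upper isomerase reactions joined to the phosphoketolase pathway by a
    mannonate kinase and a 6-phosphomannonate 2-epimerase;
``phosphoketolase``
    the phosphoketolase pathway proper, entered at 6-phosphogluconate.

Cofactor pairs (ATP/ADP, NAD+/NADH, NADP+/NADPH) are carried as signed net
deltas per reaction, not as species, so steady-state solutions need no
regeneration pseudo-reactions. Acetyl-CoA, by contrast, carries carbon
between PDH and PTA and therefore *is* a species (its formula is the acetyl
moiety; the CoA handle is implicit). H2O, H+ and inorganic phosphate are
closure species: they are solved per reaction and excluded from steady-state
constraints — the figures of merit (carbon, nitrogen, electron balance) are
invariant to them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

from .biochem import (
    GAMMA_PER_ATOM,
    CompoundRegistry,
    degree_of_reduction,
    load_default_registry,
)

__all__ = [
    "Reaction",
    "PathwayModel",
    "BalanceReport",
    "StoichiometricMatrix",
    "PathwayError",
    "PATHWAY_VARIANTS",
    "TRUNCATIONS",
    "build_pathway",
    "load_pathway_file",
    "check_reaction_balance",
    "stoichiometric_matrix",
]

PATHWAY_VARIANTS = (
    "canonical_isomerase",
    "canonical_isomerase_plus_pdh",
    "phosphoketolase",
    "hybrid_isomerase_pk",
)

COFACTORS = ("ATP", "NADH", "NADPH")
#: placeholder cofactor resolved by the uxub_cofactor build option
_NADPH_OR_NADH = "NAD(P)H"

#: electron equivalents carried per reduced nicotinamide cofactor
ELECTRONS_PER_NADH = 2.0

BALANCE_TOL = 1e-6

# Named truncation points: (reaction ids kept, external species). These give
# the partial conversions used in the redox/ATP accounting: the upper
# pathway to pyruvate + GAP, the full route to two pyruvate, and the hybrid
# upper route to ribulose-5-P + CO2.
TRUNCATIONS: dict[str, dict[str, tuple[tuple[str, ...], frozenset[str]]]] = {
    "canonical_isomerase": {
        "pyruvate_gap": (
            ("UxaC", "UxuE", "UxuB", "UxuA", "KdgK", "KdgA"),
            frozenset({"galua", "pyr", "gap"}),
        ),
        "pyruvate": (
            ("UxaC", "UxuE", "UxuB", "UxuA", "KdgK", "KdgA",
             "GAPDH", "PGK", "PGM", "ENO", "PYK"),
            frozenset({"galua", "pyr"}),
        ),
    },
    "hybrid_isomerase_pk": {
        "ru5p": (
            ("UxaC", "UxuE", "UxuB", "MAK", "MPE", "PGD"),
            frozenset({"galua", "ru5p", "co2"}),
        ),
    },
}


class PathwayError(ValueError):
    """Unknown variant, malformed definition, or invariant violation."""


@dataclass(frozen=True)
class Reaction:
    """One enzymatic step: signed species stoichiometry plus cofactor deltas.

    ``stoichiometry`` maps compound id to a signed rational coefficient
    (negative = consumed). ``cofactor_deltas`` holds the net production of
    ATP, NADH and NADPH per unit flux. ``evidence`` lists the proteome
    evidence keys; a key in ``candidate_evidence`` points to proteins whose
    gene identity for this activity is unresolved and is reported but never
    counted toward pathway completeness.
    """

    id: str
    enzyme_name: str
    ec_number: str | None
    stoichiometry: dict[str, Fraction]
    reversible: bool
    cofactor_deltas: dict[str, Fraction]
    evidence: tuple[str, ...] = ()
    candidate_evidence: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise PathwayError(f"reaction {self.id}: empty stoichiometry")

    @property
    def nad_p_h_delta(self) -> Fraction:
        return (self.cofactor_deltas.get("NADH", Fraction(0))
                + self.cofactor_deltas.get("NADPH", Fraction(0)))


@dataclass
class PathwayModel:
    """A pathway variant: reactions, substrate and designated external species."""

    name: str
    reactions: list[Reaction]
    substrate: str
    external_species: frozenset[str]
    registry: CompoundRegistry
    options: dict = field(default_factory=dict)

    @property
    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.reactions:
            for cid in r.stoichiometry:
                seen.setdefault(cid)
        return list(seen)

    @property
    def internal_species(self) -> list[str]:
        return [s for s in self.species if s not in self.external_species]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(f"no reaction {rid!r} in pathway {self.name}")

    def validate(self) -> None:
        """Enforce structural invariants and per-reaction element balance."""
        ids = [r.id for r in self.reactions]
        if len(set(ids)) != len(ids):
            raise PathwayError(f"duplicate reaction ids in {self.name}")
        if self.substrate not in self.external_species:
            raise PathwayError(f"substrate {self.substrate} must be external")
        produced: set[str] = set()
        consumed: set[str] = set()
        for r in self.reactions:
            for cid, coef in r.stoichiometry.items():
                if cid not in self.registry:
                    raise PathwayError(
                        f"reaction {r.id}: compound {cid!r} is not registered")
                (produced if coef > 0 else consumed).add(cid)
            rep = check_reaction_balance(r, self.registry)
            if not rep.closed:
                raise PathwayError(
                    f"reaction {r.id} does not balance: {rep.residuals}")
        for s in self.internal_species:
            if s not in produced or s not in consumed:
                raise PathwayError(
                    f"internal species {s!r} lacks a producer or consumer")


class BalanceReport(NamedTuple):
    """Element residuals of one reaction after implicit closure.

    ``residuals`` holds products-minus-reactants atom residuals per element;
    H, O and P are reported after solving for the closure species (water,
    inorganic phosphate, protons), whose stoichiometries appear in
    ``closure``. ``gamma_residual`` is the degree-of-reduction imbalance with
    reduced nicotinamide cofactors counting 2 electrons each.
    """

    residuals: dict[str, float]
    closure: dict[str, float]
    gamma_residual: float
    closed: bool


def check_reaction_balance(
    r: Reaction, registry: CompoundRegistry | None = None, tol: float = BALANCE_TOL
) -> BalanceReport:
    """Verify elemental and electron closure of a single reaction.

    Cofactor deltas contribute elements: each net NAD(P)H stores two hydrogen
    atoms (and two electrons); each net ATP stores one phosphoryl (HPO3)
    group. After adding those, the H/O/P residual is absorbed exactly by
    water, phosphate and protons (all with zero degree of reduction), so the
    binding checks are carbon, nitrogen, sulfur and the electron balance.
    """
    registry = registry or load_default_registry()
    res = {el: 0.0 for el in ("C", "H", "O", "N", "P", "S")}
    gamma = 0.0
    for cid, coef in r.stoichiometry.items():
        spec = registry[cid]
        for el, n in spec.formula.counts.items():
            res[el] += float(coef) * n
        gamma += float(coef) * spec.gamma
    nad = float(r.nad_p_h_delta)
    atp = float(r.cofactor_deltas.get("ATP", Fraction(0)))
    res["H"] += 2.0 * nad + 1.0 * atp
    res["O"] += 3.0 * atp
    res["P"] += 1.0 * atp
    gamma += ELECTRONS_PER_NADH * nad  # gamma(HPO3) = 0, so ATP adds nothing

    pi = -res["P"]
    h2o = -res["O"] - 4.0 * pi
    h = -(res["H"] + 2.0 * h2o + 3.0 * pi)
    closure = {"h2o": h2o, "pi": pi, "h": h}
    res["H"] = res["O"] = res["P"] = 0.0

    hard = max(abs(res["C"]), abs(res["N"]), abs(res["S"]), abs(gamma))
    return BalanceReport(res, closure, gamma, closed=hard <= tol)


class StoichiometricMatrix(NamedTuple):
    """Dense species-by-reaction matrix with its index maps."""

    matrix: np.ndarray
    species: list[str]
    reactions: list[str]

    def row(self, cid: str) -> np.ndarray:
        return self.matrix[self.species.index(cid)]


def stoichiometric_matrix(p: PathwayModel) -> StoichiometricMatrix:
    """Signed coefficient matrix: entry (i, j) of species i in reaction j."""
    species = p.species
    idx = {s: i for i, s in enumerate(species)}
    mat = np.zeros((len(species), len(p.reactions)))
    for j, r in enumerate(p.reactions):
        for cid, coef in r.stoichiometry.items():
            mat[idx[cid], j] = float(coef)
    return StoichiometricMatrix(mat, species, [r.id for r in p.reactions])


# --- definition-file parsing -------------------------------------------------

def _parse_equation(eq: str) -> tuple[dict[str, Fraction], dict[str, Fraction]]:
    """Parse ``a + 2 b -> c`` into species stoichiometry and cofactor deltas.

    Cofactor tokens (ATP, NADH, NADPH, NAD(P)H) may appear on either side and
    become signed deltas; an integer or rational prefix is a coefficient.
    """
    if "->" not in eq:
        raise PathwayError(f"equation needs '->': {eq!r}")
    left, right = eq.split("->", 1)
    stoich: dict[str, Fraction] = {}
    cof: dict[str, Fraction] = {}

    def add(side: str, sign: int) -> None:
        for term in side.split("+"):
            term = term.strip()
            if not term:
                continue
            parts = term.split()
            coef = Fraction(1)
            if len(parts) == 2:
                coef, name = Fraction(parts[0]), parts[1]
            elif len(parts) == 1:
                name = parts[0]
            else:
                raise PathwayError(f"cannot parse term {term!r} in {eq!r}")
            if name in COFACTORS or name == _NADPH_OR_NADH:
                cof[name] = cof.get(name, Fraction(0)) + sign * coef
            else:
                stoich[name] = stoich.get(name, Fraction(0)) + sign * coef

    add(left, -1)
    add(right, +1)
    return stoich, cof


def _parse_pathway_text(text: str) -> tuple[str, str, frozenset[str], list[Reaction]]:
    name = substrate = None
    externals: frozenset[str] = frozenset()
    reactions: list[Reaction] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            for key in ("pathway", "substrate", "externals"):
                if body.startswith(key + ":"):
                    val = body[len(key) + 1:].strip()
                    if key == "pathway":
                        name = val
                    elif key == "substrate":
                        substrate = val
                    else:
                        externals = frozenset(val.split())
            continue
        fields = [f.strip() for f in line.split("|")]
        if len(fields) != 6:
            raise PathwayError(f"reaction line needs 6 '|' fields: {line!r}")
        rid, enzyme, ec, eq, rev, evidence = fields
        stoich, cof = _parse_equation(eq)
        keys = evidence.split()
        reactions.append(Reaction(
            id=rid,
            enzyme_name=enzyme,
            ec_number=None if ec in {"-", ""} else ec,
            stoichiometry=stoich,
            reversible={"rev": True, "irr": False}[rev],
            cofactor_deltas=cof,
            evidence=tuple(k for k in keys if not k.endswith("?")),
            candidate_evidence=tuple(k[:-1] for k in keys if k.endswith("?")),
        ))
    if name is None or substrate is None or not externals:
        raise PathwayError("pathway file must declare pathway, substrate, externals")
    return name, substrate, externals, reactions


def load_pathway_file(
    path: str | Path, registry: CompoundRegistry | None = None
) -> PathwayModel:
    """Load (and validate) a user-supplied pathway definition file."""
    name, substrate, externals, reactions = _parse_pathway_text(
        Path(path).read_text())
    model = PathwayModel(name, reactions, substrate, externals,
                         registry or load_default_registry())
    model.validate()
    return model


def build_pathway(
    variant: str,
    uxub_cofactor: str | None = None,
    truncate: str | None = None,
    transhydrogenase: bool = False,
    registry: CompoundRegistry | None = None,
) -> PathwayModel:
    """Build one of the shipped pathway variants.

    Parameters
    ----------
    variant
        One of ``canonical_isomerase``, ``canonical_isomerase_plus_pdh``,
        ``phosphoketolase``, ``hybrid_isomerase_pk``.
    uxub_cofactor
        Which reduced cofactor fructuronate reductase consumes: "NADH" or
        "NADPH". Default: NADH for the canonical variants (the textbook
        cofactor), NADPH for the hybrid (the cofactor match with NADP+-linked
        6-phosphogluconate dehydrogenase that makes the upper hybrid route
        redox-neutral within the NADPH pool).
    truncate
        Optional named truncation point (e.g. ``"pyruvate"`` on the
        canonical variant, ``"ru5p"`` on the hybrid) selecting the partial
        route and its external sink species.
    transhydrogenase
        Whether an NADH/NADPH-interconverting transhydrogenase is assumed;
        recorded in the model options and used by cofactor summaries.
    """
    if variant not in PATHWAY_VARIANTS:
        raise PathwayError(
            f"unknown pathway variant {variant!r}; valid: {', '.join(PATHWAY_VARIANTS)}")
    registry = registry or load_default_registry()
    path = resources.files("galuferm.data.pathways").joinpath(variant + ".txt")
    name, substrate, externals, reactions = _parse_pathway_text(path.read_text())

    if uxub_cofactor is None:
        uxub_cofactor = "NADPH" if variant == "hybrid_isomerase_pk" else "NADH"
    if uxub_cofactor not in ("NADH", "NADPH"):
        raise PathwayError(f"uxub_cofactor must be NADH or NADPH, got {uxub_cofactor!r}")
    resolved = []
    for r in reactions:
        if _NADPH_OR_NADH in r.cofactor_deltas:
            cof = dict(r.cofactor_deltas)
            delta = cof.pop(_NADPH_OR_NADH)
            cof[uxub_cofactor] = cof.get(uxub_cofactor, Fraction(0)) + delta
            r = Reaction(r.id, r.enzyme_name, r.ec_number, r.stoichiometry,
                         r.reversible, cof, r.evidence, r.candidate_evidence)
        resolved.append(r)
    reactions = resolved

    if truncate is not None:
        presets = TRUNCATIONS.get(variant, {})
        if truncate not in presets:
            raise PathwayError(
                f"unknown truncation {truncate!r} for {variant}; "
                f"valid: {', '.join(presets) or '(none)'}")
        keep, externals = presets[truncate]
        order = {rid: i for i, rid in enumerate(keep)}
        reactions = sorted((r for r in reactions if r.id in keep),
                           key=lambda r: order[r.id])

    model = PathwayModel(
        name=name, reactions=reactions, substrate=substrate,
        external_species=externals, registry=registry,
        options={"uxub_cofactor": uxub_cofactor,
                 "transhydrogenase": transhydrogenase,
                 "truncate": truncate},
    )
    model.validate()
    return model
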