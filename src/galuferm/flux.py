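"""Steady-state net conversions, ATP/redox deltas and product feasibility.

The central object is the *net conversion*: the externally visible overall
stoichiometry of a pathway when every internal metabolite is at steady
state, normalized to one mole of substrate consumed, together with the net
ATP, NADH and NADPH produced. For an unbranched route this is a unique flux
ray and is solved exactly over the rationals (sympy nullspace), which makes
the redox-neutrality and ATP-yield statements deterministic identities
rather than numerical approximations. Branched product questions ("can this
variant make lactate and acetate 1:1?") are posed as linear feasibility
problems and solved with an LP.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import sympy
from scipy.optimize import linprog

from .pathways import PathwayModel, stoichiometric_matrix

__all__ = [
    "NetConversion",
    "CofactorSummary",
    "FeasibilityResult",
    "FluxError",
    "DisconnectedPathwayError",
    "UnderdeterminedError",
    "net_conversion",
    "cofactor_summary",
    "product_profile_feasible",
    "atp_yield",
]


class FluxError(ValueError):
    """Base class for steady-state solution failures."""


class DisconnectedPathwayError(FluxError):
    """No steady-state flux can carry substrate to the external sinks."""


class UnderdeterminedError(FluxError):
    """The steady-state flux ray is not unique (a free branch exists)."""

    def __init__(self, free_reactions: list[str]):
        self.free_reactions = free_reactions
        super().__init__(
            "steady-state flux is underdetermined; free reactions: "
            + ", ".join(free_reactions))


@dataclass(frozen=True)
class NetConversion:
    """Overall external stoichiometry per ``uptake`` moles of substrate."""

    pathway: str
    uptake: Fraction
    net_stoichiometry: dict[str, Fraction]
    atp_delta: Fraction
    nadh_delta: Fraction
    nadph_delta: Fraction
    flux_vector: dict[str, Fraction]

    @property
    def nad_p_h_combined(self) -> Fraction:
        return self.nadh_delta + self.nadph_delta

    def as_floats(self) -> dict:
        return {
            "pathway": self.pathway,
            "uptake": float(self.uptake),
            "net_stoichiometry": {k: float(v) for k, v in self.net_stoichiometry.items()},
            "atp_delta": float(self.atp_delta),
            "nadh_delta": float(self.nadh_delta),
            "nadph_delta": float(self.nadph_delta),
            "nad_p_h_combined": float(self.nad_p_h_combined),
            "flux_vector": {k: float(v) for k, v in self.flux_vector.items()},
        }


def _exact_internal_matrix(p: PathwayModel) -> tuple[sympy.Matrix, list[str]]:
    internals = p.internal_species
    idx = {s: i for i, s in enumerate(internals)}
    mat = sympy.zeros(len(internals), len(p.reactions))
    for j, r in enumerate(p.reactions):
        for cid, coef in r.stoichiometry.items():
            if cid in idx:
                mat[idx[cid], j] = sympy.Rational(coef.numerator, coef.denominator)
    return mat, internals


def net_conversion(p: PathwayModel, uptake: float | Fraction = 1) -> NetConversion:
    """Solve the unit-uptake steady-state flux and sum it to a net conversion.

    Solves S_internal · v = 0 with the substrate uptake fixed at ``uptake``
    and requires all irreversible fluxes to be non-negative. Raises
    :class:`DisconnectedPathwayError` when no such flux exists and
    :class:`UnderdeterminedError` (naming the free reactions) when the ray
    is not unique.
    """
    uptake = Fraction(uptake).limit_denominator(10**9) if not isinstance(
        uptake, (int, Fraction)) else Fraction(uptake)
    mat, _ = _exact_internal_matrix(p)
    null = mat.nullspace()
    if not null:
        raise DisconnectedPathwayError(
            f"pathway {p.name} admits no nonzero steady-state flux")

    # substrate row (substrate is external, so not part of the constraints)
    sub_row = [Fraction(0)] * len(p.reactions)
    for j, r in enumerate(p.reactions):
        sub_row[j] = r.stoichiometry.get(p.substrate, Fraction(0))

    def dot(vec: sympy.Matrix) -> sympy.Rational:
        return sum(sympy.Rational(c.numerator, c.denominator) * vec[j]
                   for j, c in enumerate(sub_row))

    carrying = [v for v in null if dot(v) != 0]
    free = [v for v in null if dot(v) == 0]
    if not carrying:
        raise DisconnectedPathwayError(
            f"pathway {p.name}: no steady-state flux consumes {p.substrate}")
    if free or len(carrying) > 1:
        # any second carrying vector yields an uptake-neutral difference
        directions = free + [carrying[0] * dot(v) - v * dot(carrying[0])
                             for v in carrying[1:]]
        names = sorted({p.reactions[j].id
                        for d in directions for j in range(len(p.reactions))
                        if sympy.simplify(d[j]) != 0})
        raise UnderdeterminedError(names)

    ray = carrying[0]
    scale = sympy.Rational(-1, 1) * uptake.numerator / (
        dot(ray) * uptake.denominator)
    v = [sympy.nsimplify(ray[j] * scale) for j in range(len(p.reactions))]

    flux: dict[str, Fraction] = {}
    for j, r in enumerate(p.reactions):
        q = sympy.Rational(v[j])
        fj = Fraction(int(q.p), int(q.q))
        if not r.reversible and fj < 0:
            raise FluxError(
                f"pathway {p.name}: irreversible reaction {r.id} would need "
                f"negative flux {fj}")
        flux[r.id] = fj

    net: dict[str, Fraction] = {}
    atp = nadh = nadph = Fraction(0)
    for r in p.reactions:
        fj = flux[r.id]
        for cid, coef in r.stoichiometry.items():
            if cid in p.external_species:
                net[cid] = net.get(cid, Fraction(0)) + coef * fj
        atp += r.cofactor_deltas.get("ATP", Fraction(0)) * fj
        nadh += r.cofactor_deltas.get("NADH", Fraction(0)) * fj
        nadph += r.cofactor_deltas.get("NADPH", Fraction(0)) * fj
    net = {k: v for k, v in net.items() if v != 0 or k == p.substrate}
    return NetConversion(p.name, uptake, net, atp, nadh, nadph, flux)


@dataclass(frozen=True)
class CofactorSummary:
    """ATP and redox cofactor totals of a net conversion.

    With a transhydrogenase assumed, NADH and NADPH are interconvertible and
    only the pooled NAD(P)H total is physiologically meaningful. Without
    one, the two pools are reported separately and ``imbalance`` flags the
    situation where the pooled total closes but the individual pools do not
    — the cofactor-matching problem that NADPH-linked fructuronate reductase
    resolves in the hybrid route.
    """

    values: dict[str, float]
    imbalance: bool


def cofactor_summary(n: NetConversion, transhydrogenase: bool) -> CofactorSummary:
    pooled = float(n.nad_p_h_combined)
    if transhydrogenase:
        return CofactorSummary(
            {"ATP": float(n.atp_delta), "NAD(P)H": pooled}, imbalance=False)
    sep = {"ATP": float(n.atp_delta), "NADH": float(n.nadh_delta),
           "NADPH": float(n.nadph_delta), "NAD(P)H": pooled}
    flag = pooled == 0 and (n.nadh_delta != 0 or n.nadph_delta != 0)
    return CofactorSummary(sep, imbalance=flag)


@dataclass(frozen=True)
class FeasibilityResult:
    """Outcome of a product-profile feasibility question."""

    feasible: bool
    flux_vector: dict[str, float] | None
    residual: float | None
    certificate: dict | None


def product_profile_feasible(
    p: PathwayModel,
    target_yields: dict[str, float],
    tolerance: float = 0.05,
    require_redox_neutral: bool = False,
) -> FeasibilityResult:
    """Can the pathway realize the given product yields (mol/mol substrate)?

    Linear feasibility: internal steady state, unit substrate uptake,
    irreversibility bounds, each target yield within ``tolerance``, and
    (optionally) zero net NAD(P)H. On infeasibility the certificate reports
    any structurally unreachable targets (no producing reaction) alongside
    the constraint set that could not be satisfied.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    sm = stoichiometric_matrix(p)
    absent: list[str] = []
    for cid in target_yields:
        if cid in p.external_species:
            continue
        if cid in sm.species:
            raise ValueError(
                f"target {cid!r} is an internal species of {p.name}")
        if cid not in p.registry:
            raise ValueError(f"target {cid!r} is not a registered compound")
        absent.append(cid)  # variant has no reaction touching it: yield is 0
    n_rx = len(p.reactions)
    internals = p.internal_species

    a_eq = [sm.row(s) for s in internals]
    b_eq = [0.0] * len(internals)
    a_eq.append(sm.row(p.substrate))
    b_eq.append(-1.0)
    if require_redox_neutral:
        a_eq.append(np.array([float(r.nad_p_h_delta) for r in p.reactions]))
        b_eq.append(0.0)

    a_ub, b_ub = [], []
    for cid, y in target_yields.items():
        row = np.zeros(n_rx) if cid in absent else sm.row(cid)
        a_ub.append(row)
        b_ub.append(y + tolerance)
        a_ub.append(-row)
        b_ub.append(-(y - tolerance))

    bounds = [(0.0, None) if not r.reversible else (None, None)
              for r in p.reactions]
    res = linprog(
        c=np.zeros(n_rx), A_ub=np.array(a_ub), b_ub=np.array(b_ub),
        A_eq=np.array(a_eq), b_eq=np.array(b_eq), bounds=bounds,
        method="highs")

    if res.status == 0:
        v = res.x
        resid = max(abs((0.0 if cid in absent else float(sm.row(cid) @ v)) - y)
                    for cid, y in target_yields.items())
        return FeasibilityResult(
            feasible=True,
            flux_vector={r.id: float(v[j]) for j, r in enumerate(p.reactions)},
            residual=resid, certificate=None)

    unreachable = [cid for cid, y in target_yields.items()
                   if y - tolerance > 0 and not any(
                       r.stoichiometry.get(cid, Fraction(0)) > 0
                       for r in p.reactions)]
    cert = {
        "status": "infeasible",
        "unreachable_targets": unreachable,
        "targets": dict(target_yields),
        "tolerance": tolerance,
        "require_redox_neutral": require_redox_neutral,
        "constraints": ["internal steady state", "unit substrate uptake",
                        "irreversible fluxes >= 0"]
                       + [f"|yield({c}) - {y}| <= {tolerance}"
                          for c, y in target_yields.items()]
                       + (["net NAD(P)H = 0"] if require_redox_neutral else []),
    }
    return FeasibilityResult(False, None, None, cert)


def atp_yield(p: PathwayModel) -> Fraction:
    """Net ATP per mole of substrate for the pathway's unit-uptake conversion."""
    return net_conversion(p, 1).atp_delta
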