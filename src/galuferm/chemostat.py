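"""Rate-to-yield reconciliation for chemostat cultures and batch growth rates.

A steady-state chemostat record holds biomass-specific conversion rates
q_i (mmol per gram dry biomass per hour, negative for consumption) at a
dilution rate D. At steady state the specific growth rate equals D, so the
biomass "rate" needed by the carbon and electron balances follows from D
and the C-molar biomass mass without a separate measurement:

    q_x = D / M_x * 1000        [mC-mol g^-1 h^-1],  M_x = 24.63 g/C-mol

for the ash-free composition CH1.8O0.5N0.2. Recoveries are then

    C recovery = (sum_products q_i C_i + q_x) / (|q_s| C_s)
    e recovery = (sum_products q_i g_i + q_x g_x) / (|q_s| g_s)

with g the degree of reduction (CO2 contributes zero electrons). Both are
invariant to a common rescaling of all rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .biochem import (
    CompoundRegistry,
    ElementalFormula,
    degree_of_reduction,
    load_default_registry,
    molar_mass,
    parse_formula,
)

__all__ = [
    "ChemostatRecord",
    "ReconciliationReport",
    "BatchTimeCourse",
    "yields_from_rates",
    "biomass_yield",
    "carbon_balance",
    "electron_balance",
    "reconcile",
    "estimate_mu_batch",
    "DEFAULT_BIOMASS_FORMULA",
]

DEFAULT_BIOMASS_FORMULA = "CH1.8O0.5N0.2"


@dataclass
class ChemostatRecord:
    """Measured biomass-specific rates of one steady-state chemostat."""

    dilution_rate: float                      # 1/h
    rates: dict[str, float]                   # compound id -> mmol g^-1 h^-1
    substrate_id: str = "galua"
    biomass_formula: ElementalFormula = field(
        default_factory=lambda: parse_formula(DEFAULT_BIOMASS_FORMULA))
    registry: CompoundRegistry = field(default_factory=load_default_registry)
    biomass_rate: float | None = None         # optional explicit q_x override

    def __post_init__(self) -> None:
        if self.dilution_rate <= 0:
            raise ValueError("dilution rate must be positive")
        if self.substrate_id not in self.rates:
            raise ValueError(f"no rate given for substrate {self.substrate_id!r}")
        if self.rates[self.substrate_id] >= 0:
            raise ValueError("substrate rate must be negative (consumption)")
        for cid in self.rates:
            if cid not in self.registry:
                raise KeyError(f"compound {cid!r} is not registered")

    @property
    def q_substrate(self) -> float:
        return self.rates[self.substrate_id]

    @property
    def biomass_cmol_mass(self) -> float:
        """Gram per C-mol of the (per-carbon normalized) biomass formula."""
        f = self.biomass_formula
        return molar_mass(f) / f["C"]

    @property
    def q_biomass(self) -> float:
        """Biomass formation rate in mC-mol g^-1 h^-1 (mu = D at steady state)."""
        if self.biomass_rate is not None:
            return self.biomass_rate
        return self.dilution_rate / self.biomass_cmol_mass * 1e3


@dataclass(frozen=True)
class ReconciliationReport:
    """Yields, biomass yield and balance closures of one chemostat record."""

    yields: dict[str, float]                  # mol (mol substrate)^-1
    biomass_yield: float                      # g biomass (g substrate)^-1
    carbon_recovery: float
    electron_recovery: float
    dilution_rate: float
    substrate_id: str

    def as_dict(self) -> dict:
        return {
            "dilution_rate": self.dilution_rate,
            "substrate_id": self.substrate_id,
            "yields": dict(self.yields),
            "biomass_yield": self.biomass_yield,
            "carbon_recovery": self.carbon_recovery,
            "electron_recovery": self.electron_recovery,
        }


def yields_from_rates(rec: ChemostatRecord, round_to: int | None = 2) -> dict[str, float]:
    """Molar product yields q_i / |q_s|, rounded to ``round_to`` decimals.

    Rounding defaults to 2 decimals, the precision at which chemostat yield
    tables are conventionally reported; pass ``None`` for full precision.
    """
    qs = abs(rec.q_substrate)
    if qs == 0:
        raise ZeroDivisionError("substrate rate is zero; yields undefined")
    out = {}
    for cid, q in rec.rates.items():
        if cid == rec.substrate_id:
            continue
        y = q / qs
        out[cid] = round(y, round_to) if round_to is not None else y
    return out


def biomass_yield(rec: ChemostatRecord) -> float:
    """Y_xs = D / (|q_s| * M_s) in g biomass per g substrate (mu = D)."""
    qs = abs(rec.q_substrate)
    if qs == 0:
        raise ZeroDivisionError("substrate rate is zero; biomass yield undefined")
    m_s = rec.registry[rec.substrate_id].molar_mass
    return rec.dilution_rate / (qs * 1e-3 * m_s)


def carbon_balance(rec: ChemostatRecord) -> float:
    """Fraction of consumed substrate carbon recovered in products + biomass."""
    qs = abs(rec.q_substrate)
    c_s = rec.registry[rec.substrate_id].carbon_count
    out = sum(q * rec.registry[cid].carbon_count
              for cid, q in rec.rates.items() if cid != rec.substrate_id)
    out += rec.q_biomass  # 1 C per C-mol by construction
    return out / (qs * c_s)


def electron_balance(rec: ChemostatRecord) -> float:
    """Fraction of consumed substrate electrons recovered (CO2 contributes 0)."""
    qs = abs(rec.q_substrate)
    g_s = rec.registry[rec.substrate_id].gamma
    out = sum(q * rec.registry[cid].gamma
              for cid, q in rec.rates.items() if cid != rec.substrate_id)
    f = rec.biomass_formula
    out += rec.q_biomass * degree_of_reduction(f) / f["C"]
    return out / (qs * g_s)


def reconcile(rec: ChemostatRecord, round_yields: int | None = 2,
              round_recoveries: int | None = 3) -> ReconciliationReport:
    """Full report: yields, biomass yield and both balance closures."""
    rnd = (lambda x: round(x, round_recoveries)) if round_recoveries is not None \
        else (lambda x: x)
    return ReconciliationReport(
        yields=yields_from_rates(rec, round_yields),
        biomass_yield=biomass_yield(rec),
        carbon_recovery=rnd(carbon_balance(rec)),
        electron_recovery=rnd(electron_balance(rec)),
        dilution_rate=rec.dilution_rate,
        substrate_id=rec.substrate_id,
    )


@dataclass
class BatchTimeCourse:
    """A batch culture time course: biomass proxy and concentrations vs time."""

    time: np.ndarray                          # h, strictly increasing
    biomass: np.ndarray                       # OD or g/L
    concentrations: dict[str, np.ndarray] = field(default_factory=dict)  # g/L

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.biomass = np.asarray(self.biomass, dtype=float)
        if self.time.ndim != 1 or len(self.time) != len(self.biomass):
            raise ValueError("time and biomass must be 1-D and equally long")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.biomass < 0):
            raise ValueError("biomass measurements must be non-negative")
        self.concentrations = {k: np.asarray(v, dtype=float)
                               for k, v in self.concentrations.items()}
        for k, v in self.concentrations.items():
            if len(v) != len(self.time):
                raise ValueError(f"concentration series {k!r} length mismatch")


def estimate_mu_batch(
    tc: BatchTimeCourse, window: tuple[float, float]
) -> tuple[float, float]:
    """Specific growth rate (1/h) and its standard error over a time window.

    Least-squares slope of ln(biomass) against time for points with
    window[0] <= t <= window[1]. The window is user-chosen: automatic
    exponential-phase detection is deliberately not attempted.
    """
    t0, t1 = window
    mask = (tc.time >= t0) & (tc.time <= t1)
    if mask.sum() < 3:
        raise ValueError("need at least 3 time points inside the window")
    x = tc.time[mask]
    od = tc.biomass[mask]
    if np.any(od <= 0):
        raise ValueError("non-positive biomass value inside the window")
    fit = stats.linregress(x, np.log(od))
    return float(fit.slope), float(fit.stderr)
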