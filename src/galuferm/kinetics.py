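"""Michaelis-Menten and substrate-inhibition fits for coupled enzyme assays.

Rate laws::

    MM:  v = V_max * S / (K_M + S)
    SI:  v = V_max * S / (K_M + S + S^2 / K_i)

The substrate-inhibition curve has a single interior maximum at
S* = sqrt(K_M * K_i). Fits are direct nonlinear least squares on the
untransformed rate equation (never a Lineweaver-Burk linearization, whose
error structure is badly biased), with positivity bounds and data-driven
starting values: V_max from the largest observed rate, K_M from the
substrate concentration nearest half of it, K_i at ten times the largest
concentration.

Rates from assays that lack a demonstrated excess of coupling enzyme only
support *apparent* kinetic constants; such fits can be tagged and the tag
is carried into every report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lmfit import Model

__all__ = [
    "KineticsDataset",
    "KineticParams",
    "FitNotConvergedError",
    "model_rate",
    "fit_kinetics",
]

MODELS = ("MM", "SI")


class FitNotConvergedError(RuntimeError):
    """Nonlinear least squares failed to converge; carries the final residual."""


@dataclass
class KineticsDataset:
    """Substrate concentrations (mM) and specific activities of one assay."""

    substrate_mm: np.ndarray
    rate: np.ndarray              # umol (mg protein)^-1 min^-1
    enzyme: str = ""
    apparent: bool = False        # coupling-enzyme excess not demonstrated

    def __post_init__(self) -> None:
        self.substrate_mm = np.asarray(self.substrate_mm, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.substrate_mm.shape != self.rate.shape or self.substrate_mm.ndim != 1:
            raise ValueError("substrate and rate must be matching 1-D arrays")
        if np.any(self.substrate_mm < 0):
            raise ValueError("substrate concentrations must be non-negative")

    def __len__(self) -> int:
        return len(self.substrate_mm)


@dataclass(frozen=True)
class KineticParams:
    """Fitted (or assumed) kinetic constants with asymptotic standard errors."""

    model: str                    # "MM" or "SI"
    v_max: float                  # umol mg^-1 min^-1
    k_m: float                    # mM
    k_i: float | None = None      # mM, SI only
    stderr: dict[str, float | None] = field(default_factory=dict)
    rss: float | None = None
    apparent: bool = False
    mismatch_flag: bool = False   # systematic residual trend at high S

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        if self.v_max <= 0 or self.k_m <= 0:
            raise ValueError("V_max and K_M must be positive")
        if self.model == "SI" and (self.k_i is None or self.k_i <= 0):
            raise ValueError("SI model needs a positive K_i")

    @property
    def optimum_s(self) -> float | None:
        """Rate-maximizing substrate concentration sqrt(K_M*K_i) (SI only)."""
        if self.model != "SI":
            return None
        return float(np.sqrt(self.k_m * self.k_i))

    def as_dict(self) -> dict:
        return {
            "model": self.model, "v_max": self.v_max, "k_m": self.k_m,
            "k_i": self.k_i, "stderr": dict(self.stderr), "rss": self.rss,
            "apparent": self.apparent, "mismatch_flag": self.mismatch_flag,
        }


def model_rate(s, params: KineticParams):
    """Evaluate the rate law at substrate concentration(s) ``s`` (mM)."""
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr < 0):
        raise ValueError("substrate concentration must be non-negative")
    if params.model == "MM":
        v = params.v_max * s_arr / (params.k_m + s_arr)
    else:
        v = params.v_max * s_arr / (params.k_m + s_arr + s_arr**2 / params.k_i)
    return float(v) if np.isscalar(s) else v


def _mm(s, v_max, k_m):
    return v_max * s / (k_m + s)


def _si(s, v_max, k_m, k_i):
    return v_max * s / (k_m + s + s**2 / k_i)


def fit_kinetics(
    d: KineticsDataset, model: str = "MM", start: KineticParams | None = None
) -> KineticParams:
    """Fit MM or SI constants to an assay dataset by nonlinear least squares."""
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    n_par = 2 if model == "MM" else 3
    if len(d) < n_par + 2:
        raise ValueError(
            f"{model} fit needs at least {n_par + 2} points, got {len(d)}")

    s, v = d.substrate_mm, d.rate
    v_max0 = start.v_max if start else max(float(v.max()), 1e-9)
    if start:
        k_m0 = start.k_m
    else:
        half = v_max0 / 2.0
        k_m0 = max(float(s[np.argmin(np.abs(v - half))]), 1e-6)
    k_i0 = (start.k_i if start and start.k_i else 10.0 * float(s.max()))

    lm = Model(_mm if model == "MM" else _si, independent_vars=["s"])
    pars = lm.make_params(v_max=dict(value=v_max0, min=1e-12),
                          k_m=dict(value=k_m0, min=1e-9))
    if model == "SI":
        pars.add("k_i", value=k_i0, min=1e-9)
    result = lm.fit(v, pars, s=s)
    if not result.success:
        raise FitNotConvergedError(
            f"{model} fit did not converge; final residual {result.chisqr}")

    best = result.params
    resid = v - result.best_fit
    # model-mismatch diagnostic: the upper-concentration half of the data
    # sitting systematically below the fitted curve indicates inhibition
    # that a plain MM model cannot express
    order = np.argsort(s)
    hi = resid[order][len(s) // 2:]
    sigma = float(np.sqrt(result.chisqr / max(len(s) - n_par, 1)))
    floor = 1e-9 * float(best["v_max"].value)   # ignore machine-level residuals
    mismatch = bool(
        model == "MM" and len(hi) >= 3 and sigma > floor
        and float(np.mean(hi)) < -max(0.5 * sigma / np.sqrt(len(hi)), floor)
        and float(np.median(hi)) < 0)

    return KineticParams(
        model=model,
        v_max=float(best["v_max"].value),
        k_m=float(best["k_m"].value),
        k_i=float(best["k_i"].value) if model == "SI" else None,
        stderr={name: (None if best[name].stderr is None else float(best[name].stderr))
                for name in best},
        rss=float(result.chisqr),
        apparent=d.apparent,
        mismatch_flag=mismatch,
    )
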