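"""Yields, maintenance energetics and reactor arithmetic.

Stoichiometric yields are ratios of reconciled steady-state volumetric
conversion rates, with standard deviations by first-order (linear) error
propagation of the relative errors.  The maintenance requirement is
estimated from the dilution-rate dependence of the growth yield via the
Herbert-Pirt relation

    q_s = D / Y_max + m_s        <=>        1/Y = 1/Y_max + m_s / D

so an ordinary least-squares line of 1/Y on 1/D has slope m_s (substrate
per biomass per hour spent on non-growth functions) and intercept
1/Y_max.  Dissolved N2O follows Henry's law; in a membrane bioreactor
the biomass dilution rate is set by the solids retention time D = 1/SRT.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from .reconciliation import ReconciliationResult
from .stoichiometry import ElementalComposition, parse_formula

__all__ = [
    "Measurement",
    "YieldSet",
    "PirtFit",
    "ChemostatCondition",
    "compute_yields",
    "yields_from_result",
    "estimate_maintenance",
    "dissolved_gas",
    "dilution_rate_from_srt",
    "HENRY_N2O",
]

#: Henry's constant for N2O at the 20 degC operating point, mmol/(L*Pa)
HENRY_N2O = 2.4e-4


class Measurement(NamedTuple):
    """A value with its standard deviation."""

    value: float
    sd: float


@dataclass(frozen=True)
class YieldSet:
    """The four steady-state stoichiometric yields of the enrichment.

    y_x_ac    biomass on acetate, C-mol/C-mol
    y_x_n2o   biomass on N2O, C-mol/mol
    y_n2o_ac  N2O on acetate, mol/mol
    y_nh4_x   ammonium per biomass, mol/C-mol
    """

    y_x_ac: Measurement
    y_x_n2o: Measurement
    y_n2o_ac: Measurement
    y_nh4_x: Measurement

    def __post_init__(self) -> None:
        for name in ("y_x_ac", "y_x_n2o", "y_n2o_ac", "y_nh4_x"):
            m = getattr(self, name)
            if m.value < 0 or m.sd < 0:
                raise ValueError(f"{name}: yields and SDs must be >= 0")


@dataclass(frozen=True)
class ChemostatCondition:
    """Operating point of one continuous enrichment."""

    dilution_rate: Measurement  # 1/h
    hrt_d: float
    srt_d: float
    influent_loads: Mapping[str, float]  # mmol/d

    def __post_init__(self) -> None:
        if self.dilution_rate.value <= 0:
            raise ValueError("dilution rate must be > 0")
        if self.srt_d < self.hrt_d:
            raise ValueError("membrane reactor requires SRT >= HRT")
        if any(v < 0 for v in self.influent_loads.values()):
            raise ValueError("influent loads must be >= 0")


@dataclass(frozen=True)
class PirtFit:
    m_s: float
    y_max: float
    se_m_s: float
    se_y_max: float
    r_squared: float
    n_points: int
    form: str = "inverse_yield"

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("a Pirt fit needs at least two points")
        if not math.isfinite(self.m_s):
            raise ValueError("non-finite maintenance coefficient")


def _ratio_with_sd(num: Measurement, den: Measurement) -> Measurement:
    """|num/den| with relative-error propagation (magnitudes only)."""
    if den.value == 0:
        raise ZeroDivisionError("zero denominator rate in yield computation")
    y = abs(num.value / den.value)
    if num.value == 0:
        # relative error of the numerator is undefined at 0; propagate the
        # absolute numerator SD through the denominator magnitude instead
        return Measurement(0.0, num.sd / abs(den.value))
    rel = math.sqrt((num.sd / num.value) ** 2 + (den.sd / den.value) ** 2)
    return Measurement(y, y * rel)


def compute_yields(
    rates: Mapping[str, float],
    sd: Mapping[str, float],
    donor: str = "acetate",
    acceptor: str = "N2O",
    biomass: str = "biomass",
    n_source: str = "NH4",
    donor_composition: ElementalComposition | None = None,
) -> YieldSet:
    """Yields as ratios of (reconciled) volumetric conversion rates.

    Rates are mmol/d production-positive; the biomass rate is understood
    in C-mmol/d of the assumed per-carbon biomass formula.  The donor is
    converted to C-mol using its carbon number (2 for acetate), so
    y_x_ac is C-mol/C-mol while y_n2o_ac stays mol/mol.
    """
    comp = donor_composition if donor_composition is not None else parse_formula("C2H3O2-")
    n_c = comp.n_C
    m = {k: Measurement(rates[k], sd.get(k, 0.0)) for k in rates}
    donor_cmol = Measurement(m[donor].value * n_c, m[donor].sd * n_c)
    return YieldSet(
        y_x_ac=_ratio_with_sd(m[biomass], donor_cmol),
        y_x_n2o=_ratio_with_sd(m[biomass], m[acceptor]),
        y_n2o_ac=_ratio_with_sd(m[acceptor], m[donor]),
        y_nh4_x=_ratio_with_sd(m[n_source], m[biomass]),
    )


def yields_from_result(result: ReconciliationResult, **names: str) -> YieldSet:
    """Yields from a reconciliation result, SDs from its adjusted covariance."""
    order = result.species_order
    var = np.clip(np.diag(result.covariance_reconciled), 0.0, None)
    sd = dict(zip(order, np.sqrt(var)))
    return compute_yields(dict(result.reconciled.rates), sd, **names)


def estimate_maintenance(
    dilution_rates: Sequence[float],
    yields: Sequence[float],
    yield_sd: Sequence[float] | None = None,
    form: str = "inverse_yield",
    weighted: bool = False,
) -> PirtFit:
    """Herbert-Pirt maintenance coefficient from (D, Y_X/Ac) points.

    form="inverse_yield" (default): OLS of 1/Y on 1/D; slope = m_s,
    intercept = 1/Y_max.  form="specific_rate": OLS of q_s = D/Y on D;
    intercept = m_s, slope = 1/Y_max.  With ``weighted=True`` the points
    are weighted by the inverse variance of the transformed response
    (requires ``yield_sd``); the default is the unweighted fit.
    """
    D = np.asarray(dilution_rates, dtype=float)
    Y = np.asarray(yields, dtype=float)
    if D.shape != Y.shape or D.ndim != 1:
        raise ValueError("dilution rates and yields must be matching 1-d sequences")
    if np.any(Y <= 0):
        raise ValueError("all yields must be > 0")
    if np.any(D <= 0):
        raise ValueError("all dilution rates must be > 0")
    if np.unique(D).size < 2:
        raise ValueError("need at least two distinct dilution rates")

    if form == "inverse_yield":
        x, resp = 1.0 / D, 1.0 / Y
        resp_sd = None if yield_sd is None else np.asarray(yield_sd) / Y**2
    elif form == "specific_rate":
        x, resp = D, D / Y
        resp_sd = None if yield_sd is None else np.asarray(yield_sd) * D / Y**2
    else:
        raise ValueError(f"unknown regression form {form!r}")

    if weighted:
        if resp_sd is None or np.any(resp_sd <= 0):
            raise ValueError("weighted fit requires positive yield SDs")
        w = 1.0 / resp_sd**2
    else:
        w = np.ones_like(x)

    W = np.sum(w)
    xbar = np.sum(w * x) / W
    ybar = np.sum(w * resp) / W
    sxx = np.sum(w * (x - xbar) ** 2)
    slope = np.sum(w * (x - xbar) * (resp - ybar)) / sxx
    intercept = ybar - slope * xbar
    fitted = intercept + slope * x
    n = x.size
    ss_res = np.sum(w * (resp - fitted) ** 2)
    ss_tot = np.sum(w * (resp - ybar) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if n > 2:
        s2 = ss_res / (n - 2)
        se_slope = math.sqrt(s2 / sxx)
        se_intercept = math.sqrt(s2 * (1.0 / W + xbar**2 / sxx))
    else:
        se_slope = se_intercept = 0.0

    if form == "inverse_yield":
        m_s, se_m_s = float(slope), float(se_slope)
        y_max = 1.0 / intercept if intercept > 0 else math.inf
        se_y_max = float(se_intercept / intercept**2) if intercept > 0 else math.inf
    else:
        m_s, se_m_s = float(intercept), float(se_intercept)
        y_max = 1.0 / slope if slope > 0 else math.inf
        se_y_max = float(se_slope / slope**2) if slope > 0 else math.inf
    return PirtFit(
        m_s=m_s,
        y_max=float(y_max),
        se_m_s=se_m_s,
        se_y_max=se_y_max,
        r_squared=float(r2),
        n_points=int(n),
        form=form,
    )


def dissolved_gas(partial_pressure_pa: float, henry_constant: float = HENRY_N2O) -> float:
    """Equilibrium dissolved concentration, mmol/L, from Henry's law."""
    if partial_pressure_pa < 0 or henry_constant < 0:
        raise ValueError("pressure and Henry constant must be >= 0")
    return henry_constant * partial_pressure_pa


def dilution_rate_from_srt(srt_d: float) -> float:
    """Biomass dilution rate (1/h) from the solids retention time (days)."""
    if srt_d <= 0:
        raise ValueError("SRT must be > 0")
    return 1.0 / (24.0 * srt_d)
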