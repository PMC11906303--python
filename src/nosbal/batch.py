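"""Specific consumption rates from batch depletion curves.

Ex-situ batch assays (here: nitrite reduction as a denitrification
proxy) track a dissolved substrate over time in sealed bottles at known
biomass concentration.  The volumetric rate is the sign-flipped slope of
an ordinary least-squares line through at least four concentration
points; biomass-specific rates divide by the bottle's biomass, with SDs
combined by linear error propagation.  Replicate bottles are aggregated
as mean +/- SD of per-bottle slopes.  Autoclaved controls should yield
slopes indistinguishable from zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .stoichiometry import ElementalComposition, parse_formula

__all__ = [
    "BatchSeries",
    "SpecificRate",
    "InsufficientDataError",
    "fit_volumetric_rate",
    "specific_rate",
    "gvss_to_cmol",
    "MIN_POINTS",
]

#: minimum concentration points per regression line
MIN_POINTS = 4


class InsufficientDataError(ValueError):
    """Fewer concentration points than the regression minimum."""


@dataclass(frozen=True)
class BatchSeries:
    """One bottle's concentration time series.

    times_h strictly increasing; concentrations in mmol/L; biomass in
    g VSS/L with its SD.
    """

    times_h: tuple[float, ...]
    conc_mM: tuple[float, ...]
    replicate: str
    biomass_gvss: float
    biomass_sd: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        c = np.asarray(self.conc_mM, dtype=float)
        if t.size != c.size:
            raise ValueError("times and concentrations differ in length")
        if t.size < MIN_POINTS:
            raise InsufficientDataError(
                f"need at least {MIN_POINTS} points, got {t.size}"
            )
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.biomass_gvss <= 0:
            raise ValueError("biomass concentration must be > 0")
        if self.biomass_sd < 0:
            raise ValueError("biomass SD must be >= 0")


@dataclass(frozen=True)
class SpecificRate:
    """Biomass-specific consumption rate with provenance."""

    q: float
    q_sd: float
    unit: str  # "mmol/(g VSS h)" or "mmol/(C-mol X h)"
    volumetric_rate: float
    volumetric_sd: float
    n_replicates: int

    def __post_init__(self) -> None:
        if self.q_sd < 0 or self.volumetric_sd < 0:
            raise ValueError("SDs must be >= 0")


def fit_volumetric_rate(series: BatchSeries) -> tuple[float, float]:
    """Consumption-positive OLS slope (mmol/L/h) and its standard error."""
    t = np.asarray(series.times_h, dtype=float)
    c = np.asarray(series.conc_mM, dtype=float)
    fit = stats.linregress(t, c)
    stderr = 0.0 if not np.isfinite(fit.stderr) else float(fit.stderr)
    return -float(fit.slope), stderr


def gvss_to_cmol(grams_vss: float, composition: ElementalComposition | None = None) -> float:
    """Convert g VSS to C-mol of the assumed biomass formula (24.6 g/C-mol)."""
    comp = composition if composition is not None else parse_formula("CH1.8O0.5N0.2")
    return grams_vss / comp.molar_mass


def specific_rate(
    volumetric_rates: Sequence[float],
    biomass_gvss: float,
    biomass_sd: float = 0.0,
    rate_sd: float | None = None,
    per_cmol: bool = False,
    composition: ElementalComposition | None = None,
) -> SpecificRate:
    """Mean volumetric rate over replicate bottles divided by biomass.

    The rate SD defaults to the sample SD across replicates (0 for a
    single bottle unless ``rate_sd`` is given); the specific-rate SD is
    q * sqrt((sd_r/r)^2 + (sd_X/X)^2).  With ``per_cmol=True`` biomass
    is converted from g VSS to C-mol of the assumed composition.
    """
    rates = np.asarray(volumetric_rates, dtype=float)
    if rates.size < 1:
        raise ValueError("at least one replicate rate is required")
    if biomass_gvss <= 0:
        raise ValueError("biomass concentration must be > 0")
    r = float(np.mean(rates))
    if rate_sd is not None:
        sd_r = float(rate_sd)
    else:
        sd_r = float(np.std(rates, ddof=1)) if rates.size > 1 else 0.0
    X = gvss_to_cmol(biomass_gvss, composition) if per_cmol else biomass_gvss
    sd_X = biomass_sd * (X / biomass_gvss)
    q = r / X
    rel = 0.0
    if r != 0:
        rel += (sd_r / r) ** 2
    rel += (sd_X / X) ** 2
    q_sd = abs(q) * math.sqrt(rel) if r != 0 else sd_r / X
    return SpecificRate(
        q=q,
        q_sd=q_sd,
        unit="mmol/(C-mol X h)" if per_cmol else "mmol/(g VSS h)",
        volumetric_rate=r,
        volumetric_sd=sd_r,
        n_replicates=int(rates.size),
    )
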