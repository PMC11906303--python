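"""Weighted least-squares reconciliation of measured conversion rates.

At steady state the net conversion rates of all species in the reactor
must satisfy every elemental and charge balance.  Only a subset of the
rates is measured (here: acetate, N2O, ammonium, biomass); CO2, N2,
water and protons leave unmeasured.  The balances are therefore first
*reduced*: the unmeasured columns are eliminated by projecting onto the
left null space of the unmeasured block, which leaves the constraints
actually testable from data.  For the acetate/N2O system the five CHON +
charge balances collapse to a single redundancy — the electron balance.

The measured rates are then adjusted by the classical minimum-variance
(Lagrange multiplier) solution

    r_hat = r - S E' (E S E')^-1 E r

with S the diagonal measurement covariance, and the residual statistic
h = eps' (E S E')^-1 eps is chi-square distributed with dof = rank(E)
degrees of freedom under the hypothesis of unbiased measurements — the
standard gross-error test accompanying macroscopic balancing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import null_space
from scipy.stats import chi2

from .stoichiometry import BALANCES, ConfigurationError, Species, conservation_matrix

__all__ = [
    "RateVector",
    "ReconciliationResult",
    "GrossErrorReport",
    "ReconciliationError",
    "reduce_constraints",
    "reconcile",
    "reconcile_system",
    "gross_error_test",
]

#: relative singular-value threshold used for every rank decision
RANK_RTOL = 1e-10


class ReconciliationError(ValueError):
    """The reconciliation problem is numerically unusable."""


@dataclass(frozen=True)
class RateVector:
    """Volumetric conversion rates (mmol/d, production-positive) with SDs."""

    rates: Mapping[str, float]
    sd: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.rates) != set(self.sd):
            raise ConfigurationError("rates and sd must cover the same species")
        for name, r in self.rates.items():
            s = self.sd[name]
            if not (np.isfinite(r) and np.isfinite(s)):
                raise ConfigurationError(f"non-finite rate or sd for {name!r}")
            if s <= 0:
                raise ConfigurationError(f"sd must be > 0 for measured {name!r}")

    @property
    def species(self) -> list[str]:
        return list(self.rates)

    def as_arrays(self, order: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        missing = [n for n in order if n not in self.rates]
        if missing:
            raise ConfigurationError(f"no measured rate for species {missing}")
        return (
            np.array([self.rates[n] for n in order], dtype=float),
            np.array([self.sd[n] for n in order], dtype=float),
        )


@dataclass
class ReconciliationResult:
    species_order: list[str]
    reconciled: RateVector
    residual: np.ndarray
    h_statistic: float
    dof: int
    p_value: float
    covariance_reconciled: np.ndarray
    measured: RateVector | None = None
    solved_unmeasured: dict[str, float] = field(default_factory=dict)
    degenerate: bool = False  # dof == 0: nothing was testable


@dataclass(frozen=True)
class GrossErrorReport:
    passed: bool
    p_value: float
    message: str


def reduce_constraints(
    E: np.ndarray, measured_flags: Sequence[bool], rtol: float = RANK_RTOL
) -> np.ndarray:
    """Eliminate unmeasured species from a conservation matrix.

    Partition E = [E_m | E_u] by the measured flags and return K E_m
    where the rows of K span the left null space of E_u.  The result acts
    on the measured rates alone; a zero-row matrix signals zero
    redundancy (nothing testable), which is a valid outcome.
    """
    E = np.atleast_2d(np.asarray(E, dtype=float))
    flags = np.asarray(measured_flags, dtype=bool)
    if flags.size != E.shape[1]:
        raise ConfigurationError("one measured flag per species column is required")
    if not flags.any():
        raise ConfigurationError("at least one species must be measured")
    E_m = E[:, flags]
    E_u = E[:, ~flags]
    if E_u.shape[1] == 0:
        return E.copy()
    K = null_space(E_u.T, rcond=rtol)  # columns span left null space of E_u
    if K.shape[1] == 0:
        return np.zeros((0, E_m.shape[1]))
    return K.T @ E_m


def reconcile(measured: RateVector, E_reduced: np.ndarray,
              species_order: Sequence[str] | None = None) -> ReconciliationResult:
    """Minimum-variance adjustment of measured rates under reduced balances.

    ``E_reduced`` columns must follow ``species_order`` (default: the
    insertion order of ``measured``).  Raises ReconciliationError when
    the constraint covariance is singular (duplicated constraints or
    degenerate SDs); returns a flagged degenerate result when there is
    nothing to test (zero redundancy).
    """
    order = list(species_order) if species_order is not None else measured.species
    r, sd = measured.as_arrays(order)
    E = np.atleast_2d(np.asarray(E_reduced, dtype=float))
    if E.size == 0:
        E = E.reshape(0, len(order))
    if E.shape[1] != len(order):
        raise ConfigurationError(
            f"constraint matrix has {E.shape[1]} columns for {len(order)} species"
        )
    S = np.diag(sd**2)
    dof = int(np.linalg.matrix_rank(E, tol=None if E.size == 0 else RANK_RTOL * np.linalg.norm(E, 2)))
    if E.shape[0] == 0 or dof == 0:
        warnings.warn("zero redundancy: rates returned unadjusted, h undefined")
        return ReconciliationResult(
            species_order=order,
            reconciled=measured,
            residual=np.zeros(0),
            h_statistic=float("nan"),
            dof=0,
            p_value=float("nan"),
            covariance_reconciled=S,
            measured=measured,
            degenerate=True,
        )
    if dof < E.shape[0]:
        raise ReconciliationError(
            f"constraint covariance singular: {E.shape[0]} constraint rows have "
            f"rank {dof} (duplicated or dependent balances)"
        )
    eps = E @ r
    P = E @ S @ E.T
    cond = np.linalg.cond(P)
    if not np.isfinite(cond) or cond > 1e12:
        raise ReconciliationError(
            "constraint covariance singular or ill-conditioned "
            f"(condition number {cond:.3g})"
        )
    P_inv = np.linalg.inv(P)
    gain = S @ E.T @ P_inv
    r_hat = r - gain @ eps
    cov_hat = S - gain @ E @ S
    h = float(eps @ P_inv @ eps)
    reconciled = RateVector(
        rates={n: float(v) for n, v in zip(order, r_hat)},
        sd=dict(zip(order, sd)),
    )
    return ReconciliationResult(
        species_order=order,
        reconciled=reconciled,
        residual=eps,
        h_statistic=h,
        dof=dof,
        p_value=float(chi2.sf(h, dof)),
        covariance_reconciled=cov_hat,
        measured=measured,
    )


def _back_solve_unmeasured(
    E: np.ndarray, flags: np.ndarray, r_hat: np.ndarray, unmeasured_names: list[str]
) -> dict[str, float]:
    """Rates of unmeasured species that the full balance set pins down."""
    E_m = E[:, flags]
    E_u = E[:, ~flags]
    if E_u.shape[1] == 0:
        return {}
    rhs = -E_m @ r_hat
    x, *_ = np.linalg.lstsq(E_u, rhs, rcond=None)
    N = null_space(E_u, rcond=RANK_RTOL)
    free = np.zeros(E_u.shape[1], dtype=bool)
    if N.shape[1] > 0:
        free = np.abs(N).max(axis=1) > 1e-12
    return {
        name: float(v)
        for name, v, f in zip(unmeasured_names, x, free)
        if not f
    }


def reconcile_system(
    species: Sequence[Species],
    measured: RateVector,
    balances: Sequence[str] = BALANCES,
    exempt_n_balance: Sequence[str] = (),
) -> ReconciliationResult:
    """Full pipeline: build balances, reduce, reconcile, back-solve.

    ``exempt_n_balance`` names species whose nitrogen is excluded from
    the N balance (escape hatch for the ammonium surplus the fixed
    biomass N content cannot absorb).
    """
    E = conservation_matrix(species, balances)
    balances = tuple(balances)
    if exempt_n_balance and "N" in balances:
        row = balances.index("N")
        for j, sp in enumerate(species):
            if sp.name in exempt_n_balance:
                E[row, j] = 0.0
    flags = np.array([sp.measured for sp in species])
    measured_names = [sp.name for sp in species if sp.measured]
    unmeasured_names = [sp.name for sp in species if not sp.measured]
    E_red = reduce_constraints(E, flags)
    result = reconcile(measured, E_red, measured_names)
    r_hat, _ = result.reconciled.as_arrays(measured_names)
    result.solved_unmeasured = _back_solve_unmeasured(
        E, flags, r_hat, unmeasured_names
    )
    return result


def gross_error_test(result: ReconciliationResult, alpha: float = 0.05) -> GrossErrorReport:
    """Chi-square test for gross measurement errors.

    Fails iff the upper-tail p-value of h is strictly below ``alpha``;
    the message names the species whose adjustment, standardized by its
    measurement SD, contributes most.
    """
    if result.degenerate or result.dof == 0:
        raise ReconciliationError("zero degrees of freedom: balance test untestable")
    passed = not (result.p_value < alpha)
    r_hat, sd = result.reconciled.as_arrays(result.species_order)
    if result.measured is not None:
        r_raw, _ = result.measured.as_arrays(result.species_order)
        standardized = np.abs(r_raw - r_hat) / sd
        worst = int(np.argmax(standardized))
        detail = (
            f"largest standardized adjustment: {result.species_order[worst]} "
            f"({standardized[worst]:.3g} SD)"
        )
    else:  # pragma: no cover - measured is always attached in this package
        detail = "no measured vector attached"
    message = (
        f"h = {result.h_statistic:.4g}, dof = {result.dof}, "
        f"p = {result.p_value:.4g} ({'pass' if passed else 'FAIL'} at alpha={alpha}); "
        + detail
    )
    return GrossErrorReport(passed=passed, p_value=result.p_value, message=message)
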