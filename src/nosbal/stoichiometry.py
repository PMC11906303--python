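"""Elemental bookkeeping and black-box reaction stoichiometry.

The chemostat cultures considered here grow on acetate as sole electron
donor with nitrous oxide (N2O) as sole electron acceptor.  Everything in
this module is plain conservation arithmetic over the elements C, H, O, N
and electric charge: compositions of the participating species, the
degree of reduction (available electrons per formula unit), conservation
matrices, and the exact solve for the catabolic reaction

    CH3COO- + 4 N2O + H+  ->  2 CO2 + 4 N2 + 2 H2O

which fixes the 4:1 acceptor-to-donor ratio that anchors the yield
analysis.  Biomass is represented by the conventional per-carbon formula
CH1.8O0.5N0.2.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "CompositionError",
    "ConfigurationError",
    "StoichiometryError",
    "ElementalComposition",
    "Species",
    "ReactionStoichiometry",
    "parse_formula",
    "degree_of_reduction",
    "conservation_matrix",
    "balance_catabolism",
    "predict_yields_from_electron_balance",
    "default_species",
    "BALANCES",
]

BALANCES = ("C", "H", "O", "N", "charge")

_ATOMIC_MASS = {"C": 12.011, "H": 1.008, "O": 15.999, "N": 14.007}


class CompositionError(ValueError):
    """An elemental composition is malformed."""


class ConfigurationError(ValueError):
    """A balance/species configuration is unusable."""


class StoichiometryError(ValueError):
    """No exact balanced reaction exists for the requested system."""


@dataclass(frozen=True)
class ElementalComposition:
    """Atoms of C, H, O, N per formula unit plus elementary charge.

    Fractional atom counts are allowed (biomass is CH1.8O0.5N0.2 per
    C-mol).  An all-zero, uncharged composition is rejected.
    """

    n_C: float = 0.0
    n_H: float = 0.0
    n_O: float = 0.0
    n_N: float = 0.0
    charge: float = 0.0

    def __post_init__(self) -> None:
        atoms = (self.n_C, self.n_H, self.n_O, self.n_N)
        if not all(np.isfinite(a) for a in (*atoms, self.charge)):
            raise CompositionError("atom counts and charge must be finite")
        if any(a < 0 for a in atoms):
            raise CompositionError("atom counts must be non-negative")
        if all(a == 0 for a in atoms) and self.charge == 0:
            raise CompositionError("empty composition (no atoms, no charge)")

    def balance_vector(self, balances: Sequence[str] = BALANCES) -> np.ndarray:
        """Entries of this composition for the requested balances, in order."""
        lookup = {
            "C": self.n_C,
            "H": self.n_H,
            "O": self.n_O,
            "N": self.n_N,
            "charge": self.charge,
        }
        try:
            return np.array([lookup[b] for b in balances], dtype=float)
        except KeyError as exc:  # pragma: no cover - guarded by conservation_matrix
            raise ConfigurationError(f"unknown balance {exc.args[0]!r}") from exc

    @property
    def molar_mass(self) -> float:
        """Formula mass in g/mol (average atomic masses)."""
        return (
            self.n_C * _ATOMIC_MASS["C"]
            + self.n_H * _ATOMIC_MASS["H"]
            + self.n_O * _ATOMIC_MASS["O"]
            + self.n_N * _ATOMIC_MASS["N"]
        )


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")
_CHARGE_SUFFIX = re.compile(r"([+-]+)$")


def parse_formula(formula: str) -> ElementalComposition:
    """Parse a CHON formula string such as ``"C2H3O2-"`` or ``"CH1.8O0.5N0.2"``.

    A trailing run of ``+``/``-`` signs sets the charge (one elementary
    charge per sign, so a doubly charged anion ends in ``--``); digits
    before the sign always belong to the last element subscript.
    Fractional subscripts are accepted.
    """
    body = formula.strip()
    charge = 0.0
    m = _CHARGE_SUFFIX.search(body)
    if m:
        signs = m.group(1)
        if len(set(signs)) > 1:
            raise CompositionError(f"mixed charge signs in formula {formula!r}")
        charge = float(len(signs)) * (1.0 if signs[0] == "+" else -1.0)
        body = body[: m.start()]
    counts = {"C": 0.0, "H": 0.0, "O": 0.0, "N": 0.0}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(body):
        if m.start() != pos or not m.group(0):
            break
        element, count = m.group(1), m.group(2)
        if element not in counts:
            raise CompositionError(
                f"unsupported element {element!r} in formula {formula!r} "
                "(only C, H, O, N are balanced)"
            )
        counts[element] += float(count) if count else 1.0
        pos = m.end()
    if pos != len(body):
        raise CompositionError(f"could not parse formula {formula!r}")
    return ElementalComposition(
        n_C=counts["C"], n_H=counts["H"], n_O=counts["O"], n_N=counts["N"], charge=charge
    )


@dataclass(frozen=True)
class Species:
    """A chemical species taking part in the black-box conversion."""

    name: str
    composition: ElementalComposition
    measured: bool = True
    role: str = "product"
    phase: str = "aq"

    _ROLES = frozenset(
        {"electron_donor", "electron_acceptor", "n_source", "biomass", "product"}
    )

    def __post_init__(self) -> None:
        if self.role not in self._ROLES:
            raise ConfigurationError(
                f"unknown role {self.role!r} for species {self.name!r}"
            )


def default_species() -> list[Species]:
    """The eight-species acetate/N2O chemostat system, in canonical order.

    Measured: acetate, N2O, ammonium and biomass (their conversion rates
    are observed).  Unmeasured: CO2, N2, water and protons.
    """
    return [
        Species("acetate", parse_formula("C2H3O2-"), True, "electron_donor"),
        Species("N2O", parse_formula("N2O"), True, "electron_acceptor", phase="g"),
        Species("NH4", parse_formula("NH4+"), True, "n_source"),
        Species("biomass", parse_formula("CH1.8O0.5N0.2"), True, "biomass", phase="s"),
        Species("CO2", parse_formula("CO2"), False, "product", phase="g"),
        Species("N2", parse_formula("N2"), False, "product", phase="g"),
        Species("H2O", parse_formula("H2O"), False, "product"),
        Species("H+", parse_formula("H+"), False, "product"),
    ]


def degree_of_reduction(
    comp: ElementalComposition, n_reference_valence: float = -3.0
) -> float:
    """Available electrons per formula unit.

    gamma = 4 n_C + n_H - 2 n_O + v_N n_N - charge, where ``v_N`` is the
    valence assigned to nitrogen in the reference redox state: -3 for an
    ammonia reference (organics, biomass, ammonium) or 0 for a dinitrogen
    reference (the N2O/N2 acceptor couple, for which gamma(N2O) = -2,
    i.e. two electrons accepted per mole).
    """
    return (
        4.0 * comp.n_C
        + comp.n_H
        - 2.0 * comp.n_O
        + n_reference_valence * comp.n_N
        - comp.charge
    )


def conservation_matrix(
    species: Sequence[Species], balances: Sequence[str] = BALANCES
) -> np.ndarray:
    """Conservation matrix E: rows follow ``balances``, columns ``species``.

    ``E @ v = 0`` expresses conservation for any vector ``v`` of signed
    stoichiometric coefficients or net conversion rates.
    """
    balances = tuple(balances)
    if not balances:
        raise ConfigurationError("at least one balance is required")
    for b in balances:
        if b not in BALANCES:
            raise ConfigurationError(f"unknown balance {b!r}")
    if len(species) < 2:
        raise ConfigurationError("a conservation system needs at least two species")
    names = [s.name for s in species]
    if len(set(names)) != len(names):
        raise ConfigurationError("species names must be unique")
    return np.column_stack([s.composition.balance_vector(balances) for s in species])


@dataclass(frozen=True)
class ReactionStoichiometry:
    """Signed stoichiometric coefficients (products > 0, substrates < 0)."""

    coefficients: Mapping[str, float]

    def coefficient(self, name: str) -> float:
        return self.coefficients[name]

    def verify(
        self,
        species: Sequence[Species],
        balances: Sequence[str] = BALANCES,
        tol: float = 1e-9,
    ) -> None:
        """Raise StoichiometryError unless every balance closes within tol."""
        E = conservation_matrix(species, balances)
        v = np.array([self.coefficients.get(s.name, 0.0) for s in species])
        residual = E @ v
        worst = int(np.argmax(np.abs(residual)))
        if np.abs(residual[worst]) > tol:
            raise StoichiometryError(
                f"{tuple(balances)[worst]} balance violated by {residual[worst]:.3g}"
            )


def balance_catabolism(
    donor: Species,
    acceptor: Species,
    products: Iterable[Species],
    balances: Sequence[str] = BALANCES,
    tol: float = 1e-9,
) -> ReactionStoichiometry:
    """Solve the exact catabolic stoichiometry with the donor fixed at -1.

    The acceptor and product coefficients are the unique solution of the
    requested conservation balances.  Raises StoichiometryError naming
    the violated balance when no exact solution exists, and when the
    product set leaves the system under-determined.
    """
    products = list(products)
    species = [donor, acceptor, *products]
    E = conservation_matrix(species, balances)
    e_donor = E[:, 0]
    E_rest = E[:, 1:]
    n_unknown = E_rest.shape[1]
    if np.linalg.matrix_rank(E_rest) < n_unknown:
        raise StoichiometryError(
            "under-determined catabolic system: product set does not pin down "
            "a unique stoichiometry"
        )
    # E @ (-1, v) = 0  <=>  E_rest v = e_donor
    v, *_ = np.linalg.lstsq(E_rest, e_donor, rcond=None)
    residual = E_rest @ v - e_donor
    worst = int(np.argmax(np.abs(residual)))
    if np.abs(residual[worst]) > tol:
        raise StoichiometryError(
            f"inconsistent catabolic system: {tuple(balances)[worst]} balance "
            f"cannot be closed (residual {residual[worst]:.3g})"
        )
    coeffs = {donor.name: -1.0}
    for sp, c in zip(species[1:], v):
        coeffs[sp.name] = float(c)
    result = ReactionStoichiometry(coeffs)
    result.verify(species, balances, tol)
    return result


def predict_yields_from_electron_balance(
    y_x_ac: float,
    donor: ElementalComposition | None = None,
    biomass: ElementalComposition | None = None,
) -> dict[str, float]:
    """Close the electron balance around a given biomass yield on acetate.

    Given ``y_x_ac`` (C-mol biomass per C-mol acetate), distribute the
    donor electrons between biomass formation and N2O respiration:

        gamma_donor = gamma_X * n_C * y_x_ac + 2 * y_n2o_ac

    with gamma in the ammonia-nitrogen reference (acetate: 8 e-/mol,
    biomass: 4.2 e-/C-mol) and 2 electrons accepted per N2O.  Returns the
    N2O yield on acetate (mol/mol), the biomass yield on N2O
    (C-mol/mol), and the ammonium requirement per biomass (mol/C-mol,
    the biomass nitrogen content).  At ``y_x_ac = 0`` this reproduces the
    pure catabolic 4:1 N2O:acetate ratio.
    """
    donor = donor if donor is not None else parse_formula("C2H3O2-")
    biomass = biomass if biomass is not None else parse_formula("CH1.8O0.5N0.2")
    gamma_donor = degree_of_reduction(donor, -3.0)  # per mol donor
    gamma_x = degree_of_reduction(biomass, -3.0)  # per C-mol
    n_c = donor.n_C
    electrons_per_n2o = -degree_of_reduction(parse_formula("N2O"), 0.0)  # = 2
    y_max_limit = gamma_donor / (gamma_x * n_c)
    if not 0.0 <= y_x_ac < y_max_limit:
        raise ValueError(
            f"y_x_ac must lie in [0, {y_max_limit:.4g}); got {y_x_ac!r}"
        )
    y_n2o_ac = (gamma_donor - gamma_x * n_c * y_x_ac) / electrons_per_n2o
    return {
        "y_n2o_ac": y_n2o_ac,
        "y_x_n2o": n_c * y_x_ac / y_n2o_ac if y_x_ac > 0 else 0.0,
        "y_nh4_x": biomass.n_N,
    }
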