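"""Constraint reduction, weighted least-squares adjustment, gross-error test."""

import numpy as np
import pytest
from scipy.linalg import null_space
from scipy.optimize import minimize

from nosbal.reconciliation import (
    RateVector,
    ReconciliationError,
    gross_error_test,
    reconcile,
    reconcile_system,
    reduce_constraints,
)
from nosbal.stoichiometry import conservation_matrix


def _lstsq_oracle(r, sd, E):
    """Independent null-space solution of min (x-r)' S^-1 (x-r) s.t. Ex=0."""
    N = null_space(E)
    W = np.diag(1.0 / sd)
    z, *_ = np.linalg.lstsq(W @ N, W @ r, rcond=None)
    return N @ z


class TestReduceConstraints:
    def test_all_measured_returns_input(self, species):
        E = conservation_matrix(species[:4])
        out = reduce_constraints(E, [True] * 4)
        np.testing.assert_allclose(out, E)

    def test_paper_system_single_electron_constraint(self, species):
        E = conservation_matrix(species)
        out = reduce_constraints(E, [s.measured for s in species])
        assert out.shape == (1, 4)
        # unique testable redundancy: the electron balance over measured
        # species, proportional to (8, -2, 3, 4.8) on (Ac, N2O, NH4, X)
        scaled = out[0] / out[0, 0] * 8.0
        np.testing.assert_allclose(scaled, [8.0, -2.0, 3.0, 4.8], atol=1e-9)

    def test_single_measured_species_zero_redundancy(self, species):
        E = conservation_matrix(species)
        out = reduce_constraints(E, [True] + [False] * 7)
        assert out.shape[0] == 0

    def test_reduced_rows_annihilate_unmeasured_block(self, species):
        E = conservation_matrix(species)
        flags = np.array([s.measured for s in species])
        out = reduce_constraints(E, flags)
        # every reduced row, padded with zeros on the unmeasured columns,
        # must lie in the row space of the full balance matrix
        for row in out:
            v = np.zeros(E.shape[1])
            v[flags] = row
            coeff, *_ = np.linalg.lstsq(E.T, v, rcond=None)
            np.testing.assert_allclose(E.T @ coeff, v, atol=1e-9)


class TestReconcile:
    def test_consistent_rates_unchanged(self, species, catabolic_rates):
        res = reconcile_system(species, catabolic_rates)
        assert res.h_statistic == pytest.approx(0.0, abs=1e-12)
        for name, r in catabolic_rates.rates.items():
            assert res.reconciled.rates[name] == pytest.approx(r, abs=1e-9)
        assert res.solved_unmeasured["CO2"] == pytest.approx(20.0, abs=1e-8)
        assert res.solved_unmeasured["N2"] == pytest.approx(40.0, abs=1e-8)

    def test_matches_constrained_optimizer_oracle(self, species):
        rv = RateVector(
            rates={"acetate": -10.0, "N2O": -38.0, "NH4": 0.0, "biomass": 0.0},
            sd={"acetate": 0.5, "N2O": 2.0, "NH4": 0.1, "biomass": 0.1},
        )
        E = conservation_matrix(species)
        E_red = reduce_constraints(E, [s.measured for s in species])
        res = reconcile(rv, E_red, ["acetate", "N2O", "NH4", "biomass"])
        r = np.array([-10.0, -38.0, 0.0, 0.0])
        sd = np.array([0.5, 2.0, 0.1, 0.1])
        opt = minimize(
            lambda x: np.sum(((x - r) / sd) ** 2),
            x0=r,
            constraints={"type": "eq", "fun": lambda x: E_red @ x},
            method="SLSQP",
            tol=1e-14,
            options={"maxiter": 500},
        )
        r_hat = np.array([res.reconciled.rates[n] for n in res.species_order])
        np.testing.assert_allclose(r_hat, opt.x, atol=1e-8)
        assert res.h_statistic == pytest.approx(opt.fun, abs=1e-8)

    @pytest.mark.parametrize("n_species, n_constraints", [(3, 1), (5, 2), (8, 3)])
    def test_random_systems_match_nullspace_oracle(self, rng, n_species, n_constraints):
        for _ in range(20):
            E = rng.normal(size=(n_constraints, n_species))
            r = rng.normal(size=n_species) * 10
            sd = rng.uniform(0.1, 2.0, size=n_species)
            names = [f"s{i}" for i in range(n_species)]
            rv = RateVector(rates=dict(zip(names, r)), sd=dict(zip(names, sd)))
            res = reconcile(rv, E, names)
            r_hat = np.array([res.reconciled.rates[n] for n in names])
            np.testing.assert_allclose(r_hat, _lstsq_oracle(r, sd, E), atol=1e-8)
            np.testing.assert_allclose(E @ r_hat, 0.0, atol=1e-8 * np.abs(r).max())

    def test_idempotent_projection(self, species):
        rv = RateVector(
            rates={"acetate": -10.0, "N2O": -38.0, "NH4": -0.5, "biomass": 1.5},
            sd={"acetate": 0.5, "N2O": 2.0, "NH4": 0.1, "biomass": 0.1},
        )
        E = conservation_matrix(species)
        E_red = reduce_constraints(E, [s.measured for s in species])
        order = ["acetate", "N2O", "NH4", "biomass"]
        once = reconcile(rv, E_red, order)
        twice = reconcile(once.reconciled, E_red, order)
        for n in order:
            assert twice.reconciled.rates[n] == pytest.approx(
                once.reconciled.rates[n], abs=1e-9
            )
        assert twice.h_statistic == pytest.approx(0.0, abs=1e-12)

    def test_h_invariant_to_common_rescaling(self, species):
        E = conservation_matrix(species)
        E_red = reduce_constraints(E, [s.measured for s in species])
        order = ["acetate", "N2O", "NH4", "biomass"]
        base = {"acetate": -10.0, "N2O": -38.0, "NH4": -0.5, "biomass": 1.5}
        sds = {"acetate": 0.5, "N2O": 2.0, "NH4": 0.1, "biomass": 0.1}
        h1 = reconcile(RateVector(base, sds), E_red, order).h_statistic
        k = 7.3
        h2 = reconcile(
            RateVector({n: k * v for n, v in base.items()},
                       {n: k * v for n, v in sds.items()}),
            E_red, order,
        ).h_statistic
        assert h2 == pytest.approx(h1, rel=1e-10)

    def test_shrinking_sd_pins_the_trusted_rate(self, species):
        E = conservation_matrix(species)
        E_red = reduce_constraints(E, [s.measured for s in species])
        order = ["acetate", "N2O", "NH4", "biomass"]
        base = {"acetate": -10.0, "N2O": -38.0, "NH4": 0.0, "biomass": 0.0}
        prev_gap = None
        for sd_ac in (2.0, 0.5, 0.1, 0.01):
            rv = RateVector(base, {"acetate": sd_ac, "N2O": 2.0, "NH4": 0.1, "biomass": 0.1})
            res = reconcile(rv, E_red, order)
            gap = abs(res.reconciled.rates["acetate"] - base["acetate"])
            if prev_gap is not None:
                assert gap <= prev_gap + 1e-12
            prev_gap = gap
        assert prev_gap < 1e-3

    def test_h_follows_chi_square_under_consistent_noise(self, species):
        from nosbal.synthetic import ChemostatGroundTruth, generate_chemostat_dataset

        hs = []
        for seed in range(300):
            truth = ChemostatGroundTruth(noise_cv=0.05, d_levels=(0.006,), seed=seed)
            data, _ = generate_chemostat_dataset(truth)
            res = reconcile_system(species, data[0.006])
            hs.append(res.h_statistic)
        hs = np.asarray(hs)
        assert hs.mean() == pytest.approx(1.0, abs=0.25)  # E[chi2(1)] = 1

    def test_duplicate_constraints_rejected(self):
        rv = RateVector(rates={"a": 1.0, "b": -1.0}, sd={"a": 0.1, "b": 0.1})
        E = np.array([[1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(ReconciliationError):
            reconcile(rv, E, ["a", "b"])

    def test_zero_redundancy_flagged(self):
        rv = RateVector(rates={"a": 1.0}, sd={"a": 0.1})
        with pytest.warns(UserWarning, match="zero redundancy"):
            res = reconcile(rv, np.zeros((0, 1)), ["a"])
        assert res.degenerate and res.dof == 0


class TestGrossErrorTest:
    def test_zero_h_passes(self, species, catabolic_rates):
        res = reconcile_system(species, catabolic_rates)
        assert gross_error_test(res, alpha=0.05).passed

    def test_boundary_h_passes_strictly(self, species):
        from scipy.stats import chi2

        res = reconcile_system(species, RateVector(
            rates={"acetate": -10.0, "N2O": -40.0, "NH4": 0.0, "biomass": 0.0},
            sd={"acetate": 0.5, "N2O": 2.0, "NH4": 0.1, "biomass": 0.1},
        ))
        res.h_statistic = float(chi2.isf(0.05, 1))  # exactly 3.841...
        res.p_value = float(chi2.sf(res.h_statistic, 1))
        assert res.p_value == pytest.approx(0.05, abs=1e-10)
        assert gross_error_test(res, alpha=0.05).passed  # strict '<'

    def test_large_h_fails_and_names_contributor(self, species):
        rv = RateVector(
            rates={"acetate": -10.0, "N2O": -30.0, "NH4": 0.0, "biomass": 0.0},
            sd={"acetate": 0.2, "N2O": 1.0, "NH4": 0.05, "biomass": 0.05},
        )
        res = reconcile_system(species, rv)
        report = gross_error_test(res, alpha=0.05)
        assert not report.passed
        assert "N2O" in report.message

    def test_untestable_without_redundancy(self):
        rv = RateVector(rates={"a": 1.0}, sd={"a": 0.1})
        with pytest.warns(UserWarning):
            res = reconcile(rv, np.zeros((0, 1)), ["a"])
        with pytest.raises(ReconciliationError):
            gross_error_test(res)
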