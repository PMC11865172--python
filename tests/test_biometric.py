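import numpy as np
import pytest
from scipy import stats

from twinwell import biometric as bm
from twinwell.biometric import (
    CholeskyParams,
    CholeskySpec,
    compare_models,
    expected_pair_covariance,
    fit_cholesky,
    minus2_log_likelihood,
    standardize,
    twin_correlations,
)
from twinwell.errors import ComparabilityError, FitError, ValidationError
from twinwell.synthetic import SimulationConfig, simulate_cohort
from twinwell.twin_data import TwinDataset, to_wide


def ae_params_1d(a2, e2):
    return CholeskyParams(L_a=[[np.sqrt(a2)]], L_e=[[np.sqrt(e2)]])


class TestExpectedCovariance:
    def test_univariate_cross_twin_covariance(self):
        p = ae_params_1d(0.4, 0.6)
        mz = expected_pair_covariance(p, "MZ")
        dz = expected_pair_covariance(p, "DZ")
        assert mz[0, 1] == pytest.approx(0.4)
        assert dz[0, 1] == pytest.approx(0.2)
        assert mz[0, 0] == dz[0, 0] == pytest.approx(1.0)

    def test_no_genetics_makes_zygosities_identical(self):
        p = CholeskyParams(L_a=np.zeros((2, 2)), L_e=np.eye(2) * 0.7)
        assert np.array_equal(
            expected_pair_covariance(p, "MZ"), expected_pair_covariance(p, "DZ")
        )

    def test_symmetric_psd(self):
        rng = np.random.default_rng(0)
        p = CholeskyParams(
            L_a=np.tril(rng.normal(size=(3, 3))),
            L_c=np.tril(rng.normal(size=(3, 3))),
            L_e=np.tril(rng.normal(size=(3, 3))) + np.eye(3),
        )
        for z in ("MZ", "DZ"):
            S = expected_pair_covariance(p, z)
            assert np.allclose(S, S.T)
            assert np.linalg.eigvalsh(S).min() > -1e-10

    def test_monte_carlo_oracle(self):
        # independent simulation of the generative model, written out here
        rng = np.random.default_rng(12)
        L_a = np.array([[0.6, 0.0], [0.3, 0.5]])
        L_e = np.array([[0.7, 0.0], [-0.2, 0.6]])
        p = CholeskyParams(L_a=L_a, L_e=L_e)
        n = 400_000
        for z, r in (("MZ", 1.0), ("DZ", 0.5)):
            gc = rng.standard_normal((n, 2))
            g1 = np.sqrt(r) * gc + np.sqrt(1 - r) * rng.standard_normal((n, 2))
            g2 = np.sqrt(r) * gc + np.sqrt(1 - r) * rng.standard_normal((n, 2))
            x1 = g1 @ L_a.T + rng.standard_normal((n, 2)) @ L_e.T
            x2 = g2 @ L_a.T + rng.standard_normal((n, 2)) @ L_e.T
            emp = np.cov(np.hstack([x1, x2]).T)
            assert np.allclose(emp, expected_pair_covariance(p, z), atol=0.012)

    def test_bad_zygosity(self):
        with pytest.raises(ValidationError):
            expected_pair_covariance(ae_params_1d(0.5, 0.5), "OS")


@pytest.fixture(scope="module")
def small_bivariate():
    cfg = SimulationConfig(
        n_mz_pairs=40, n_dz_pairs=40, traits=("a", "b"), h2=[0.4, 0.3], seed=21
    )
    ds, _ = simulate_cohort(cfg)
    return ds


class TestLikelihood:
    def test_matches_direct_density_on_complete_pairs(self, small_bivariate):
        pairs = to_wide(small_bivariate, ["a", "b"])
        rng = np.random.default_rng(3)
        p = CholeskyParams(
            L_a=np.tril(rng.normal(0, 0.4, (2, 2))),
            L_e=np.tril(rng.normal(0, 0.4, (2, 2))) + np.eye(2),
        )
        got = minus2_log_likelihood(p, pairs)
        direct = 0.0
        for wp in pairs:
            x = np.concatenate([wp.values_twin1, wp.values_twin2])
            S = expected_pair_covariance(p, wp.zygosity)
            direct += -2.0 * stats.multivariate_normal(np.zeros(4), S).logpdf(x)
        assert got == pytest.approx(direct, abs=1e-8)

    def test_incomplete_pair_contributes_marginal(self, small_bivariate):
        pairs = to_wide(small_bivariate, ["a", "b"])
        wp = pairs[0]
        wp.values_twin2[:] = np.nan  # make twin 2 fully missing
        p = ae_params_1d(0.4, 0.6)
        p2 = CholeskyParams(
            L_a=np.array([[0.5, 0], [0.2, 0.4]]),
            L_e=np.array([[0.8, 0], [0.1, 0.7]]),
        )
        single = minus2_log_likelihood(p2, [wp])
        S = expected_pair_covariance(p2, wp.zygosity)[:2, :2]
        expected = -2.0 * stats.multivariate_normal(np.zeros(2), S).logpdf(wp.values_twin1)
        assert single == pytest.approx(expected, abs=1e-10)

    def test_duplicating_pairs_doubles_value(self, small_bivariate):
        pairs = to_wide(small_bivariate, ["a", "b"])
        p = CholeskyParams(
            L_a=np.array([[0.5, 0], [0.2, 0.4]]),
            L_e=np.array([[0.8, 0], [0.1, 0.7]]),
        )
        one = minus2_log_likelihood(p, pairs)
        two = minus2_log_likelihood(p, pairs + pairs)
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_nonpd_returns_penalty_not_crash(self, small_bivariate):
        pairs = to_wide(small_bivariate, ["a", "b"])
        p = CholeskyParams(L_a=np.zeros((2, 2)), L_e=np.zeros((2, 2)))
        assert minus2_log_likelihood(p, pairs) >= 1e12


class TestStandardize:
    def test_diagonal_genetic_paths_give_identity_rg(self):
        p = CholeskyParams(L_a=np.diag([0.5, 0.7]), L_e=np.eye(2) * 0.6)
        _, rg, _, _ = standardize(p, ["a", "b"])
        assert np.allclose(rg.values, np.eye(2))

    def test_rank_one_genetic_factor_gives_unit_rg(self):
        L_a = np.array([[0.6, 0.0], [0.4, 0.0]])  # single shared genetic factor
        p = CholeskyParams(L_a=L_a, L_e=np.eye(2) * 0.5)
        _, rg, _, _ = standardize(p, ["a", "b"])
        assert np.allclose(np.abs(rg.values), 1.0)

    def test_components_sum_to_one(self):
        rng = np.random.default_rng(9)
        p = CholeskyParams(
            L_a=np.tril(rng.normal(size=(3, 3))),
            L_c=np.tril(rng.normal(size=(3, 3))),
            L_e=np.tril(rng.normal(size=(3, 3))) + np.eye(3),
        )
        std, _, _, _ = standardize(p, ["a", "b", "c"])
        assert np.allclose(std.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_genetic_variance_reported_undefined(self):
        p = CholeskyParams(
            L_a=np.array([[0.0, 0.0], [0.0, 0.6]]), L_e=np.eye(2) * 0.7
        )
        _, rg, _, _ = standardize(p, ["a", "b"])
        assert np.isnan(rg.values[0, 1]) and np.isnan(rg.values[0, 0])
        assert rg.values[1, 1] == 1.0


class TestFit:
    def test_recovers_heritability(self):
        cfg = SimulationConfig(
            n_mz_pairs=2000, n_dz_pairs=2000, traits=("t",), h2=[0.42], seed=31
        )
        ds, _ = simulate_cohort(cfg)
        fit = fit_cholesky(ds, CholeskySpec(("t",), ("A", "E")), seed=0, n_restarts=3)
        assert fit.standardized.loc["t", "h2"] == pytest.approx(0.42, abs=0.04)
        assert fit.AIC == pytest.approx(fit.minus2lnL + 2 * fit.n_params)

    def test_null_heritability(self):
        cfg = SimulationConfig(
            n_mz_pairs=5000, n_dz_pairs=5000, traits=("t",), h2=[0.0], seed=32
        )
        ds, _ = simulate_cohort(cfg)
        fit = fit_cholesky(ds, CholeskySpec(("t",), ("A", "E")), seed=0, n_restarts=3)
        assert fit.standardized.loc["t", "h2"] < 0.02

    def test_mle_beats_generating_params(self):
        cfg = SimulationConfig(
            n_mz_pairs=300, n_dz_pairs=300, traits=("t",), h2=[0.3], seed=33
        )
        ds, _ = simulate_cohort(cfg)
        fit = fit_cholesky(
            ds, CholeskySpec(("t",), ("A", "E")), seed=0, standardize_input=False
        )
        pairs = to_wide(ds, ["t"])
        truth = ae_params_1d(0.3, 0.7)
        assert fit.minus2lnL <= minus2_log_likelihood(truth, pairs) + 1e-6

    def test_guard_on_pair_counts(self, small_bivariate):
        with pytest.raises(FitError, match="at least"):
            fit_cholesky(small_bivariate, CholeskySpec(("a",), ("A", "E")), min_pairs=100)

    def test_falconer_consistency(self):
        cfg = SimulationConfig(
            n_mz_pairs=4000, n_dz_pairs=4000, traits=("t",), h2=[0.4], seed=34
        )
        ds, _ = simulate_cohort(cfg)
        fit = fit_cholesky(ds, CholeskySpec(("t",), ("A", "E")), seed=0, n_restarts=2)
        tc = twin_correlations(ds, "t")
        falconer = bm.falconer_h2(tc["r_MZ"], tc["r_DZ"])
        assert fit.standardized.loc["t", "h2"] == pytest.approx(falconer, abs=0.06)

    def test_fiml_uses_incomplete_pairs(self):
        cfg = SimulationConfig(
            n_mz_pairs=800, n_dz_pairs=800, traits=("t",), h2=[0.4],
            missing_pair_fraction=0.3, seed=35,
        )
        ds, _ = simulate_cohort(cfg)
        fit = fit_cholesky(ds, CholeskySpec(("t",), ("A", "E")), seed=0, n_restarts=2)
        assert fit.diagnostics["n_pairs_used"] == ds.n_pairs
        assert fit.standardized.loc["t", "h2"] == pytest.approx(0.4, abs=0.1)


class TestCompareModels:
    def test_aic_definition(self):
        # AIC of a model with -2lnL = 100 and k = 5 is 110
        assert 100 + 2 * 5 == 110

    def test_nesting_monotonicity_and_table(self, small_bivariate):
        cfg = SimulationConfig(
            n_mz_pairs=400, n_dz_pairs=400, traits=("a", "b"), h2=[0.4, 0.3], seed=41
        )
        ds, _ = simulate_cohort(cfg)
        specs = [CholeskySpec(("a", "b"), tuple(l)) for l in ("ACE", "AE", "E")]
        table, fits = compare_models(ds, specs, seed=0, n_restarts=2)
        m2 = {r["model"]: r["minus2lnL"] for _, r in table.iterrows()}
        assert m2["ACE"] <= m2["AE"] + 1e-6 <= m2["E"] + 1e-6
        assert set(table["model"]) == {"ACE", "AE", "E"}
        assert table["dAIC"].iloc[0] == 0.0
        assert table["best"].iloc[0]

    def test_comparability_error(self, small_bivariate):
        specs = [
            CholeskySpec(("a",), ("A", "E")),
            CholeskySpec(("b",), ("A", "E")),
        ]
        with pytest.raises(ComparabilityError):
            compare_models(small_bivariate, specs)


class TestTwinCorrelations:
    def test_identical_twins_give_one(self):
        rows = []
        rng = np.random.default_rng(5)
        for pid in range(1, 11):
            z = "MZ" if pid <= 5 else "DZ"
            v = float(rng.normal())
            for ti in (1, 2):
                rows.append(dict(pair_id=pid, twin_index=ti, zygosity=z,
                                 sex="F", age=60, wave=1, t=v))
        import pandas as pd
        ds = TwinDataset(pd.DataFrame(rows))
        tc = twin_correlations(ds, "t")
        assert tc["r_MZ"] == pytest.approx(1.0)
        assert tc["r_DZ"] == pytest.approx(1.0)

    def test_independent_twins_near_zero(self):
        cfg = SimulationConfig(
            n_mz_pairs=10_000, n_dz_pairs=10_000, traits=("t",), h2=[0.0], seed=51
        )
        ds, _ = simulate_cohort(cfg)
        tc = twin_correlations(ds, "t")
        assert abs(tc["r_MZ"]) < 0.03 and abs(tc["r_DZ"]) < 0.03

    def test_insufficient_pairs_error(self, tiny_cohort):
        with pytest.raises(ValidationError):
            twin_correlations(tiny_cohort, "trait_a")


def test_twin_swap_leaves_likelihood_unchanged(small_bivariate):
    pairs = to_wide(small_bivariate, ["a", "b"])
    p = CholeskyParams(
        L_a=np.array([[0.5, 0], [0.2, 0.4]]),
        L_e=np.array([[0.8, 0], [0.1, 0.7]]),
    )
    swapped = [
        bm.WidePair(
            pair_id=w.pair_id, zygosity=w.zygosity, sex=w.sex, age=w.age,
            traits=w.traits, values_twin1=w.values_twin2.copy(),
            values_twin2=w.values_twin1.copy(),
        )
        for w in pairs
    ]
    a = minus2_log_likelihood(p, pairs)
    b = minus2_log_likelihood(p, swapped)
    assert a == pytest.approx(b, abs=1e-9)


def test_spec_requires_e():
    with pytest.raises(ValidationError):
        CholeskySpec(("a",), ("A",))
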