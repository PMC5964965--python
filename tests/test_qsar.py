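"""OLS engine, all-subsets enumeration and parabola utilities."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from tambja import FitError, InputError, enumerate_models, fit_ols, optimum_logp
from tambja.qsar import QSARModel


class TestParabolicFitOnFixture:
    def test_two_term_model_matches_published_coefficients(self, table1):
        fit = fit_ols(table1, ["alogps", "alogps-sq"])
        assert fit.n_obs == 43
        assert fit.intercept == pytest.approx(-0.579, abs=1e-3)
        assert fit.coefficients["alogps"] == pytest.approx(1.203, abs=1e-3)
        assert fit.coefficients["alogps-sq"] == pytest.approx(-0.133, abs=1e-3)
        assert fit.rsquared == pytest.approx(0.6292, abs=5e-4)

    def test_excluding_imputed_record_drops_one_observation(self, table1):
        fit = fit_ols(table1, ["alogps", "alogps-sq"], include_imputed=False)
        assert fit.n_obs == 42

    def test_optimum_logp_of_fixture_parabola(self, table1):
        fit = fit_ols(table1, ["alogps", "alogps-sq"])
        assert fit.optimum_logp() == pytest.approx(4.527, abs=5e-3)


class TestOLSEngine:
    def test_agrees_with_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        for trial in range(20):
            n, k = rng.integers(8, 30), rng.integers(1, 4)
            X = pd.DataFrame(
                rng.normal(size=(n, k)), columns=[f"d{i}" for i in range(k)]
            )
            y = rng.normal(size=n)
            fit = fit_ols(X, list(X.columns), response=y)
            Xc = np.column_stack([np.ones(n), X.to_numpy()])
            beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ y)
            assert np.allclose(fit.params.to_numpy(), beta, rtol=1e-10, atol=1e-12)

    def test_exactly_linear_response_gives_r2_one(self):
        X = pd.DataFrame({"x": np.arange(10.0)})
        fit = fit_ols(X, ["x"], response=2.0 + 3.0 * np.arange(10.0))
        assert fit.rsquared == pytest.approx(1.0)
        assert np.allclose(fit.resid, 0.0, atol=1e-12)

    def test_duplicated_column_raises_naming_collinear_terms(self):
        X = pd.DataFrame({"a": np.arange(8.0), "b": np.arange(8.0)})
        with pytest.raises(FitError, match="collinear"):
            fit_ols(X, ["a", "b"], response=np.arange(8.0))

    def test_confidence_bounds_ordered(self, table1):
        ci = fit_ols(table1, ["alogps", "alogps-sq"]).conf_int()
        assert (ci["ci_low"] < ci["ci_high"]).all()

    def test_too_few_observations_rejected(self):
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        with pytest.raises(InputError):
            QSARModel(X, ["x", "x-sq"], response=[1.0, 2.0, 3.0]).fit()


@pytest.fixture(scope="module")
def toy(table1):
    rng = np.random.default_rng(11)
    logp = table1.data["alogps"].to_numpy()
    m = pd.DataFrame({f"decoy{i}": rng.normal(size=43) for i in range(5)})
    m["ALOGPs"] = logp
    m["ALOGPs-sq"] = logp**2
    return table1.log_potency().to_numpy(), m


class TestEnumeration:
    def test_ranking_matches_brute_force_oracle(self, toy):
        y, m = toy
        ranked = enumerate_models(y, m, max_terms=3)
        # independent brute force: plain lstsq over every subset
        expected = []
        for size in range(1, 4):
            for combo in combinations(sorted(m.columns), size):
                X = np.column_stack([np.ones(len(y)), m[list(combo)].to_numpy()])
                beta, *_ = np.linalg.lstsq(X, y, rcond=None)
                r = y - X @ beta
                r2 = 1 - r @ r / np.sum((y - y.mean()) ** 2)
                expected.append((tuple(combo), r2))
        expected.sort(key=lambda t: (-t[1], t[0]))
        assert len(ranked) == len(expected)
        for fit, (terms, r2) in zip(ranked, expected):
            assert tuple(fit.terms) == terms
            assert fit.rsquared == pytest.approx(r2, abs=1e-10)

    def test_ranking_stable_under_column_shuffle(self, toy):
        y, m = toy
        shuffled = m[list(reversed(m.columns))]
        a = enumerate_models(y, m, max_terms=2)
        b = enumerate_models(y, shuffled, max_terms=2)
        assert [f.terms for f in a] == [f.terms for f in b]

    def test_adding_a_term_never_decreases_r2(self, toy):
        y, m = toy
        by_terms = {
            tuple(f.terms): f.rsquared for f in enumerate_models(y, m, max_terms=3)
        }
        for terms, r2 in by_terms.items():
            for sub_size in range(1, len(terms)):
                for sub in combinations(terms, sub_size):
                    assert by_terms[tuple(sorted(sub))] <= r2 + 1e-12

    def test_single_maximal_subset_equals_direct_fit(self, table1, toy):
        y, _ = toy
        logp = table1.data["alogps"].to_numpy()
        m = pd.DataFrame({"ALOGPs": logp, "ALOGPs-sq": logp**2})
        top = enumerate_models(y, m, max_terms=2)[0]
        assert top.terms == ["ALOGPs", "ALOGPs-sq"]
        assert top.rsquared == pytest.approx(0.6294, abs=5e-4)

    def test_identical_decoys_rank_adjacent_in_name_order(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=20)
        col = rng.normal(size=20)
        m = pd.DataFrame({"dupB": col, "dupA": col})
        ranked = enumerate_models(y, m, max_terms=1)
        assert [f.terms for f in ranked] == [["dupA"], ["dupB"]]

    def test_unknown_candidate_name_rejected(self, toy):
        y, m = toy
        with pytest.raises(InputError, match="ghost"):
            enumerate_models(y, m, max_terms=2, candidate_subset=["ghost"])

    def test_top_k_truncates(self, toy):
        y, m = toy
        assert len(enumerate_models(y, m, max_terms=2, top_k=5)) == 5


class TestOptimumLogP:
    def test_published_coefficients_give_vertex(self):
        x = np.linspace(1, 7, 30)
        y = -0.579 + 1.203 * x - 0.133 * x**2
        m = pd.DataFrame({"ALOGPs": x})
        fit = fit_ols(m, ["ALOGPs", "ALOGPs-sq"], response=y)
        assert optimum_logp(fit) == pytest.approx(1.203 / (2 * 0.133), abs=1e-6)
        assert optimum_logp(fit) == pytest.approx(4.5226, abs=1e-3)

    def test_symmetric_construction_centred_at_three(self):
        x = np.linspace(0, 6, 25)
        y = 5.0 - 0.4 * (x - 3.0) ** 2
        fit = fit_ols(pd.DataFrame({"x": x}), ["x", "x-sq"], response=y)
        assert optimum_logp(fit) == pytest.approx(3.0, abs=1e-6)

    def test_upward_parabola_has_no_interior_maximum(self):
        x = np.linspace(0, 6, 25)
        y = (x - 3.0) ** 2
        fit = fit_ols(pd.DataFrame({"x": x}), ["x", "x-sq"], response=y)
        with pytest.raises(InputError, match="no interior maximum"):
            optimum_logp(fit)
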