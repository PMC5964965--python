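"""Subgroup classification, per-group quadratics, shared-curvature models."""

import numpy as np
import pandas as pd
import pytest

from tambja import (
    CompoundTable,
    InputError,
    SharedCurvatureModel,
    classify_subgroups,
    fit_group_quadratics,
    fit_ols,
)
from tambja.subgroups import UNCLASSIFIED


def _annotated_table(logp, y, r4, r5, r6):
    n = len(logp)
    return CompoundTable(
        pd.DataFrame(
            {
                "compound_id": [str(i) for i in range(n)],
                "ec50_molpct": 10.0 ** (-np.asarray(y, float)),
                "hill_n": np.ones(n),
                "kini_pct_per_s": np.ones(n),
                "alogps": np.asarray(logp, float),
                "rt_min": np.full(n, 10.0),
                "r4": pd.Series(r4, dtype=object),
                "r5": pd.Series(r5, dtype=object),
                "r6_class": pd.Series(r6, dtype=object),
                "ec50_imputed": np.zeros(n, dtype=bool),
            }
        )
    )


class TestClassification:
    def test_composite_label_is_dot_join(self):
        t = _annotated_table([3.0], [1.0], ["OMe"], ["NH"], ["alkyl"])
        assert classify_subgroups(t).iloc[0] == "OMe.NH.alkyl"

    def test_rare_enamine_substituents_are_unclassified(self):
        t = _annotated_table(
            [3.0, 3.5], [1.0, 1.1], ["OMe", "OMe"], ["NH-CH2-Ph", "NH-py"],
            ["alkyl", "alkyl"],
        )
        assert (classify_subgroups(t) == UNCLASSIFIED).all()

    def test_missing_ring_substituent_is_unclassified(self):
        t = _annotated_table([3.0], [1.0], [None], ["NH"], ["alkyl"])
        assert classify_subgroups(t).iloc[0] == UNCLASSIFIED

    def test_fixture_without_annotations_is_fully_unclassified(self, table1):
        assert (classify_subgroups(table1) == UNCLASSIFIED).all()


class TestGroupQuadratics:
    def _three_group_table(self):
        rng = np.random.default_rng(5)
        logp, ys, r6 = [], [], []
        # distinct planted vertices: 1.09/(2*0.146) = 3.73 vs 1.8/(2*0.2) = 4.5
        coefs = {"alkyl": (0.17, 1.09, -0.146), "halogen": (-1.0, 1.8, -0.2)}
        for name, (a, b, c) in coefs.items():
            x = np.linspace(1.5, 6.5, 8)
            logp += list(x)
            ys += list(a + b * x + c * x**2)
            r6 += [name] * 8
        # a 2-point group that must be skipped
        logp += [2.0, 3.0]
        ys += [1.0, 1.2]
        r6 += ["O-R'", "O-R'"]
        n = len(logp)
        return _annotated_table(logp, ys, ["OMe"] * n, ["NH-Ph"] * n, r6), coefs

    def test_small_groups_skipped_and_exact_quadratics_recovered(self):
        t, coefs = self._three_group_table()
        labels = classify_subgroups(t)
        fits, skipped = fit_group_quadratics(t, labels)
        assert skipped == ["OMe.NH-Ph.O-R'"]
        fit = fits["OMe.NH-Ph.alkyl"]
        assert fit.intercept == pytest.approx(0.17, abs=1e-8)
        assert fit.coefficients["alogps"] == pytest.approx(1.09, abs=1e-8)
        assert fit.coefficients["alogps-sq"] == pytest.approx(-0.146, abs=1e-8)
        assert fit.rsquared == pytest.approx(1.0)

    def test_group_fits_equal_independent_ols_per_subset(self):
        t, _ = self._three_group_table()
        labels = classify_subgroups(t)
        fits, _ = fit_group_quadratics(t, labels)
        for name, fit in fits.items():
            sub = t.subset((labels == name).to_numpy())
            direct = fit_ols(sub, ["alogps", "alogps-sq"])
            assert np.allclose(fit.params, direct.params, rtol=1e-12)

    def test_group_vertices_differ_when_constructed_to_differ(self):
        t, coefs = self._three_group_table()
        fits, _ = fit_group_quadratics(t, classify_subgroups(t))
        vertices = {g: f.optimum_logp() for g, f in fits.items()}
        vals = list(vertices.values())
        assert abs(vals[0] - vals[1]) > 0.1


def _grouped_data(offsets, n_per_group=20, noise_sd=0.1, seed=0,
                  b=1.2, c=-0.13, a=-0.5):
    rng = np.random.default_rng(seed)
    xs, ys, gs = [], [], []
    for name, off in offsets.items():
        x = rng.uniform(1.0, 7.5, n_per_group)
        y = a + off + b * x + c * x**2 + rng.normal(0, noise_sd, n_per_group)
        xs += list(x)
        ys += list(y)
        gs += [name] * n_per_group
    return np.array(xs), np.array(ys), gs


class TestSharedCurvature:
    def test_single_group_reduces_to_plain_ols(self):
        x = np.linspace(1, 7, 12)
        y = -0.5 + 1.2 * x - 0.13 * x**2 + 0.01 * np.sin(x)
        fit = SharedCurvatureModel(x, y, ["only"] * 12).fit("fixed_offsets")
        direct = fit_ols(pd.DataFrame({"x": x, "x-sq": x**2}), ["x", "x-sq"],
                         response=y)
        assert fit.group_offsets == {"only": 0.0}
        assert fit.beta_linear == pytest.approx(direct.coefficients["x"], rel=1e-10)
        assert fit.global_intercept == pytest.approx(direct.intercept, rel=1e-10)

    def test_fixed_offsets_sum_to_zero(self):
        x, y, g = _grouped_data({"A": -0.5, "B": 0.0, "C": 0.5}, seed=1)
        fit = SharedCurvatureModel(x, y, g).fit("fixed_offsets")
        assert sum(fit.group_offsets.values()) == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("mode", ["fixed_offsets", "random_intercept"])
    def test_planted_offsets_recovered(self, mode):
        truth = {"A": -0.5, "B": 0.0, "C": 0.5}
        x, y, g = _grouped_data(truth, n_per_group=20, noise_sd=0.1, seed=2)
        fit = SharedCurvatureModel(x, y, g).fit(mode)
        for name, off in truth.items():
            assert fit.group_offsets[name] == pytest.approx(off, abs=0.15)
        assert fit.beta_linear == pytest.approx(1.2, rel=0.10)
        assert fit.beta_quad == pytest.approx(-0.13, rel=0.10)

    def test_random_intercept_matches_statsmodels_mixedlm(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        x, y, g = _grouped_data({"A": -0.6, "B": 0.1, "C": 0.7}, seed=4,
                                noise_sd=0.2)
        fit = SharedCurvatureModel(x, y, g).fit("random_intercept")
        df = pd.DataFrame({"y": y, "x": x, "x2": x**2, "g": g})
        ml = smf.mixedlm("y ~ x + x2", df, groups=df["g"]).fit(reml=True)
        assert fit.beta_linear == pytest.approx(ml.fe_params["x"], rel=1e-4)
        assert fit.beta_quad == pytest.approx(ml.fe_params["x2"], rel=1e-4)
        assert fit.global_intercept == pytest.approx(
            ml.fe_params["Intercept"], rel=1e-4
        )
        # two independent REML optimisers; variance agrees to ~0.5%
        assert fit.offset_variance == pytest.approx(
            float(ml.cov_re.iloc[0, 0]), rel=5e-3
        )

    def test_offset_variance_vanishes_as_groups_coincide(self):
        x, y, g = _grouped_data({"A": 0.0, "B": 0.0, "C": 0.0}, seed=6,
                                noise_sd=0.05)
        fit = SharedCurvatureModel(x, y, g).fit("random_intercept")
        assert fit.offset_variance < 1e-3
        pooled = fit_ols(pd.DataFrame({"x": x, "x-sq": x**2}), ["x", "x-sq"],
                         response=y)
        assert fit.beta_linear == pytest.approx(pooled.coefficients["x"], abs=5e-3)

    def test_reml_criterion_unimodal_on_scanned_grid(self):
        x, y, g = _grouped_data({"A": -0.5, "B": 0.5}, seed=8, noise_sd=0.1)
        model = SharedCurvatureModel(x, y, g)
        grid = np.log(np.geomspace(1e-6, 1e3, 40))
        vals = np.array([model._reml_neg2(ll) for ll in grid])
        # at most one sign change from decreasing to increasing
        diffs = np.sign(np.diff(vals))
        switches = np.sum(np.abs(np.diff(diffs[diffs != 0])) > 0)
        assert switches <= 1

    def test_random_intercept_needs_two_groups(self):
        x = np.linspace(1, 7, 10)
        y = 1.0 + x
        with pytest.raises(InputError):
            SharedCurvatureModel(x, y, ["A"] * 10).fit("random_intercept")
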