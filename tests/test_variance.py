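"""ReML variance components, ICC, reliability bands and label summaries.

The profile-ReML solver is checked against two independent oracles: the
closed-form balanced one-way ANOVA solution, and statsmodels' MixedLM (a
completely separate ReML implementation).
"""

import numpy as np
import pandas as pd
import pytest

import connvar as cv
from connvar.variance import (GLOBAL_COVARIATES, balanced_anova_components,
                              fit_metric_models)


def _balanced_data(rng, n=12, k=5, sigma_b=0.6, sigma_w=0.4, mu=2.0):
    b = rng.normal(0, sigma_b, n)
    y = mu + b[:, None] + rng.normal(0, sigma_w, (n, k))
    return y.ravel(), np.repeat(np.arange(n), k)


class TestReMLOracle:
    def test_matches_closed_form_on_50_balanced_datasets(self, rng):
        worst = 0.0
        for _ in range(50):
            y, g = _balanced_data(rng, n=int(rng.integers(6, 20)),
                                  k=int(rng.integers(3, 9)),
                                  sigma_b=float(rng.uniform(0.1, 1.5)),
                                  sigma_w=float(rng.uniform(0.1, 1.5)))
            X = np.ones((y.size, 1))
            d = cv.reml_random_intercept(y, X, g)
            sb_o, sw_o = balanced_anova_components(y, g)
            if sb_o > 0:    # interior solution: ReML == ANOVA closed form
                worst = max(worst, abs(d.sigma_b2 - sb_o) / sb_o,
                            abs(d.sigma_w2 - sw_o) / sw_o)
            else:
                assert d.sigma_b2 == 0.0
        assert worst < 1e-6

    def test_matches_statsmodels_mixedlm_with_covariates(self, rng):
        import statsmodels.api as sm
        y, g = _balanced_data(rng, n=15, k=6)
        x1 = rng.standard_normal(y.size)
        x2 = rng.standard_normal(y.size)
        y = y + 0.5 * x1 - 0.3 * x2
        X = np.column_stack([np.ones(y.size), x1, x2])
        d = cv.reml_random_intercept(y, X, g)
        md = sm.MixedLM(y, X, groups=g).fit(reml=True)
        assert d.sigma_b2 == pytest.approx(float(np.asarray(md.cov_re)[0, 0]),
                                           rel=1e-4)
        assert d.sigma_w2 == pytest.approx(float(md.scale), rel=1e-4)
        assert np.allclose(d.beta, np.asarray(md.fe_params), rtol=1e-5)

    def test_boundary_when_no_between_subject_variance(self, rng):
        hits = 0
        for _ in range(50):
            y, g = _balanced_data(rng, n=30, k=10, sigma_b=0.0, sigma_w=1.0)
            d = cv.reml_random_intercept(y, np.ones((y.size, 1)), g)
            if d.icc < 0.05:
                hits += 1
        assert hits >= 45        # 95% of the time per the boundary behavior

    def test_rank_deficient_design_rejected(self, rng):
        y, g = _balanced_data(rng)
        X = np.column_stack([np.ones(y.size), np.zeros(y.size)])
        with pytest.raises(ValueError):
            cv.reml_random_intercept(y, X, g)

    def test_session_permutation_invariance(self, rng):
        """Exchangeability: shuffling sessions within subject leaves the
        random-intercept estimates unchanged."""
        y, g = _balanced_data(rng, n=8, k=6)
        X = np.ones((y.size, 1))
        d1 = cv.reml_random_intercept(y, X, g)
        order = np.arange(y.size).reshape(8, 6)
        for row in order:
            rng.shuffle(row)
        idx = order.ravel()
        d2 = cv.reml_random_intercept(y[idx], X, g[idx])
        assert d1.sigma_b2 == pytest.approx(d2.sigma_b2, abs=1e-10)
        assert d1.sigma_w2 == pytest.approx(d2.sigma_w2, abs=1e-10)


class TestICCBands:
    def test_equal_components_moderate(self):
        d = cv.reml_random_intercept(*_mk(sigma_b=1.0, sigma_w=1.0))
        icc, band, intra, inter = cv.icc_and_bands(d)
        assert intra + inter == pytest.approx(1.0, abs=1e-12)
        assert icc == inter

    @pytest.mark.parametrize("icc,expected", [
        (0.05, "slight"), (0.2, "slight"), (0.3, "fair"), (0.4, "fair"),
        (0.5, "moderate"), (0.6, "moderate"), (0.7, "substantial"),
        (0.8, "substantial"), (0.85, "almost_perfect"), (1.0, "almost_perfect"),
        (0.0, "slight"),
    ])
    def test_band_intervals_lower_closed(self, icc, expected):
        from connvar.variance import _classify_band
        assert _classify_band(icc) == expected


def _mk(sigma_b, sigma_w, n=20, k=8, seed=0):
    rng = np.random.default_rng(seed)
    y, g = _balanced_data(rng, n=n, k=k, sigma_b=sigma_b, sigma_w=sigma_w)
    return y, np.ones((y.size, 1)), g


class TestSignificanceStrength:
    def test_scale_invariance(self, rng):
        y, g = _balanced_data(rng, mu=1.5)
        X = np.ones((y.size, 1))
        z1 = cv.significance_strength(cv.reml_random_intercept(y, X, g))
        z2 = cv.significance_strength(cv.reml_random_intercept(7.0 * y, X, g))
        assert z1 == pytest.approx(z2, rel=1e-6)

    def test_grows_with_sample_size(self, rng):
        zs = []
        for n in (10, 40, 160):
            y, g = _balanced_data(rng, n=n, k=4, mu=0.5,
                                  sigma_b=0.5, sigma_w=0.5)
            zs.append(abs(cv.significance_strength(
                cv.reml_random_intercept(y, np.ones((y.size, 1)), g))))
        assert zs[0] < zs[1] < zs[2]


class TestFitMetricModels:
    def _table(self, rng, n=10, k=4, n_targets=3):
        rows = []
        for j in range(n):
            age, sex = rng.uniform(20, 30), float(rng.integers(0, 2))
            b = rng.normal(0, 0.5)
            for i in range(k):
                fd = rng.lognormal(-2, 0.3)
                for t in range(n_targets):
                    rows.append(dict(subject=f"s{j}", session=f"e{i}",
                                     target=t, value=b + rng.normal(0, 0.5),
                                     age=age, sex=sex, meanFD=fd,
                                     mcBBR=rng.lognormal(-0.5, 0.1),
                                     gM=rng.normal(1, 0.1),
                                     jacobian=rng.normal(1, 0.05)))
        return pd.DataFrame(rows)

    def test_one_fit_per_target_with_vertex_design(self, rng):
        table = self._table(rng)
        fits = fit_metric_models(table, "vertex")
        assert set(fits) == {0, 1, 2}
        d = fits[0]
        assert d.beta_names == ("intercept", "gM", "age", "sex", "meanFD",
                                "mcBBR", "jacobian")

    def test_global_design_follows_whole_brain_model(self, rng):
        table = self._table(rng, n_targets=1)
        table["target"] = "global"
        fit = fit_metric_models(table, "global")["global"]
        assert fit.beta_names == ("intercept",) + GLOBAL_COVARIATES

    def test_missing_covariate_reported(self, rng):
        table = self._table(rng).drop(columns=["mcBBR"])
        with pytest.raises(ValueError, match="mcBBR"):
            fit_metric_models(table, "vertex")

    def test_null_covariate_barely_moves_icc(self, rng):
        """Adding a covariate with true coefficient zero should not move the
        ICC appreciably (simulation average)."""
        deltas = []
        for _ in range(30):
            y, g = _balanced_data(rng, n=20, k=6)
            X0 = np.ones((y.size, 1))
            X1 = np.column_stack([X0, rng.standard_normal(y.size)])
            d0 = cv.reml_random_intercept(y, X0, g)
            d1 = cv.reml_random_intercept(y, X1, g)
            deltas.append(d1.icc - d0.icc)
        assert abs(np.mean(deltas)) < 0.02


class TestSummarizeByLabels:
    def test_counted_example(self):
        out = cv.summarize_by_labels(np.array([0.3, 0.5, 0.7]),
                                     np.array([1, 1, 1]), 0.4)
        assert out.loc[0, "mean"] == pytest.approx(0.5)
        assert out.loc[0, "percent_high"] == pytest.approx(200.0 / 3.0)

    def test_all_below_threshold(self):
        out = cv.summarize_by_labels(np.array([0.1, 0.2]), np.array([1, 1]))
        assert out.loc[0, "percent_high"] == 0.0

    def test_zero_threshold_on_positive_values(self):
        out = cv.summarize_by_labels(np.array([0.1, 0.2]), np.array([1, 1]),
                                     threshold=0.0)
        assert out.loc[0, "percent_high"] == 100.0

    def test_masked_values_excluded_and_empty_label_reported(self):
        values = np.array([np.nan, 0.6, np.nan])
        labels = np.array([1, 2, 2])
        out = cv.summarize_by_labels(values, labels).set_index("label")
        assert out.loc[1, "n"] == 0 and np.isnan(out.loc[1, "mean"])
        assert out.loc[2, "n"] == 1 and out.loc[2, "mean"] == 0.6
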