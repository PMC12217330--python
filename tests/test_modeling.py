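"""Stepwise selection, importance decomposition, compound scores."""

import itertools

import numpy as np
import pandas as pd
import pytest

from levospeech.modeling import (
    CollinearityError,
    build_compound,
    apply_compound,
    importance,
    reference_stats_from_changes,
    stepwise_linear,
    stepwise_logistic,
    subset_r2,
)


def _noise_frame(rng, n, p, prefix="x"):
    return pd.DataFrame(
        rng.normal(size=(n, p)), columns=[f"{prefix}{i}" for i in range(p)]
    )


class TestStepwiseLinear:
    def test_signal_retained_over_noise(self, rng):
        hits = 0
        for _ in range(30):
            X = _noise_frame(rng, 500, 6)
            y = 2.0 * X["x0"] + rng.normal(size=500)
            sw = stepwise_linear(X, y)
            hits += "x0" in sw.selected
        assert hits >= 29

    def test_all_noise_mostly_empty_selection(self, rng):
        """Null candidates: intercept-only is the modal outcome and spurious
        retention stays near AIC's per-candidate rate (~0.16)."""
        empties, sizes = 0, []
        for _ in range(30):
            X = _noise_frame(rng, 500, 5)
            y = pd.Series(rng.normal(size=500))
            sw = stepwise_linear(X, y)
            empties += len(sw.selected) == 0
            sizes.append(len(sw.selected))
        assert empties >= 10
        assert np.mean(sizes) < 1.5

    def test_perfect_single_candidate(self, rng):
        X = _noise_frame(rng, 50, 1)
        sw = stepwise_linear(X, X["x0"])
        assert sw.selected == ["x0"]
        assert sw.r2 == pytest.approx(1.0)
        assert sw.aic_trace == []

    def test_aic_trace_strictly_decreasing(self, rng):
        X = _noise_frame(rng, 80, 8)
        y = X["x0"] + rng.normal(size=80)
        sw = stepwise_linear(X, y)
        aics = [a for _, a in sw.aic_trace]
        assert all(b < a for a, b in zip(aics, aics[1:])) or len(aics) <= 1

    def test_final_model_locally_aic_optimal(self, rng):
        """No single removal from the final model lowers AIC."""
        import statsmodels.api as sm

        X = _noise_frame(rng, 100, 6)
        y = X["x0"] + 0.5 * X["x1"] + rng.normal(size=100)
        sw = stepwise_linear(X, y)

        def aic(cols):
            Z = sm.add_constant(X[cols], has_constant="add")
            return sm.OLS(np.asarray(y), Z).fit().aic

        final = aic(sw.selected)
        assert final == pytest.approx(sw.final_aic, abs=1e-8)
        for f in sw.selected:
            assert aic([c for c in sw.selected if c != f]) >= final

    def test_collinear_columns_named(self, rng):
        X = _noise_frame(rng, 60, 3)
        X["x2"] = X["x0"] * 2.0
        with pytest.raises(CollinearityError, match="x0|x2"):
            stepwise_linear(X, X["x1"])

    def test_too_few_rows_rejected(self, rng):
        X = _noise_frame(rng, 6, 5)
        with pytest.raises(ValueError):
            stepwise_linear(X, rng.normal(size=6))


class TestStepwiseLogistic:
    def test_null_deviance_balanced_labels(self, rng):
        """Balanced labels: null deviance = 2 n ln 2 (~70.7 at n = 51)."""
        X = _noise_frame(rng, 51, 4)
        y = np.array([0, 1] * 25 + [1])
        y_bal = np.concatenate([np.zeros(25), np.ones(26)])
        sw = stepwise_logistic(X, y_bal)
        expected = -2 * (25 * np.log(25 / 51) + 26 * np.log(26 / 51))
        assert sw.null_deviance == pytest.approx(expected, rel=1e-6)
        assert sw.null_deviance == pytest.approx(2 * 51 * np.log(2), abs=0.05)

    def test_informative_feature_retained(self, rng):
        X = _noise_frame(rng, 200, 4)
        latent = X["x0"] * 3 + rng.normal(0, 0.5, 200)
        y = (latent > 0).astype(float)
        sw = stepwise_logistic(X, y)
        assert "x0" in sw.selected
        assert sw.residual_deviance < 0.5 * sw.null_deviance

    def test_label_noise_mostly_empty_selection(self, rng):
        empties, sizes = 0, []
        for _ in range(30):
            X = _noise_frame(rng, 300, 4)
            y = rng.integers(0, 2, 300).astype(float)
            sel = stepwise_logistic(X, y).selected
            empties += len(sel) == 0
            sizes.append(len(sel))
        assert empties >= 10
        assert np.mean(sizes) < 1.5

    def test_perfect_separation_fallback(self, rng):
        X = _noise_frame(rng, 40, 2)
        y = (X["x0"] > 0).astype(float)  # perfectly separable
        sw = stepwise_logistic(X, y)
        assert np.all(np.isfinite(sw.coefficients))

    def test_nonbinary_labels_rejected(self, rng):
        with pytest.raises(ValueError):
            stepwise_logistic(_noise_frame(rng, 30, 2), np.arange(30))


class TestSubsetR2:
    def test_empty_and_full(self, rng):
        X = _noise_frame(rng, 100, 3)
        y = (X["x0"] + rng.normal(size=100)).to_numpy()
        assert subset_r2(X, y, []) == 0.0
        sw = stepwise_linear(X[["x0"]], y)
        assert subset_r2(X, y, ["x0"]) == pytest.approx(sw.r2)

    def test_orthogonal_additivity(self, rng):
        a = rng.normal(size=(200, 3))
        a -= a.mean(axis=0)  # zero-mean columns stay orthogonal to the intercept
        q, _ = np.linalg.qr(a)
        X = pd.DataFrame(q, columns=["a", "b", "c"])
        y = (2 * X["a"] + 1 * X["b"] + 0.5 * X["c"]).to_numpy()
        total = subset_r2(X, y, ["a", "b", "c"])
        parts = sum(subset_r2(X, y, [c]) for c in X.columns)
        assert parts == pytest.approx(total, abs=1e-10)


class TestImportance:
    def test_single_feature_share_is_r2(self, rng):
        X = _noise_frame(rng, 100, 1)
        y = X["x0"] + rng.normal(size=100)
        imp = importance(X, y, method="pmvd")
        assert imp.shares["x0"] == pytest.approx(subset_r2(X, y.to_numpy(), ["x0"]))

    def test_lmg_matches_explicit_enumeration(self, rng):
        """DP over the subset lattice equals brute-force p! averaging."""
        n, p = 250, 5
        X = _noise_frame(rng, n, p)
        X["x1"] += 0.6 * X["x0"]
        y = (X["x0"] + 0.5 * X["x2"] + rng.normal(size=n)).to_numpy()
        imp = importance(X, y, method="lmg")
        cache = {}
        shares = np.zeros(p)
        for order in itertools.permutations(range(p)):
            prev, cols = 0.0, []
            for k in order:
                cols.append(X.columns[k])
                cur = subset_r2(X, y, cols, cache)
                shares[k] += cur - prev
                prev = cur
        import math
        shares /= math.factorial(p)
        np.testing.assert_allclose(imp.shares.to_numpy(), shares, atol=1e-10)

    def test_pmvd_matches_explicit_enumeration(self, rng):
        n, p = 250, 4
        X = _noise_frame(rng, n, p)
        y = (X["x0"] + 0.3 * X["x1"] + rng.normal(size=n)).to_numpy()
        imp = importance(X, y, method="pmvd")
        cache = {}
        full = subset_r2(X, y, list(X.columns), cache)
        shares, wtot = np.zeros(p), 0.0
        for order in itertools.permutations(range(p)):
            prev, w, cols, inc = 0.0, 1.0, [], np.zeros(p)
            for i, k in enumerate(order):
                cols.append(X.columns[k])
                cur = subset_r2(X, y, cols, cache)
                inc[k] = cur - prev
                prev = cur
                if i < p - 1:
                    w *= 1.0 / max(full - cur, 1e-12)
            shares += w * inc
            wtot += w
        np.testing.assert_allclose(imp.shares.to_numpy(), shares / wtot, atol=1e-10)

    @pytest.mark.parametrize("method", ["pmvd", "lmg"])
    def test_shares_sum_to_r2_and_nonnegative(self, method, default_cohort):
        X = default_cohort.change().iloc[:, :6]
        y = default_cohort.clinical_change("updrs3_no_tremor")
        imp = importance(X, y, method=method)
        assert imp.shares.sum() == pytest.approx(imp.total, abs=1e-8)
        assert (imp.shares >= 0).all()

    @pytest.mark.parametrize("method", ["pmvd", "lmg"])
    def test_column_order_permutation_invariance(self, method, rng):
        X = _noise_frame(rng, 150, 4)
        y = X["x0"] + 0.5 * X["x3"] + rng.normal(size=150)
        a = importance(X, y, method=method).shares
        perm = ["x2", "x0", "x3", "x1"]
        b = importance(X[perm], y, method=method).shares
        np.testing.assert_allclose(a.reindex(perm), b, atol=1e-10)

    def test_pmvd_exclusion_property(self, rng):
        """Correlated zero-coefficient predictor: pmvd share vanishes, LMG's does not."""
        n = 5000
        z = rng.normal(size=(n, 2))
        x1 = z[:, 0]
        x2 = 0.7 * z[:, 0] + 0.3 * z[:, 1]
        y = 2 * x1 + rng.normal(size=n)
        X = pd.DataFrame({"x1": x1, "x2": x2})
        pmvd = importance(X, y, method="pmvd")
        lmg = importance(X, y, method="lmg")
        assert pmvd.shares["x2"] / pmvd.total < 0.01
        assert lmg.shares["x2"] / lmg.total > 0.05

    def test_orthogonal_closed_form(self, rng):
        a = rng.normal(size=(400, 2))
        a -= a.mean(axis=0)
        q, _ = np.linalg.qr(a)
        y = np.sqrt(0.3) * q[:, 0] + np.sqrt(0.1) * q[:, 1] + 0.0
        X = pd.DataFrame(q, columns=["u", "v"])
        for method in ("pmvd", "lmg"):
            imp = importance(X, y, method=method)
            ratio = imp.shares["u"] / imp.shares["v"]
            assert ratio == pytest.approx(3.0, rel=1e-6)

    def test_large_p_requires_seed(self, rng):
        X = _noise_frame(rng, 100, 13)
        y = rng.normal(size=100)
        with pytest.raises(ValueError, match="seed"):
            importance(X, y, method="lmg", max_exact_p=12)
        imp = importance(X, y, method="lmg", max_exact_p=12, seed=1, n_samples=50)
        assert np.isfinite(imp.shares).all()


class TestCompound:
    @pytest.fixture()
    def fitted(self, default_cohort):
        X = default_cohort.change()
        y = default_cohort.clinical_change("updrs3_no_tremor")
        sw = stepwise_linear(X, y)
        imp = importance(X, y, sw.selected, method="pmvd")
        ref = reference_stats_from_changes(X)
        return X, y, sw, imp, ref

    def test_single_feature_weight_one(self, rng):
        X = _noise_frame(rng, 60, 1)
        y = 2 * X["x0"] + rng.normal(size=60) * 0.1
        sw = stepwise_linear(X, y)
        imp = importance(X, y, sw.selected)
        cd = build_compound(sw, imp, reference_stats_from_changes(X))
        assert cd.weights["x0"] == pytest.approx(1.0)
        z = (X["x0"] - X["x0"].mean()) / X["x0"].std(ddof=1)
        np.testing.assert_allclose(apply_compound(cd, X), z, atol=1e-12)

    def test_importance_scale_invariance(self, fitted):
        X, y, sw, imp, ref = fitted
        cd1 = build_compound(sw, imp, ref)
        imp2 = type(imp)(shares=imp.shares * 2, total=imp.total * 2, method=imp.method)
        cd2 = build_compound(sw, imp2, ref)
        np.testing.assert_allclose(cd1.weights, cd2.weights)

    def test_reference_mean_scores_zero(self, fitted):
        X, y, sw, imp, ref = fitted
        cd = build_compound(sw, imp, ref)
        at_mean = pd.Series(
            {f: cd.reference_stats.loc[f, "mean"] for f in cd.features}
        )
        assert apply_compound(cd, at_mean) == pytest.approx(0.0, abs=1e-12)

    def test_affine_rescaling_invariance(self, fitted):
        """Rescaling a raw feature is absorbed by the z-scoring reference."""
        X, y, sw, imp, ref = fitted
        cd = build_compound(sw, imp, ref)
        s1 = apply_compound(cd, X)
        feat = cd.features[0]
        X2 = X.copy()
        X2[feat] = X2[feat] * 3.0 + 5.0
        ref2 = reference_stats_from_changes(X2)
        cd2 = build_compound(sw, imp, ref2)
        np.testing.assert_allclose(apply_compound(cd2, X2), s1, atol=1e-10)

    def test_missing_feature_named(self, fitted):
        X, y, sw, imp, ref = fitted
        cd = build_compound(sw, imp, ref)
        with pytest.raises(ValueError, match=cd.features[0]):
            apply_compound(cd, X.drop(columns=[cd.features[0]]))

    def test_permuted_outcome_kills_correlation(self, fitted, rng):
        X, y, sw, imp, ref = fitted
        cd = build_compound(sw, imp, ref)
        score = apply_compound(cd, X)
        rs = [
            abs(np.corrcoef(score, rng.permutation(y))[0, 1]) for _ in range(50)
        ]
        assert np.median(rs) < 0.2
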