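"""Backward stepwise selection, relative importance, and compound scores.

Three pieces of machinery used to link biomarker changes to clinical-score
changes:

1. **Backward stepwise selection by AIC** (linear and logistic): starting
   from the full candidate set, repeatedly remove the predictor whose
   removal lowers AIC the most, stopping when no removal lowers it.

2. **Relative importance** of the selected predictors by decomposition of
   the model R² over predictor orderings:

   - *LMG*: the unweighted average over all p! orderings of each predictor's
     sequential R² increment (the Shapley value of the R² game);
   - *pmvd* (proportional marginal variance decomposition, Feldman 2005):
     the same sequential increments averaged with data-dependent ordering
     weights proportional to the inverse product of the not-yet-explained
     R² after each entry step.  pmvd has the exclusion property: predictors
     with a zero population coefficient receive a vanishing share.

   Both are computed exactly from a memoized subset-R² lattice via dynamic
   programming over the 2^p subsets (orderings never enumerated explicitly),
   with an optional seeded ordering-sampling mode for large p.  For logistic
   models the same machinery runs on McFadden pseudo-R² increments.

3. **Compound scores**: selected features are z-scored against reference
   statistics, weighted by normalized importance shares, and signed by the
   direction of the final regression coefficients.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

_EPS = 1e-12


class CollinearityError(ValueError):
    """Raised when candidate predictors are numerically collinear."""


@dataclass
class StepwiseResult:
    """Outcome of a backward stepwise run."""

    selected: list[str]
    coefficients: pd.Series  # includes "const"
    aic_trace: list[tuple[str, float]]  # (removed feature, AIC after removal)
    final_aic: float
    model_kind: str  # "linear" | "logistic"
    r2: float | None = None
    adj_r2: float | None = None
    null_deviance: float | None = None
    residual_deviance: float | None = None
    pvalues: pd.Series | None = None


@dataclass
class ImportanceDecomposition:
    """Nonnegative importance shares summing to the model (pseudo-)R²."""

    shares: pd.Series
    total: float
    method: str  # "pmvd" | "lmg"

    def normalized(self) -> pd.Series:
        """Shares rescaled to sum to 1."""
        s = self.shares.sum()
        if s <= 0:
            raise ValueError("total importance is zero; cannot normalize")
        return self.shares / s


@dataclass
class CompoundScoreDefinition:
    """A weighted, signed, z-scored combination of selected biomarker changes."""

    features: list[str]
    signs: pd.Series  # ±1 per feature, from the regression coefficients
    weights: pd.Series  # normalized importance shares, sum 1
    reference_stats: pd.DataFrame  # columns: mean, sd; one row per feature


# ---------------------------------------------------------------------------
# model adapters


def _check_collinearity(X: pd.DataFrame) -> None:
    if X.shape[1] < 2:
        return
    std = X.std(ddof=1)
    if (std == 0).any():
        bad = std.index[std == 0][0]
        raise CollinearityError(f"predictor {bad!r} is constant")
    Z = (X - X.mean()) / std
    cond = np.linalg.cond(Z.to_numpy())
    if cond > 1e8:
        corr = Z.corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        raise CollinearityError(
            f"collinear predictors (condition number {cond:.2e}): "
            f"{X.columns[i]!r} and {X.columns[j]!r}"
        )


def _fit_ols(X: pd.DataFrame, y: np.ndarray):
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


@dataclass
class _PenalizedLogitFit:
    """Minimal fit object for the small-L2 fallback under separation."""

    params: pd.Series


def _ridge_logit(Xc: pd.DataFrame, y: np.ndarray, alpha: float = 1e-2) -> _PenalizedLogitFit:
    """Newton/IRLS logistic fit with a small L2 penalty (intercept unpenalized)."""
    A = Xc.to_numpy(dtype=float)
    beta = np.zeros(A.shape[1])
    pen = alpha * np.eye(A.shape[1])
    pen[0, 0] = 0.0
    for _ in range(50):
        eta = A @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = np.maximum(p * (1 - p), 1e-10)
        H = (A * w[:, None]).T @ A + pen
        g = A.T @ (y - p) - pen @ beta
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return _PenalizedLogitFit(params=pd.Series(beta, index=Xc.columns))


def _fit_logit(X: pd.DataFrame, y: np.ndarray):
    Xc = sm.add_constant(X, has_constant="add")
    model = sm.Logit(y, Xc)
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(fit.params)) or np.abs(fit.params).max() > 1e3:
            raise ValueError("separated fit")
        return fit
    except Exception:
        logger.warning("logistic fit failed or separated; falling back to small-L2 fit")
        return _ridge_logit(Xc, y)


def _logit_deviance(fit, y: np.ndarray, X: pd.DataFrame) -> float:
    eta = sm.add_constant(X, has_constant="add").to_numpy() @ np.asarray(fit.params)
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


# ---------------------------------------------------------------------------
# backward stepwise


def _backward_stepwise(
    X: pd.DataFrame, y: np.ndarray, kind: str
) -> StepwiseResult:
    n, p = X.shape
    if n <= p + 2:
        raise ValueError(f"need n > p + 2 (n={n}, p={p})")
    mask = np.isfinite(y) & np.all(np.isfinite(X.to_numpy()), axis=1)
    dropped = int((~mask).sum())
    if dropped:
        logger.warning("dropping %d rows with missing cells", dropped)
        X, y = X[mask], y[mask]
    _check_collinearity(X)

    def aic_of(cols: list[str]) -> float:
        Xs = X[cols]
        if kind == "linear":
            return float(_fit_ols(Xs, y).aic)
        fit = _fit_logit(Xs, y)
        dev = _logit_deviance(fit, y, Xs)
        return dev + 2 * (len(cols) + 1)

    current = sorted(X.columns)  # lexicographic tie-break order
    current_aic = aic_of(current)
    trace: list[tuple[str, float]] = []
    while current:
        candidates = [(aic_of([c for c in current if c != f]), f) for f in current]
        best_aic, best_f = min(candidates)  # ties break lexicographically
        if best_aic < current_aic:
            current = [c for c in current if c != best_f]
            current_aic = best_aic
            trace.append((best_f, best_aic))
        else:
            break

    if kind == "linear":
        fit = _fit_ols(X[current], y) if current else sm.OLS(
            y, np.ones((len(y), 1))
        ).fit()
        coefficients = (
            fit.params if current else pd.Series({"const": float(np.mean(y))})
        )
        return StepwiseResult(
            selected=current,
            coefficients=coefficients,
            aic_trace=trace,
            final_aic=current_aic,
            model_kind="linear",
            r2=float(fit.rsquared) if current else 0.0,
            adj_r2=float(fit.rsquared_adj) if current else 0.0,
            pvalues=fit.pvalues if current else None,
        )

    null_fit = _fit_logit(X[[]], y)
    null_dev = _logit_deviance(null_fit, y, X[[]])
    if current:
        fit = _fit_logit(X[current], y)
        res_dev = _logit_deviance(fit, y, X[current])
        params = pd.Series(np.asarray(fit.params),
                           index=["const"] + current)
        pvals = None
        if hasattr(fit, "pvalues"):
            try:
                pvals = pd.Series(np.asarray(fit.pvalues), index=["const"] + current)
            except Exception:
                pvals = None
    else:
        params = pd.Series({"const": float(np.asarray(null_fit.params)[0])})
        res_dev = null_dev
        pvals = None
    return StepwiseResult(
        selected=current,
        coefficients=params,
        aic_trace=trace,
        final_aic=current_aic,
        model_kind="logistic",
        null_deviance=null_dev,
        residual_deviance=res_dev,
        pvalues=pvals,
    )


def stepwise_linear(X: pd.DataFrame, y: pd.Series | np.ndarray) -> StepwiseResult:
    """Backward stepwise OLS by AIC over the candidate change scores."""
    y = np.asarray(y, dtype=float)
    return _backward_stepwise(X, y, "linear")


def stepwise_logistic(X: pd.DataFrame, labels: pd.Series | np.ndarray) -> StepwiseResult:
    """Backward stepwise logistic regression by binomial-deviance AIC."""
    y = np.asarray(labels, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return _backward_stepwise(X, y, "logistic")


# ---------------------------------------------------------------------------
# subset-R² lattice and importance


def subset_r2(
    X: pd.DataFrame,
    y: np.ndarray,
    subset: tuple[str, ...] | list[str],
    _cache: dict | None = None,
) -> float:
    """OLS R² of y on a feature subset; the empty subset scores 0."""
    key = tuple(sorted(subset))
    if _cache is not None and key in _cache:
        return _cache[key]
    if not key:
        val = 0.0
    else:
        val = float(_fit_ols(X[list(key)], y).rsquared)
    if _cache is not None:
        _cache[key] = val
    return val


def _r2_lattice(X: pd.DataFrame, y: np.ndarray, features: list[str], kind: str) -> dict:
    """(Pseudo-)R² for every subset of the features, keyed by frozenset index."""
    p = len(features)
    cache: dict[frozenset, float] = {}
    if kind == "linear":
        for r in range(p + 1):
            for combo in itertools.combinations(range(p), r):
                cols = [features[i] for i in combo]
                cache[frozenset(combo)] = subset_r2(X, y, cols)
    else:
        null_fit = _fit_logit(X[[]], y)
        null_dev = _logit_deviance(null_fit, y, X[[]])
        for r in range(p + 1):
            for combo in itertools.combinations(range(p), r):
                cols = [features[i] for i in combo]
                if not cols:
                    cache[frozenset()] = 0.0
                    continue
                fit = _fit_logit(X[cols], y)
                dev = _logit_deviance(fit, y, X[cols])
                cache[frozenset(combo)] = max(0.0, 1.0 - dev / null_dev)
    return cache


def _lmg_from_lattice(r2: dict, p: int) -> np.ndarray:
    """Shapley allocation: share_k = sum over subsets S not containing k of
    |S|!(p−|S|−1)!/p! * (R²(S∪{k}) − R²(S))."""
    from math import factorial

    shares = np.zeros(p)
    fact = [factorial(i) for i in range(p + 1)]
    for S, r2s in r2.items():
        s = len(S)
        if s == p:
            continue
        w = fact[s] * fact[p - s - 1] / fact[p]
        for k in range(p):
            if k in S:
                continue
            shares[k] += w * (r2[S | {k}] - r2s)
    return shares


def _pmvd_from_lattice(r2: dict, p: int) -> np.ndarray:
    """pmvd allocation by forward/backward DP over the subset lattice.

    An ordering's weight is proportional to the product over its proper
    non-empty prefixes S of 1 / (R²_full − R²(S)) — orderings that leave
    little unexplained early receive more weight.  Shares are the
    weight-averaged sequential increments; the allocation is computed by
    summing path weights through each lattice edge rather than enumerating
    the p! orderings.
    """
    full = frozenset(range(p))
    r2_full = r2[full]

    def node_factor(S: frozenset) -> float:
        if len(S) == 0 or len(S) == p:
            return 1.0
        rem = max(r2_full - r2[S], _EPS)
        return 1.0 / rem

    subsets_by_size: list[list[frozenset]] = [[] for _ in range(p + 1)]
    for S in r2:
        subsets_by_size[len(S)].append(S)

    fwd: dict[frozenset, float] = {frozenset(): 1.0}
    for size in range(1, p + 1):
        for S in subsets_by_size[size]:
            tot = sum(fwd[S - {k}] for k in S)
            fwd[S] = tot * node_factor(S)

    bwd: dict[frozenset, float] = {full: 1.0}
    for size in range(p - 1, -1, -1):
        for S in subsets_by_size[size]:
            tot = 0.0
            for k in range(p):
                if k in S:
                    continue
                T = S | {k}
                tot += node_factor(T) * bwd[T]
            bwd[S] = tot

    Z = fwd[full]
    shares = np.zeros(p)
    for S in r2:
        s = len(S)
        if s == p:
            continue
        for k in range(p):
            if k in S:
                continue
            T = S | {k}
            weight = fwd[S] * node_factor(T) * bwd[T]
            shares[k] += weight * (r2[T] - r2[S])
    return shares / Z


def _sampled_orderings(
    r2_of: callable, p: int, method: str, n_samples: int, seed: int
) -> np.ndarray:
    rng = np.random.default_rng(seed)
    shares = np.zeros(p)
    weights_total = 0.0
    full_cols = tuple(range(p))
    r2_full = r2_of(full_cols)
    for _ in range(n_samples):
        order = rng.permutation(p)
        prev = 0.0
        incs = np.zeros(p)
        w = 1.0
        cols: list[int] = []
        for i, k in enumerate(order):
            cols.append(k)
            cur = r2_of(tuple(sorted(cols)))
            incs[k] = cur - prev
            prev = cur
            if method == "pmvd" and i < p - 1:
                w *= 1.0 / max(r2_full - cur, _EPS)
        shares += w * incs
        weights_total += w
    return shares / weights_total


def importance(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    features: list[str] | None = None,
    method: str = "pmvd",
    model_kind: str = "linear",
    max_exact_p: int = 12,
    n_samples: int = 2000,
    seed: int | None = None,
) -> ImportanceDecomposition:
    """Decompose model (pseudo-)R² into per-feature importance shares.

    Exact over the 2^p subset lattice for p <= ``max_exact_p``; beyond that
    an explicit seeded ordering-sampling mode must be requested by passing a
    seed, otherwise an error advises it.
    """
    if method not in ("pmvd", "lmg"):
        raise ValueError(f"method must be 'pmvd' or 'lmg', got {method!r}")
    features = list(features) if features is not None else list(X.columns)
    y = np.asarray(y, dtype=float)
    p = len(features)
    if p == 0:
        raise ValueError("no features to decompose")

    if p > max_exact_p:
        if seed is None:
            raise ValueError(
                f"p = {p} exceeds the exact-enumeration guard ({max_exact_p}); "
                "pass a seed to use sampled orderings"
            )
        cache: dict = {}

        def r2_of(combo: tuple[int, ...]) -> float:
            if combo in cache:
                return cache[combo]
            cols = [features[i] for i in combo]
            val = subset_r2(X, y, cols) if model_kind == "linear" else None
            if val is None:
                raise NotImplementedError("sampled logistic importance not supported")
            cache[combo] = val
            return val

        shares = _sampled_orderings(r2_of, p, method, n_samples, seed)
        total = r2_of(tuple(range(p)))
    else:
        lattice = _r2_lattice(X, y, features, model_kind)
        total = lattice[frozenset(range(p))]
        if method == "lmg":
            shares = _lmg_from_lattice(lattice, p)
        else:
            shares = _pmvd_from_lattice(lattice, p)

    shares = np.maximum(shares, 0.0)
    return ImportanceDecomposition(
        shares=pd.Series(shares, index=features), total=float(total), method=method
    )


# ---------------------------------------------------------------------------
# compound scores


def build_compound(
    sw: StepwiseResult,
    imp: ImportanceDecomposition,
    ref_stats: pd.DataFrame,
) -> CompoundScoreDefinition:
    """Assemble a compound-score definition from selection and importance.

    Signs come from the final regression coefficients, weights are the
    importance shares normalized to sum to 1, and the reference mean/SD per
    feature is captured for later z-scoring.
    """
    if sorted(imp.shares.index) != sorted(sw.selected):
        raise ValueError("importance features must equal the selected features")
    if imp.shares.sum() <= 0:
        raise ValueError("zero total importance")
    missing = [f for f in sw.selected if f not in ref_stats.index]
    if missing:
        raise ValueError(f"reference stats missing for {missing}")
    signs = np.sign(sw.coefficients.reindex(sw.selected))
    signs[signs == 0] = 1.0
    return CompoundScoreDefinition(
        features=list(sw.selected),
        signs=signs.astype(float),
        weights=imp.normalized().reindex(sw.selected),
        reference_stats=ref_stats.loc[sw.selected, ["mean", "sd"]].copy(),
    )


def apply_compound(
    definition: CompoundScoreDefinition,
    changes: pd.DataFrame | pd.Series,
) -> pd.Series | float:
    """Score = sum_k sign_k * weight_k * z_k(change_k).

    z-scoring uses the reference statistics captured at build time, so the
    score is invariant to affine rescaling of any raw feature.
    """
    single = isinstance(changes, pd.Series)
    frame = changes.to_frame().T if single else changes
    missing = [f for f in definition.features if f not in frame.columns]
    if missing:
        raise ValueError(f"missing features in input: {missing}")
    score = pd.Series(0.0, index=frame.index)
    for f in definition.features:
        mu = definition.reference_stats.loc[f, "mean"]
        sd = definition.reference_stats.loc[f, "sd"]
        if sd <= 0:
            raise ValueError(f"non-positive reference SD for {f!r}")
        z = (frame[f] - mu) / sd
        score += definition.signs[f] * definition.weights[f] * z
    return float(score.iloc[0]) if single else score


def reference_stats_from_changes(changes: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD of each change score across the cohort (the z-scoring reference)."""
    return pd.DataFrame({"mean": changes.mean(), "sd": changes.std(ddof=1)})
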