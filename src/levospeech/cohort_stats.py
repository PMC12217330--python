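"""Univariate cohort statistics for paired OFF/ON speech biomarker studies.

Implements the univariate layer of the analysis: Shapiro–Wilk-routed paired
comparisons (paired t vs Wilcoxon signed-rank), Holm–Bonferroni correction,
effect sizes with conventional magnitude labels, covariate-adjusted PD-vs-HC
regression contrasts, repeated-OFF test–retest reliability, and the exact
noncentral-t power of a paired t design.

Normality is routed on the paired *differences* — they are what the paired
tests see — at Shapiro alpha = 0.05.  The change direction is fixed as
ON − OFF throughout the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats
import statsmodels.api as sm

from levospeech.synthgen import PairedCohortTable

logger = logging.getLogger(__name__)


@dataclass
class ComparisonResult:
    """One feature's comparison: test route, p-values and effect size."""

    feature: str
    test: str  # "paired_t" | "wilcoxon" | "regression"
    statistic: float
    p_raw: float
    p_holm: float | None
    effect_size: float
    effect_type: str  # "cohen_d" | "rank_biserial" | "std_beta"
    n: int


def cohen_d_paired(diff: np.ndarray) -> float:
    """Cohen's d for paired data: mean difference / SD of differences."""
    sd = np.std(diff, ddof=1)
    if sd == 0:
        return 0.0
    return float(np.mean(diff) / sd)


def rank_biserial(diff: np.ndarray) -> float:
    """Matched-pairs rank-biserial correlation r = (W+ − W−)/(W+ + W−)."""
    nz = diff[diff != 0]
    if len(nz) == 0:
        return 0.0
    ranks = spstats.rankdata(np.abs(nz))
    w_pos = ranks[nz > 0].sum()
    w_neg = ranks[nz < 0].sum()
    return float((w_pos - w_neg) / (w_pos + w_neg))


def paired_compare(
    table: PairedCohortTable,
    feature: str,
    alpha_normality: float = 0.05,
) -> ComparisonResult:
    """Paired OFF/ON comparison with Shapiro–Wilk routing.

    Shapiro–Wilk on the ON − OFF differences decides the route: p >=
    ``alpha_normality`` -> paired t with Cohen's d; otherwise Wilcoxon
    signed-rank with the matched-pairs rank-biserial correlation.
    """
    off = table.features_off[feature]
    on = table.features_on[feature]
    diff = (on - off).dropna().to_numpy()
    if len(diff) < 3:
        raise ValueError(f"need >= 3 complete pairs for {feature!r}, got {len(diff)}")

    if np.all(diff == 0):
        logger.warning("paired_compare(%s): all differences zero; degenerate", feature)
        return ComparisonResult(feature, "wilcoxon", 0.0, 1.0, None, 0.0,
                                "rank_biserial", len(diff))

    shapiro_p = spstats.shapiro(diff).pvalue
    if shapiro_p >= alpha_normality:
        stat, p = spstats.ttest_rel(on.dropna(), off.dropna())
        return ComparisonResult(feature, "paired_t", float(stat), float(p), None,
                                cohen_d_paired(diff), "cohen_d", len(diff))
    res = spstats.wilcoxon(diff)
    return ComparisonResult(feature, "wilcoxon", float(res.statistic), float(res.pvalue),
                            None, rank_biserial(diff), "rank_biserial", len(diff))


def holm_adjust(p_values: list[float] | np.ndarray) -> np.ndarray:
    """Step-down Holm–Bonferroni adjustment, order-preserving.

    Sorted ascending, p_(i) is multiplied by (m − i), a running maximum
    enforces monotonicity, and values are capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def compare_all_features(
    table: PairedCohortTable, alpha_normality: float = 0.05
) -> pd.DataFrame:
    """Paired OFF/ON comparison of all 16 biomarkers with Holm correction."""
    results = [paired_compare(table, f, alpha_normality) for f in table.features_off.columns]
    frame = pd.DataFrame(
        {
            "feature": [r.feature for r in results],
            "test": [r.test for r in results],
            "statistic": [r.statistic for r in results],
            "p_raw": [r.p_raw for r in results],
            "effect_size": [r.effect_size for r in results],
            "effect_type": [r.effect_type for r in results],
            "effect_label": [effect_size_classify(r.effect_size) for r in results],
            "n": [r.n for r in results],
        }
    ).set_index("feature")
    frame["p_holm"] = holm_adjust(frame["p_raw"].to_numpy())
    return frame


def effect_size_classify(value: float) -> str:
    """Magnitude label on |value|: <=0.2 small, <=0.5 medium, >=0.8 large.

    The conventional thresholds leave (0.5, 0.8) unnamed; values there are
    labeled ``medium-to-large``.  Exactly zero is ``none``.
    """
    v = abs(float(value))
    if not np.isfinite(v):
        raise ValueError("effect size must be finite")
    if v == 0:
        return "none"
    if v <= 0.2:
        return "small"
    if v <= 0.5:
        return "medium"
    if v < 0.8:
        return "medium-to-large"
    return "large"


def hc_adjusted_compare(
    table: PairedCohortTable, feature: str, group: str = "OFF_vs_HC"
) -> ComparisonResult:
    """PD-vs-HC contrast adjusted for age, gender and MoCA.

    Fits ``feature ~ group + age + gender + moca`` by OLS on the pooled PD
    (one medication state) and HC rows; the group coefficient is reported
    with a standardized beta as effect size.
    """
    if table.hc_features is None or table.hc_covariates is None:
        raise ValueError("cohort table has no healthy-control rows")
    if group == "OFF_vs_HC":
        pd_vals = table.features_off[feature]
    elif group == "ON_vs_HC":
        pd_vals = table.features_on[feature]
    else:
        raise ValueError(f"group must be OFF_vs_HC or ON_vs_HC, got {group!r}")

    y = np.concatenate([pd_vals.to_numpy(), table.hc_features[feature].to_numpy()])
    g = np.concatenate([np.ones(len(pd_vals)), np.zeros(len(table.hc_features))])
    age = np.concatenate([table.demographics["age"], table.hc_covariates["age"]])
    gender = np.concatenate(
        [
            (table.demographics["gender"] == "m").astype(float),
            (table.hc_covariates["gender"] == "m").astype(float),
        ]
    )
    moca = np.concatenate([table.demographics["moca"], table.hc_covariates["moca"]])

    X = pd.DataFrame({"group": g, "age": age, "gender": gender, "moca": moca})
    keep = np.isfinite(y)
    X, y = X[keep], y[keep]
    if int(keep.sum()) < 6 or g[keep].sum() < 3 or (1 - g[keep]).sum() < 3:
        raise ValueError("need >= 3 subjects per group")
    for col in X.columns:
        if X[col].nunique() <= 1:
            raise ValueError(f"covariate {col!r} is constant; singular design")
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    beta = fit.params["group"]
    std_beta = beta * np.std(X["group"], ddof=1) / np.std(y, ddof=1)
    return ComparisonResult(feature, "regression", float(beta),
                            float(fit.pvalues["group"]), None, float(std_beta),
                            "std_beta", len(y))


def test_retest(
    off1: pd.DataFrame, off2: pd.DataFrame, alpha_normality: float = 0.05
) -> pd.Series:
    """Per-feature test–retest correlation between two OFF assessments.

    Pearson when both sessions pass Shapiro–Wilk normality, Spearman
    otherwise.  Zero-variance features yield NaN with a logged warning.
    """
    if len(off1) != len(off2) or len(off1) < 3:
        raise ValueError("need paired vectors with n >= 3")
    out = {}
    for feature in off1.columns:
        a = off1[feature].to_numpy(dtype=float)
        b = off2[feature].to_numpy(dtype=float)
        keep = np.isfinite(a) & np.isfinite(b)
        a, b = a[keep], b[keep]
        if len(a) < 3 or np.std(a) == 0 or np.std(b) == 0:
            logger.warning("test_retest(%s): undefined correlation", feature)
            out[feature] = np.nan
            continue
        normal = (
            spstats.shapiro(a).pvalue >= alpha_normality
            and spstats.shapiro(b).pvalue >= alpha_normality
        )
        r = spstats.pearsonr(a, b)[0] if normal else spstats.spearmanr(a, b)[0]
        out[feature] = float(r)
    return pd.Series(out, name="test_retest_r")


def power_paired_t(
    n: int, d: float, alpha: float = 0.05, two_sided: bool = True
) -> float:
    """Exact power of a paired t-test via the noncentral t distribution.

    With df = n − 1 and noncentrality d·sqrt(n), power is P(|T'| > t_crit)
    (two-sided) or P(T' > t_crit) (one-sided).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not np.isfinite(d):
        raise ValueError("d must be finite")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    df = n - 1
    nc = d * np.sqrt(n)
    if two_sided:
        tcrit = spstats.t.ppf(1 - alpha / 2, df)
        power = spstats.nct.sf(tcrit, df, nc) + spstats.nct.cdf(-tcrit, df, nc)
    else:
        tcrit = spstats.t.ppf(1 - alpha, df)
        power = spstats.nct.sf(tcrit, df, nc)
    return float(power)
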