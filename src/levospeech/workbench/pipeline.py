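"""End-to-end cohort analysis: univariate stats, models, compounds, transition.

``run_cohort_analysis`` reproduces the analysis order of an OFF/ON
levodopa-challenge speech study on any :class:`PairedCohortTable`:

1. paired OFF/ON comparisons of all 16 biomarkers with Holm correction
   (plus covariate-adjusted PD-vs-HC contrasts when HC rows are present);
2. backward stepwise AIC models of the hypokinetic (no-tremor MDS-UPDRS-III
   change) and hyperkinetic (axial Marconi change) outcomes, with pmvd
   relative importance;
3. weighted z-scored compound scores for both domains, correlated with
   their clinical outcomes and LOOCV-evaluated;
4. the randomized medication-state-transition experiment on the union of
   the selected feature sets.
"""

from __future__ import annotations

import logging
import time

import numpy as np
import pandas as pd

from levospeech.cohort_stats import compare_all_features, hc_adjusted_compare
from levospeech.evaluation import (
    loocv_regression,
    make_transition_dataset,
    predict_subscores,
    transition_eval,
)
from levospeech.modeling import (
    build_compound,
    importance,
    reference_stats_from_changes,
    stepwise_linear,
)
from levospeech.synthgen import PairedCohortTable
from levospeech.workbench.config import PipelineConfig

logger = logging.getLogger(__name__)


def _fit_domain(
    X: pd.DataFrame, y: pd.Series, config: PipelineConfig, name: str
) -> dict:
    """Stepwise model + importance + compound + LOOCV for one outcome."""
    t0 = time.perf_counter()
    sw = stepwise_linear(X, y)
    out: dict = {"stepwise": sw}
    if sw.selected:
        imp = importance(
            X, y, sw.selected,
            method=config.importance_method,
            max_exact_p=config.max_exact_p,
            seed=config.seed if len(sw.selected) > config.max_exact_p else None,
        )
        compound = build_compound(sw, imp, reference_stats_from_changes(X))
        from levospeech.modeling import apply_compound

        score = apply_compound(compound, X)
        out.update(
            importance=imp,
            compound=compound,
            compound_scores=score,
            compound_r=float(np.corrcoef(score, y)[0, 1]),
            loocv=loocv_regression(X, y, sw.selected),
            compound_loocv=loocv_regression(score.to_frame("compound"), y),
        )
    logger.info("%s model fitted in %.2f s (selected %d features)",
                name, time.perf_counter() - t0, len(sw.selected))
    return out


def run_cohort_analysis(
    table: PairedCohortTable, config: PipelineConfig | None = None
) -> dict:
    """Run the full feature-level analysis chain; returns a results dict."""
    config = config or PipelineConfig()
    logger.info("pipeline start (config hash %s, seed %d)", config.hash(), config.seed)
    results: dict = {"config": config.to_dict(), "config_hash": config.hash()}

    t0 = time.perf_counter()
    results["paired_comparisons"] = compare_all_features(table, config.shapiro_alpha)
    if table.hc_features is not None:
        hc = {}
        for group in ("OFF_vs_HC", "ON_vs_HC"):
            rows = {}
            for feature in table.features_off.columns:
                r = hc_adjusted_compare(table, feature, group)
                rows[feature] = {
                    "beta": r.statistic, "p_raw": r.p_raw, "std_beta": r.effect_size,
                }
            hc[group] = pd.DataFrame(rows).T
        results["hc_contrasts"] = hc
    logger.info("univariate stage done in %.2f s", time.perf_counter() - t0)

    X = table.change()
    y_hypo = table.clinical_change("updrs3_no_tremor")
    y_hyper = table.clinical_change("marconi_axial")

    results["hypokinetic"] = _fit_domain(X, y_hypo, config, "hypokinetic")
    results["hyperkinetic"] = _fit_domain(X, y_hyper, config, "hyperkinetic")

    hypo_sel = results["hypokinetic"]["stepwise"].selected
    if hypo_sel:
        results["subscores"] = predict_subscores(table, hypo_sel)

    pool = sorted(set(hypo_sel) | set(results["hyperkinetic"]["stepwise"].selected))
    if len(pool) >= 2:
        ds = make_transition_dataset(table, seed=config.seed)
        results["transition"] = transition_eval(
            ds, pool,
            threshold=config.classification_threshold,
            nested_selection=config.nested_selection,
        )
        results["transition_pool"] = pool
    logger.info("pipeline complete")
    return results


def render_report(results: dict) -> str:
    """Human-readable summary mirroring the layout of published model tables."""
    lines: list[str] = []
    comp = results["paired_comparisons"]
    lines.append("PAIRED OFF/ON COMPARISONS (Holm-adjusted)")
    lines.append(f"{'feature':<16}{'test':<10}{'p_raw':>8}{'p_holm':>8}{'effect':>8}  label")
    for feat, row in comp.iterrows():
        lines.append(
            f"{feat:<16}{row['test']:<10}{row['p_raw']:>8.3f}{row['p_holm']:>8.3f}"
            f"{row['effect_size']:>8.2f}  {row['effect_label']}"
        )
    for name, label in (("hypokinetic", "HYPOKINETIC FEATURES MODEL"),
                        ("hyperkinetic", "HYPERKINETIC FEATURES MODEL")):
        dom = results.get(name)
        if not dom:
            continue
        sw = dom["stepwise"]
        lines.append("")
        lines.append(f"{label} (backward stepwise by AIC)")
        order = sw.selected
        if "importance" in dom:
            order = list(dom["importance"].shares.sort_values(ascending=False).index)
        lines.append(f"{'term':<18}{'estimate':>12}{'importance':>12}")
        lines.append(f"{'INTERCEPT':<18}{sw.coefficients.get('const', float('nan')):>12.4f}{'':>12}")
        for feat in order:
            share = dom["importance"].shares[feat] if "importance" in dom else float("nan")
            lines.append(f"{feat:<18}{sw.coefficients[feat]:>12.4f}{share:>12.4f}")
        lines.append(f"Multiple R2: {sw.r2:.2f}; Adj. R2: {sw.adj_r2:.2f}; AIC: {sw.final_aic:.1f}")
        if "loocv" in dom:
            lv = dom["loocv"]
            lines.append(
                f"LOOCV: MAE {lv.mae:.2f}, RMSE {lv.rmse:.2f}, R2_pred {lv.r2_pred:.2f}; "
                f"compound r = {dom['compound_r']:.2f}"
            )
    tr = results.get("transition")
    if tr is not None:
        lines.append("")
        lines.append("MEDICATION-STATE TRANSITION MODEL")
        lines.append(f"pool: {', '.join(results['transition_pool'])}")
        lines.append(f"selected: {', '.join(tr.selected)}")
        lo, hi = tr.accuracy_ci
        lines.append(
            f"AUC {tr.auc:.2f}; accuracy {tr.accuracy:.0%} (95% CI {lo:.2f}-{hi:.2f}); "
            f"sens {tr.sensitivity:.0%}; spec {tr.specificity:.0%}; "
            f"PPV {tr.ppv:.0%}; NPV {tr.npv:.0%}"
        )
    return "\n".join(lines)
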