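"""LOOCV evaluation, subscore prediction, and the medication-state-transition
experiment.

Leave-one-out cross-validation refits the *coefficients* of a fixed feature
set per fold; feature selection is performed once on the full data (nested
re-selection is available behind a flag for honesty about selection
optimism).  The transition experiment randomizes each subject's change
vector to an OFF→ON (label 0, ON − OFF) or ON→OFF (label 1, the negation)
orientation with a fair coin, then asks a stepwise logistic model to recover
the orientation — emulating detection of a medication-state transition from
a single pair of recordings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats

from levospeech.modeling import (
    _fit_logit,
    stepwise_logistic,
)
from levospeech.synthgen import PairedCohortTable

logger = logging.getLogger(__name__)

import statsmodels.api as sm


@dataclass
class EvaluationReport:
    """LOOCV metrics for a regression or classification model."""

    mode: str  # "regression" | "classification"
    predictions: pd.Series
    mae: float | None = None
    rmse: float | None = None
    r2_pred: float | None = None
    auc: float | None = None
    accuracy: float | None = None
    accuracy_ci: tuple[float, float] | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    ppv: float | None = None
    npv: float | None = None
    selected: list[str] | None = None


@dataclass
class TransitionDataset:
    """Randomly oriented change vectors with transition labels.

    Label 0 keeps the ON − OFF change (an OFF→ON transition); label 1 stores
    its elementwise negation (an ON→OFF transition).
    """

    X: pd.DataFrame
    labels: pd.Series
    seed: int


def loocv_regression(
    X: pd.DataFrame, y: pd.Series | np.ndarray, features: list[str] | None = None
) -> EvaluationReport:
    """LOOCV of a fixed-feature OLS model.

    For each held-out subject the coefficients are refit on the remaining
    n − 1 (the feature set itself is not re-selected).  Reports MAE, RMSE and
    R²_pred = 1 − SSE_loo / SST, which can be negative for uninformative
    models.
    """
    features = list(features) if features is not None else list(X.columns)
    y = pd.Series(np.asarray(y, dtype=float), index=X.index)
    n = len(y)
    if n < len(features) + 3:
        raise ValueError("need n >= p + 3 for LOOCV")
    A = X[features] if features else pd.DataFrame(index=X.index)
    preds = pd.Series(index=X.index, dtype=float)
    for i, idx in enumerate(X.index):
        train = X.index != idx
        At = sm.add_constant(A[train], has_constant="add")
        design = At.to_numpy()
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError(f"singular design in fold {i}")
        fit = sm.OLS(y[train], At).fit()
        row = pd.DataFrame([A.loc[idx]]) if features else pd.DataFrame(index=[idx])
        row = sm.add_constant(row, has_constant="add")
        pred = fit.predict(row.reindex(columns=At.columns, fill_value=1.0))
        preds[idx] = float(np.asarray(pred)[0])
    resid = y - preds
    sst = float(np.sum((y - y.mean()) ** 2))
    return EvaluationReport(
        mode="regression",
        predictions=preds,
        mae=float(np.mean(np.abs(resid))),
        rmse=float(np.sqrt(np.mean(resid**2))),
        r2_pred=1.0 - float(np.sum(resid**2)) / sst if sst > 0 else np.nan,
        selected=features,
    )


SUBSCORE_COLUMNS = {
    "bradykinesia": "updrs3_brady",
    "axial": "updrs3_axial",
    "rigidity": "updrs3_rigidity",
    "tremor": "updrs3_tremor",
}


def predict_subscores(
    table: PairedCohortTable, features: list[str]
) -> dict[str, EvaluationReport]:
    """LOOCV of the fixed hypokinetic feature set against each motor-subscore
    change (bradykinesia, axial, rigidity, tremor)."""
    X = table.change()[features]
    out = {}
    for name, col in SUBSCORE_COLUMNS.items():
        y = table.clinical_change(col)
        if np.std(y) == 0:
            raise ValueError(f"subscore {name!r} change has zero variance")
        out[name] = loocv_regression(X, y, features)
    return out


def make_transition_dataset(
    table: PairedCohortTable, seed: int = 0
) -> TransitionDataset:
    """Fair-coin orientation of each subject's change vector.

    Returns the oriented matrix and the labels: 0 -> row is ON − OFF,
    1 -> row is −(ON − OFF).
    """
    change = table.change()
    if change.isna().any().any():
        raise ValueError("complete change vectors required")
    rng = np.random.default_rng(seed)
    labels = pd.Series(rng.integers(0, 2, len(change)), index=change.index)
    oriented = change.where(labels == 0, -change)
    return TransitionDataset(X=oriented, labels=labels, seed=seed)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC = P(score⁺ > score⁻) + ½ P(tie), via the Mann–Whitney rank statistic."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    ranks = spstats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial confidence interval for a proportion."""
    lo = spstats.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
    hi = spstats.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
    return float(lo), float(hi)


def transition_eval(
    ds: TransitionDataset,
    pool: list[str],
    threshold: float = 0.5,
    nested_selection: bool = False,
) -> EvaluationReport:
    """Stepwise logistic transition model with LOOCV predicted probabilities.

    Selection runs once on the full dataset (or per fold when
    ``nested_selection``); coefficients are refit per fold; AUC is computed
    on the pooled leave-one-out probabilities and the confusion metrics at
    the given threshold, with a Clopper–Pearson interval for accuracy.
    """
    unknown = [f for f in pool if f not in ds.X.columns]
    if unknown:
        raise ValueError(f"pool features not in dataset: {unknown}")
    if ds.labels.nunique() < 2:
        raise ValueError("both transition classes must be present")
    X, y = ds.X[pool], ds.labels.astype(float)

    sw = stepwise_logistic(X, y)
    probs = pd.Series(index=X.index, dtype=float)
    for idx in X.index:
        train = X.index != idx
        if nested_selection:
            sel = stepwise_logistic(X[train], y[train]).selected
        else:
            sel = sw.selected
        Xt = X.loc[train, sel]
        fit = _fit_logit(Xt, y[train].to_numpy())
        row = np.concatenate([[1.0], X.loc[idx, sel].to_numpy()])
        eta = float(np.clip(row @ np.asarray(fit.params), -35, 35))
        probs[idx] = 1.0 / (1.0 + np.exp(-eta))

    pred = (probs >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    n = len(y)
    correct = tp + tn
    return EvaluationReport(
        mode="classification",
        predictions=probs,
        auc=roc_auc(probs.to_numpy(), y.to_numpy()),
        accuracy=correct / n,
        accuracy_ci=clopper_pearson(correct, n),
        sensitivity=tp / (tp + fn) if tp + fn else np.nan,
        specificity=tn / (tn + fp) if tn + fp else np.nan,
        ppv=tp / (tp + fp) if tp + fp else np.nan,
        npv=tn / (tn + fn) if tn + fn else np.nan,
        selected=sw.selected,
    )
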