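"""Single-feature ROC discrimination between diagnostic groups.

A univariate logistic model is fit on a stratified 50% train split; the
held-out half is scored and ranked into an ROC. The AUC confidence
interval comes from a stratified bootstrap of the test half and the
p-value from the rank-sum relation between the two classes' scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve

from .exceptions import DesignError, EvaluationError, SplitError


@dataclass
class ROCResult:
    feature: tuple[str, str]  # (band, metric)
    contrast: tuple[str, str]  # (negative class, positive class)
    auc: float
    ci_low: float
    ci_high: float
    p: float
    curve: list[tuple[float, float]]
    split_seed: int
    n_train: int = 0
    n_test: int = 0


def split_half(
    records: pd.DataFrame, seed: int, label_col: str = "group"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic stratified 50/50 split; both halves keep every class."""
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for label, block in records.groupby(label_col, sort=True):
        n = len(block)
        if n < 2:
            raise SplitError(f"class {label!r} has {n} member(s); need ≥ 2 to split")
        perm = rng.permutation(n)
        half = n // 2
        test_parts.append(block.iloc[perm[:half]])
        train_parts.append(block.iloc[perm[half:]])
    return (
        pd.concat(train_parts).sort_index(),
        pd.concat(test_parts).sort_index(),
    )


def _auc_trapezoid(fpr: np.ndarray, tpr: np.ndarray) -> float:
    return float(np.trapezoid(tpr, fpr))


def fit_score_roc(
    train: pd.DataFrame,
    test: pd.DataFrame,
    feature: str,
    label_col: str = "group",
    positive: str | None = None,
    seed: int = 0,
    n_bootstrap: int = 2000,
) -> ROCResult:
    """Fit a univariate logistic model on train, evaluate ROC on test."""
    classes = sorted(set(train[label_col]) | set(test[label_col]))
    if len(classes) != 2:
        raise DesignError(f"binary contrast required, got classes {classes}")
    if positive is None:
        positive = classes[1]
    negative = classes[0] if positive == classes[1] else classes[1]
    y_test = (test[label_col] == positive).to_numpy()
    if y_test.all() or not y_test.any():
        raise EvaluationError("test half contains a single class")

    x_train = train[[feature]].to_numpy(dtype=np.float64)
    y_train = (train[label_col] == positive).to_numpy()
    if np.ptp(x_train) == 0:
        # constant feature: logistic fit is degenerate, scores carry no ranking
        scores = np.zeros(len(test))
    else:
        # effectively unpenalized (large C keeps the API stable across versions)
        model = LogisticRegression(C=1e12, solver="lbfgs", max_iter=1000)
        model.fit(x_train, y_train)
        scores = model.decision_function(test[[feature]].to_numpy(dtype=np.float64))

    fpr, tpr, _ = roc_curve(y_test, scores)
    auc = _auc_trapezoid(fpr, tpr)

    rng = np.random.default_rng(seed)
    pos_scores = scores[y_test]
    neg_scores = scores[~y_test]
    boot = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        ps = rng.choice(pos_scores, size=len(pos_scores), replace=True)
        ns = rng.choice(neg_scores, size=len(neg_scores), replace=True)
        boot[b] = _rank_auc(ns, ps)
    ci_low, ci_high = np.quantile(boot, [0.025, 0.975])

    if np.ptp(scores) == 0:
        p = 1.0
    else:
        p = float(
            stats.mannwhitneyu(pos_scores, neg_scores, alternative="two-sided").pvalue
        )

    return ROCResult(
        feature=("", feature),
        contrast=(negative, positive),
        auc=auc,
        ci_low=float(min(ci_low, auc)),
        ci_high=float(max(ci_high, auc)),
        p=p,
        curve=list(zip(fpr.tolist(), tpr.tolist())),
        split_seed=seed,
        n_train=len(train),
        n_test=len(test),
    )


def _rank_auc(neg: np.ndarray, pos: np.ndarray) -> float:
    """AUC via the Mann-Whitney identity (ties count half)."""
    pooled = np.concatenate([neg, pos])
    ranks = stats.rankdata(pooled)
    r_pos = ranks[len(neg) :].sum()
    n_pos, n_neg = len(pos), len(neg)
    u = r_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def run_contrasts(
    records: pd.DataFrame,
    features: Sequence[tuple[str, str]],
    contrasts: Sequence[tuple[str, str]],
    seed: int,
    label_col: str = "group",
    n_bootstrap: int = 2000,
) -> list[ROCResult]:
    """One ROCResult per feature × contrast.

    ``records`` is wide-format: one row per subject, a group column, and one
    column per (band, metric) feature named ``"{band}:{metric}"``.
    """
    present = set(records[label_col])
    results = []
    for ga, gb in contrasts:
        if ga not in present or gb not in present:
            raise DesignError(f"contrast ({ga}, {gb}) names a group absent from data")
        subset = records[records[label_col].isin([ga, gb])]
        train, test = split_half(subset, seed=seed, label_col=label_col)
        for band, metric in features:
            col = f"{band}:{metric}"
            if col not in records.columns:
                raise DesignError(f"feature column {col!r} missing")
            res = fit_score_roc(
                train, test, col,
                label_col=label_col, positive=gb, seed=seed,
                n_bootstrap=n_bootstrap,
            )
            res.feature = (band, metric)
            results.append(res)
    return results


def results_to_frame(results: Sequence[ROCResult]) -> pd.DataFrame:
    rows = [
        {
            "band": r.feature[0],
            "metric": r.feature[1],
            "contrast": f"{r.contrast[1]} vs {r.contrast[0]}",
            "auc": r.auc,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "p": r.p,
            "n_train": r.n_train,
            "n_test": r.n_test,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
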