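"""Group-level nonparametric inference and covariate-adjusted correlations.

Omnibus Kruskal-Wallis per (band, metric), Dunn's z post-hoc gated on
omnibus significance, Holm-Bonferroni multiplicity control within a
configurable family (per band by default), Mann-Whitney for two-group
contrasts, and Pearson/partial correlations via residualization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DesignError, ParameterError

GROUPS = ("HC", "MCI-AD", "AD")


@dataclass
class GroupTestResult:
    metric: tuple[str, str]  # (band, metric name)
    h_statistic: float
    df: int
    p_omnibus: float
    pairwise: dict[tuple[str, str], float] = field(default_factory=dict)
    p_adjusted: float = float("nan")
    group_means: dict[str, float] = field(default_factory=dict)
    group_sds: dict[str, float] = field(default_factory=dict)


@dataclass
class CorrelationResult:
    x: str
    y: str
    r: float
    p: float
    n: int
    covariates: list[str] = field(default_factory=list)


def _rank_all(samples: Sequence[Sequence[float]]) -> tuple[list[np.ndarray], np.ndarray]:
    pooled = np.concatenate([np.asarray(s, dtype=np.float64) for s in samples])
    ranks = stats.rankdata(pooled)
    out, start = [], 0
    for s in samples:
        out.append(ranks[start : start + len(s)])
        start += len(s)
    return out, pooled


def _tie_term(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts**3 - counts))


def kruskal_wallis(samples: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H with χ² p-value (df = groups − 1).

    Degenerate input (all pooled observations identical) returns H = 0, p = 1.
    """
    if len(samples) < 2 or any(len(s) == 0 for s in samples):
        raise ParameterError("need ≥2 groups, each non-empty")
    group_ranks, pooled = _rank_all(samples)
    n = len(pooled)
    df = len(samples) - 1
    tie = _tie_term(pooled)
    correction = 1.0 - tie / (n**3 - n) if n > 1 else 0.0
    if correction <= 0:
        return 0.0, df, 1.0
    h = 12.0 / (n * (n + 1)) * sum(
        len(r) * (r.mean() - (n + 1) / 2.0) ** 2 for r in group_ranks
    )
    h /= correction
    p = float(stats.chi2.sf(h, df))
    return float(h), df, p


def dunn_posthoc(
    samples: Sequence[Sequence[float]],
    labels: Sequence[str],
    pairs: Sequence[tuple[str, str]] | None = None,
) -> dict[tuple[str, str], float]:
    """Dunn's pairwise z tests on pooled ranks with tie correction.

    Returns two-sided p per requested pair (all pairs by default).
    """
    if any(len(s) == 0 for s in samples):
        raise ParameterError("empty group in Dunn post-hoc")
    if len(labels) != len(samples):
        raise ParameterError("labels must match samples")
    group_ranks, pooled = _rank_all(samples)
    n = len(pooled)
    tie = _tie_term(pooled)
    variance_base = n * (n + 1) / 12.0 - tie / (12.0 * (n - 1))
    mean_ranks = {lab: r.mean() for lab, r in zip(labels, group_ranks)}
    sizes = {lab: len(r) for lab, r in zip(labels, group_ranks)}

    if pairs is None:
        pairs = [
            (labels[i], labels[j])
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        ]
    out: dict[tuple[str, str], float] = {}
    for a, b in pairs:
        if a not in mean_ranks or b not in mean_ranks:
            raise DesignError(f"unknown group in pair ({a}, {b})")
        se = np.sqrt(variance_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        if se == 0:
            out[(a, b)] = 1.0
            continue
        z = (mean_ranks[a] - mean_ranks[b]) / se
        out[(a, b)] = float(2.0 * stats.norm.sf(abs(z)))
    return out


def holm_adjust(pvals: Sequence[float]) -> list[float]:
    """Holm-Bonferroni step-down adjustment, capped at 1, order-preserving."""
    p = np.asarray(pvals, dtype=np.float64)
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p[idx]))
        adjusted[idx] = running
    return adjusted.tolist()


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (exact for small tie-free samples)."""
    if len(a) == 0 or len(b) == 0:
        raise ParameterError("both samples must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def pearson(
    x: Sequence[float],
    y: Sequence[float],
    covariates: np.ndarray | None = None,
    x_name: str = "x",
    y_name: str = "y",
    covariate_names: Sequence[str] = (),
) -> CorrelationResult:
    """Pearson correlation, optionally partial (residualized on covariates).

    With covariates, x and y are each regressed on [1, covariates]; the
    residuals are correlated and the t-test df is reduced by the covariate
    count. An empty covariate matrix reproduces the plain Pearson r exactly.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1-D and equally long")
    k = 0
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=np.float64)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        if covariates.shape[0] != len(x):
            raise ParameterError("covariate rows must match x length")
        k = covariates.shape[1]
    n = len(x)
    if n < 3 + k:
        raise ParameterError(f"need at least {3 + k} observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ParameterError("zero variance in x or y: correlation undefined")

    if k:
        design = np.column_stack([np.ones(n), covariates])
        x = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
        y = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
        if np.std(x) == 0 or np.std(y) == 0:
            raise ParameterError("residual variance is zero after adjustment")

    r = float(np.corrcoef(x, y)[0, 1])
    df = n - 2 - k
    r_clip = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r_clip * np.sqrt(df / (1.0 - r_clip**2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return CorrelationResult(
        x=x_name, y=y_name, r=r, p=p, n=n, covariates=list(covariate_names)
    )


def run_group_analysis(
    table: pd.DataFrame,
    groups: pd.Series | pd.DataFrame,
    alpha: float = 0.05,
    family_rule: str = "per_band",
) -> list[GroupTestResult]:
    """Omnibus + post-hoc testing for every (band, metric) cell.

    ``table`` is long-format with columns subject, band, metric, value;
    ``groups`` maps subject → group label (Series, or a DataFrame with
    subject_id/group columns). Dunn's test runs only where the omnibus
    p < alpha; Holm adjustment is applied to omnibus p-values within each
    band (``family_rule='per_band'``) or across all cells (``'global'``).
    """
    if family_rule not in ("per_band", "global"):
        raise ParameterError(f"unknown family_rule {family_rule!r}")
    if isinstance(groups, pd.DataFrame):
        groups = groups.set_index("subject_id")["group"]
    required = {"subject", "band", "metric", "value"}
    if not required.issubset(table.columns):
        raise DesignError(f"metrics table must have columns {sorted(required)}")

    merged = table.copy()
    merged["group"] = merged["subject"].map(groups)
    if merged["group"].isna().any():
        missing = merged.loc[merged["group"].isna(), "subject"].unique().tolist()
        raise DesignError(f"subjects without group label: {missing}")
    present = sorted(merged["group"].unique(), key=lambda g: GROUPS.index(g) if g in GROUPS else 99)
    if len(present) < 2:
        raise DesignError("group analysis needs at least 2 groups")

    results: list[GroupTestResult] = []
    for (band, metric), cell in merged.groupby(["band", "metric"], sort=False):
        by_group = [cell.loc[cell["group"] == g, "value"].to_numpy() for g in present]
        if any(len(v) == 0 for v in by_group):
            raise DesignError(f"group absent from ({band}, {metric}) data")
        h, df, p = kruskal_wallis(by_group)
        res = GroupTestResult(
            metric=(str(band), str(metric)),
            h_statistic=h,
            df=df,
            p_omnibus=p,
            group_means={g: float(v.mean()) for g, v in zip(present, by_group)},
            group_sds={g: float(v.std(ddof=1)) if len(v) > 1 else 0.0 for g, v in zip(present, by_group)},
        )
        if p < alpha and len(present) > 2:
            res.pairwise = dunn_posthoc(by_group, present)
        results.append(res)

    if family_rule == "global":
        adj = holm_adjust([r.p_omnibus for r in results])
        for r, a in zip(results, adj):
            r.p_adjusted = a
    else:
        by_band: dict[str, list[GroupTestResult]] = {}
        for r in results:
            by_band.setdefault(r.metric[0], []).append(r)
        for band_results in by_band.values():
            adj = holm_adjust([r.p_omnibus for r in band_results])
            for r, a in zip(band_results, adj):
                r.p_adjusted = a
    return results


def correlation_table(
    features: pd.DataFrame,
    targets: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Pearson (or covariate-adjusted partial) correlations, all pairs.

    ``features`` and ``targets`` are indexed alike (one row per subject);
    every feature column is correlated with every target column. Rows with
    missing values in a pair (or the covariates) are dropped pairwise.
    Returns a long table (x, y, r, p, n).
    """
    rows = []
    cov_names = list(covariates.columns) if covariates is not None else []
    for x_name in features.columns:
        for y_name in targets.columns:
            block = pd.concat(
                [features[x_name], targets[y_name]]
                + ([covariates] if covariates is not None else []),
                axis=1,
            ).dropna()
            if len(block) < 3 + len(cov_names):
                continue
            if block[x_name].std() == 0 or block[y_name].std() == 0:
                continue  # constant column: correlation undefined, skip the cell
            res = pearson(
                block[x_name].to_numpy(dtype=float),
                block[y_name].to_numpy(dtype=float),
                covariates=block[cov_names].to_numpy(dtype=float) if cov_names else None,
                x_name=str(x_name),
                y_name=str(y_name),
                covariate_names=cov_names,
            )
            rows.append(
                {"x": res.x, "y": res.y, "r": res.r, "p": res.p, "n": res.n}
            )
    return pd.DataFrame(rows)


def results_to_frame(results: Sequence[GroupTestResult]) -> pd.DataFrame:
    """Flatten GroupTestResults into a report table."""
    rows = []
    for r in results:
        row: dict[str, object] = {
            "band": r.metric[0],
            "metric": r.metric[1],
            "chi2": r.h_statistic,
            "df": r.df,
            "p": r.p_omnibus,
            "p_holm": r.p_adjusted,
        }
        for g, m in r.group_means.items():
            row[f"mean_{g}"] = m
            row[f"sd_{g}"] = r.group_sds[g]
        for (a, b), p in r.pairwise.items():
            row[f"dunn_{a}_vs_{b}"] = p
        rows.append(row)
    return pd.DataFrame(rows)
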