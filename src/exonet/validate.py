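"""Diagnostic and prognostic validation of key features.

Per-feature diagnostic ROC/AUC (rank-based concordance with ties counting
one half) with stratified-bootstrap 95% confidence intervals; overall
survival by median-expression split with Kaplan-Meier curves and a
two-group log-rank test; tumor-stage association by Kruskal-Wallis; and
MSS vs MSI-H phenotype comparison by Wilcoxon rank-sum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .errors import InputError


@dataclass
class RocResult:
    feature_id: str
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int


def _auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 * P(tie)."""
    ranks = stats.rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    r_pos = ranks[labels == 1].sum()
    return (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def roc_auc(scores, labels, feature_id: str = "", n_boot: int = 2000,
            seed: int = 0) -> RocResult:
    """AUC with a stratified-bootstrap percentile 95% CI.

    Positives and negatives are resampled separately so every bootstrap
    replicate contains both classes.  The interval is widened to contain
    the point estimate when the bootstrap distribution is degenerate.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise InputError("scores and labels must have the same length")
    if set(np.unique(labels)) != {0, 1}:
        raise InputError("labels must contain both classes (0 and 1)")
    auc = _auc_rank(scores, labels)

    rng = np.random.default_rng(seed)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    boot = np.empty(n_boot)
    for b in range(n_boot):
        sp = rng.choice(pos, size=pos.size, replace=True)
        sn = rng.choice(neg, size=neg.size, replace=True)
        s = np.concatenate([sp, sn])
        lab = np.concatenate([np.ones(pos.size, int), np.zeros(neg.size, int)])
        boot[b] = _auc_rank(s, lab)
    lo, hi = np.quantile(boot, [0.025, 0.975])
    return RocResult(feature_id=feature_id, auc=float(auc),
                     ci_low=float(min(lo, auc)), ci_high=float(max(hi, auc)),
                     n_pos=pos.size, n_neg=neg.size)


@dataclass
class SurvivalResult:
    feature_id: str
    statistic: float
    p_value: float
    n_high: int
    n_low: int
    curves: dict    # group -> DataFrame(time, survival, at_risk)


def _km_curve(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    curve = kmf.survival_function_.reset_index()
    curve.columns = ["time", "survival"]
    at_risk = kmf.event_table["at_risk"].reindex(curve["time"]).to_numpy()
    curve["at_risk"] = at_risk
    return curve


def km_logrank_median_split(expression: pd.Series, metadata: pd.DataFrame,
                            feature_id: str = "") -> SurvivalResult:
    """Median-split overall survival with a two-group log-rank test.

    Samples with expression <= median go to the "low" group (deterministic
    tie policy).  Requires tumor samples with survival_time and event.
    """
    meta = metadata.loc[metadata["group"] == "tumor"]
    meta = meta.dropna(subset=["survival_time", "event"])
    common = [s for s in meta.index if s in expression.index]
    meta = meta.loc[common]
    expr = expression.loc[common].astype(float)
    if expr.nunique() <= 1:
        raise InputError(f"degenerate median split for feature {feature_id!r}: "
                         "all expression values equal")
    median = expr.median()
    low = (expr <= median).to_numpy()
    if low.sum() < 2 or (~low).sum() < 2:
        raise InputError("need >= 2 tumor samples with survival data per group")
    t = meta["survival_time"].to_numpy(float)
    e = meta["event"].to_numpy(int)
    res = logrank_test(t[low], t[~low], event_observed_A=e[low],
                       event_observed_B=e[~low])
    curves = {
        "low": _km_curve(t[low], e[low]),
        "high": _km_curve(t[~low], e[~low]),
    }
    return SurvivalResult(feature_id=feature_id,
                          statistic=float(res.test_statistic),
                          p_value=float(res.p_value),
                          n_high=int((~low).sum()), n_low=int(low.sum()),
                          curves=curves)


def stage_association(expression, stage) -> tuple[float, float]:
    """Kruskal-Wallis test of expression across ordinal tumor stages.

    Stages with fewer than 2 samples are dropped with a warning; at least
    two populated stages must remain.
    """
    expr = np.asarray(expression, dtype=float)
    stage = np.asarray(stage)
    groups = []
    for s in pd.unique(stage):
        if pd.isna(s):
            continue
        vals = expr[stage == s]
        if vals.size < 2:
            warnings.warn(f"stage {s!r} has fewer than 2 samples; dropped",
                          stacklevel=2)
            continue
        groups.append(vals)
    if len(groups) < 2:
        raise InputError("need at least 2 stages with >= 2 samples each")
    if np.ptp(np.concatenate(groups)) == 0:
        return 0.0, 1.0
    stat, p = stats.kruskal(*groups)
    return float(stat), float(p)


def msi_association(expression, msi) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of MSS vs MSI-H expression."""
    expr = np.asarray(expression, dtype=float)
    msi = np.asarray(msi)
    mask = ~pd.isna(msi)
    expr, msi = expr[mask], msi[mask]
    labels = set(np.unique(msi))
    if labels != {"MSS", "MSI-H"}:
        raise InputError(f"need both MSS and MSI-H phenotypes, got {sorted(labels)}")
    a = expr[msi == "MSS"]
    b = expr[msi == "MSI-H"]
    if np.ptp(expr) == 0:
        return 0.5 * a.size * b.size, 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def validate_features(matrix, metadata: pd.DataFrame, feature_ids,
                      roc_seed: int = 0, n_boot: int = 2000) -> pd.DataFrame:
    """Run all applicable validations per feature; returns a tidy table."""
    rows = []
    labels = (metadata["group"] == "tumor").astype(int)
    has_surv = {"survival_time", "event"} <= set(metadata.columns)
    has_stage = "stage" in metadata.columns
    has_msi = "msi" in metadata.columns
    tumors = metadata.index[metadata["group"] == "tumor"]
    for fid in feature_ids:
        if fid not in matrix.features:
            warnings.warn(f"feature {fid!r} absent from the matrix; skipped",
                          stacklevel=2)
            continue
        expr = matrix.data.loc[fid, metadata.index]
        roc = roc_auc(expr.to_numpy(float), labels.to_numpy(), feature_id=fid,
                      n_boot=n_boot, seed=roc_seed)
        row = {"feature_id": fid, "auc": roc.auc, "auc_ci_low": roc.ci_low,
               "auc_ci_high": roc.ci_high}
        if has_surv and metadata.loc[tumors, "survival_time"].notna().any():
            try:
                surv = km_logrank_median_split(expr, metadata, feature_id=fid)
                row["logrank_statistic"] = surv.statistic
                row["logrank_p"] = surv.p_value
            except InputError:
                row["logrank_statistic"] = np.nan
                row["logrank_p"] = np.nan
        if has_stage:
            try:
                stat, p = stage_association(expr.loc[tumors],
                                            metadata.loc[tumors, "stage"])
                row["stage_statistic"], row["stage_p"] = stat, p
            except InputError:
                row["stage_statistic"] = row["stage_p"] = np.nan
        if has_msi:
            try:
                stat, p = msi_association(expr.loc[tumors],
                                          metadata.loc[tumors, "msi"])
                row["msi_statistic"], row["msi_p"] = stat, p
            except InputError:
                row["msi_statistic"] = row["msi_p"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
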