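"""Dual-method differential expression with union merging.

Two assumption-distinct per-feature tests are run on the same normalized
matrix — a parametric Welch t-test and a nonparametric Wilcoxon rank-sum
test — and their call sets are directly merged by union.  A feature is
called when |log2FC| > 1 and Benjamini-Hochberg FDR < 0.05 (both strict),
with log2FC defined as mean(tumor) - mean(normal) on the log2 scale.

Counts are normalized to counts-per-million and log2(CPM + 1) transformed
after a low-expression filter; intensity matrices are log2-transformed
directly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, align_samples
from .errors import InputError

DE_COLUMNS = ("feature_id", "log2fc", "p_value", "fdr", "called", "method")

DEFAULT_LOG2FC_CUTOFF = 1.0
DEFAULT_FDR_CUTOFF = 0.05


def cpm(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Counts-per-million: each column rescaled to sum to 10^6."""
    if matrix.modality != "counts":
        raise InputError(f"CPM is defined for counts, got modality {matrix.modality!r}")
    counts = matrix.data
    if (counts.to_numpy() < 0).any():
        raise InputError("counts must be non-negative")
    colsum = counts.sum(axis=0)
    zero = colsum[colsum == 0]
    if len(zero):
        raise InputError(f"all-zero sample column(s): {list(zero.index)[:5]}")
    return counts / colsum * 1e6


def normalize_cpm(matrix: ExpressionMatrix, low_expr_min_cpm: float = 1.0,
                  low_expr_min_samples: int | None = None) -> ExpressionMatrix:
    """log2(CPM + 1) after dropping lowly expressed features.

    Features with CPM >= ``low_expr_min_cpm`` in fewer than
    ``low_expr_min_samples`` samples (default: 25% of samples) are dropped.
    CPM is computed on the unfiltered matrix, so per-sample CPM totals are
    exactly 10^6 before the log transform.
    """
    c = cpm(matrix)
    if low_expr_min_samples is None:
        low_expr_min_samples = int(np.ceil(0.25 * c.shape[1]))
    keep = (c >= low_expr_min_cpm).sum(axis=1) >= low_expr_min_samples
    return ExpressionMatrix(np.log2(c.loc[keep] + 1.0), modality="log2")


def prepare_expression(matrix: ExpressionMatrix, **cpm_kwargs) -> ExpressionMatrix:
    """Bring any modality onto the log2 scale used by testing and selection."""
    if matrix.modality == "counts":
        return normalize_cpm(matrix, **cpm_kwargs)
    if matrix.modality == "intensity":
        values = matrix.data
        if (values.to_numpy() <= 0).any():
            raise InputError("intensities must be strictly positive for log2 transform")
        return ExpressionMatrix(np.log2(values), modality="log2")
    return matrix


def _group_arrays(norm: ExpressionMatrix, metadata: pd.DataFrame):
    meta = align_samples(norm, metadata)
    tumor = norm.data.loc[:, (meta["group"] == "tumor").to_numpy()].to_numpy(float)
    normal = norm.data.loc[:, (meta["group"] == "normal").to_numpy()].to_numpy(float)
    if tumor.shape[1] < 2 or normal.shape[1] < 2:
        raise InputError("each group needs at least 2 samples for testing")
    return tumor, normal


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise InputError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise InputError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def _assemble(features, log2fc, p, method, log2fc_cutoff, fdr_cutoff) -> pd.DataFrame:
    fdr = bh_adjust(p)
    called = (np.abs(log2fc) > log2fc_cutoff) & (fdr < fdr_cutoff)
    return pd.DataFrame({
        "feature_id": features, "log2fc": log2fc, "p_value": p,
        "fdr": fdr, "called": called, "method": method,
    })


def de_test_parametric(norm: ExpressionMatrix, metadata: pd.DataFrame,
                       log2fc_cutoff: float = DEFAULT_LOG2FC_CUTOFF,
                       fdr_cutoff: float = DEFAULT_FDR_CUTOFF) -> pd.DataFrame:
    """Per-feature Welch two-sample t-test on the log2 matrix."""
    tumor, normal = _group_arrays(norm, metadata)
    log2fc = tumor.mean(axis=1) - normal.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(tumor, normal, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    # Zero variance in both groups: p undefined; identical means -> null.
    degenerate = np.isnan(p)
    p[degenerate & (log2fc == 0)] = 1.0
    p[degenerate & (log2fc != 0)] = 0.0
    return _assemble(norm.features, log2fc, p, "parametric", log2fc_cutoff, fdr_cutoff)


def _rank_p(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method="auto").pvalue)


def de_test_rank(norm: ExpressionMatrix, metadata: pd.DataFrame,
                 log2fc_cutoff: float = DEFAULT_LOG2FC_CUTOFF,
                 fdr_cutoff: float = DEFAULT_FDR_CUTOFF) -> pd.DataFrame:
    """Per-feature two-sided Wilcoxon rank-sum test.

    Exact p-values for small tie-free samples, tie-corrected normal
    approximation otherwise (scipy's "auto" policy).
    """
    tumor, normal = _group_arrays(norm, metadata)
    log2fc = tumor.mean(axis=1) - normal.mean(axis=1)
    p = np.array([_rank_p(tumor[i], normal[i]) for i in range(tumor.shape[0])])
    return _assemble(norm.features, log2fc, p, "rank", log2fc_cutoff, fdr_cutoff)


def called_set(result: pd.DataFrame) -> set[str]:
    return set(result.loc[result["called"], "feature_id"])


def merge_de(a: pd.DataFrame, b: pd.DataFrame) -> set[str]:
    """Directly merge two DE call sets: the union of called feature IDs."""
    return called_set(a) | called_set(b)


def run_dea(matrix: ExpressionMatrix, metadata: pd.DataFrame,
            log2fc_cutoff: float = DEFAULT_LOG2FC_CUTOFF,
            fdr_cutoff: float = DEFAULT_FDR_CUTOFF,
            **cpm_kwargs) -> dict:
    """Normalize, run both tests, and union-merge the calls."""
    norm = prepare_expression(matrix, **cpm_kwargs)
    parametric = de_test_parametric(norm, metadata, log2fc_cutoff, fdr_cutoff)
    rank = de_test_rank(norm, metadata, log2fc_cutoff, fdr_cutoff)
    return {
        "normalized": norm,
        "parametric": parametric,
        "rank": rank,
        "merged": merge_de(parametric, rank),
    }
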