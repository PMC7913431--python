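"""Reproducible calibration and recovery experiments.

Each experiment builds its own synthetic inputs from a seed, runs the
package's machinery, and returns the measured quantities.  They are the
basis of the acceptance checks and of the numbers the reproduction script
reports; sizes are desk-scale by design (the methods note states them).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test

from .containers import ExpressionMatrix
from .dea import de_test_parametric, de_test_rank, prepare_expression
from .lasso import cross_validate_lambda
from .simulate import SimulationConfig, simulate_tissue_counts
from .stability import StabilityConfig, run_stability_selection


def make_planted_classification(n_features: int = 500, n_informative: int = 10,
                                m: int = 200, n: int = 20, effect: float = 2.0,
                                seed: int = 0):
    """Gaussian log-scale fixture: class-imbalanced cohort, planted panel.

    ``effect`` is the tumor-minus-control mean shift of the informative
    features in units of the within-group SD.
    """
    rng = np.random.default_rng(seed)
    shift = np.zeros(n_features)
    shift[:n_informative] = effect
    group = np.array([1.0] * m + [0.0] * n)
    X = rng.normal(size=(m + n, n_features)) + group[:, None] * shift[None, :]
    ids = [f"T{i:03d}" for i in range(m)] + [f"N{i:03d}" for i in range(n)]
    features = [f"f{j:03d}" for j in range(n_features)]
    matrix = ExpressionMatrix(pd.DataFrame(X.T, index=features, columns=ids),
                              "log2")
    meta = pd.DataFrame({"group": ["tumor"] * m + ["normal"] * n}, index=ids)
    meta.index.name = "sample_id"
    return matrix, meta, features[:n_informative]


def stability_recovery(B: int = 200, n_folds: int = 10, seed: int = 0,
                       **fixture_kwargs) -> dict:
    """Balanced-subsample selection on the planted fixture.

    Returns the planted features' selection frequencies, the worst planted
    frequency, and the fraction of null features below frequency 1/2.
    """
    matrix, meta, informative = make_planted_classification(
        seed=seed, **fixture_kwargs)
    cfg = StabilityConfig(B=B, n_folds=n_folds, seed=seed)
    result = run_stability_selection(matrix, meta, cfg)
    table = result.table.set_index("feature_id")
    planted = table.loc[informative, "frequency"]
    nulls = table.drop(index=informative)["frequency"]
    return {
        "planted_frequencies": planted,
        "min_planted_frequency": float(planted.min()),
        "frac_nulls_below_half": float((nulls < 0.5).mean()),
        "n_key": int(table["is_key"].sum()),
        "result": result,
    }


def null_cv_deviance(n: int = 60, p: int = 20, seed: int = 0) -> float:
    """Cross-validated deviance of the intercept-only model on balanced noise.

    The closed form for a balanced binary null is 2*ln(2) per sample.
    """
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = np.tile([1.0, 0.0], n // 2)
    cv = cross_validate_lambda(X, y, n_folds=10, seed=seed)
    return float(cv.mean_deviance[0])  # largest lambda = null model


def de_calibration(n_rep: int = 20, n_features: int = 300,
                   n_per_group: int = 25, seed: int = 0) -> dict:
    """Null calibration and planted sensitivity of both DE tests.

    Null replicates have no planted effects; planted replicates carry
    log2FC = 2 at baseline mean 50.
    """
    seeds = np.random.SeedSequence(seed).generate_state(2 * n_rep) % (2 ** 31)
    null_rates = {"parametric": [], "rank": []}
    sens, fdp = [], []
    for r in range(n_rep):
        null_cfg = SimulationConfig(
            n_features_mrna=n_features, n_tumor=n_per_group,
            n_control=n_per_group, n_planted_de=0, n_planted_key=0,
            baseline_mean=50.0, seed=int(seeds[2 * r]))
        matrix, _, meta = simulate_tissue_counts(null_cfg)
        norm = prepare_expression(matrix)
        for name, test in (("parametric", de_test_parametric),
                           ("rank", de_test_rank)):
            res = test(norm, meta)
            null_rates[name].append(res["called"].mean())

        alt_cfg = SimulationConfig(
            n_features_mrna=n_features, n_tumor=n_per_group,
            n_control=n_per_group, n_planted_de=30, n_planted_key=0,
            planted_log2fc=2.0, baseline_mean=50.0, seed=int(seeds[2 * r + 1]))
        matrix, truth, meta = simulate_tissue_counts(alt_cfg)
        norm = prepare_expression(matrix)
        res_p = de_test_parametric(norm, meta)
        res_r = de_test_rank(norm, meta)
        called = (set(res_p.loc[res_p["called"], "feature_id"])
                  | set(res_r.loc[res_r["called"], "feature_id"]))
        planted = truth.planted_de["mrna"]
        sens.append(len(called & planted) / len(planted))
        fdp.append(len(called - planted) / max(len(called), 1))
    return {
        "null_call_rate_parametric": float(np.mean(null_rates["parametric"])),
        "null_call_rate_rank": float(np.mean(null_rates["rank"])),
        "sensitivity": float(np.mean(sens)),
        "false_discovery_proportion": float(np.mean(fdp)),
        "n_replicates": n_rep,
    }


def logrank_power(n_rep: int = 20, n_tumors: int = 200, hazard_ratio: float = 3.0,
                  baseline_hazard: float = 0.03, seed: int = 0) -> dict:
    """Rejection rate of the median-split log-rank under a planted hazard link.

    Survival is exponential with the hazard multiplied by ``hazard_ratio``
    for samples above the median of the linked score; no censoring, so
    every sample contributes an event.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_rep):
        score = rng.normal(size=n_tumors)
        high = score > np.median(score)
        rate = baseline_hazard * np.where(high, hazard_ratio, 1.0)
        t = rng.exponential(1.0 / rate)
        res = logrank_test(t[~high], t[high],
                           event_observed_A=np.ones((~high).sum()),
                           event_observed_B=np.ones(high.sum()))
        rejections += res.p_value < 0.05
    return {"power": rejections / n_rep, "n_replicates": n_rep,
            "n_events": n_tumors}
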