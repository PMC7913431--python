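"""Seeded synthetic study generator with planted ground truth.

Emulates the data regime of a serum-exosome biomarker study in colorectal
cancer: bulk tissue RNA-seq counts (mRNA and miRNA) for a large tumor
cohort with few adjacent normals, serum exosomal miRNA microarray
intensities for a second, severely imbalanced cohort (default 88 cancer
sera vs 11 healthy controls), clinical covariates on the tumor samples,
and a multi-source miRNA->mRNA target-prediction table in which planted
regulatory edges are hidden among decoys.

Counts follow a negative-binomial model parameterized by mean and
dispersion (variance = mu + dispersion * mu^2) with per-sample log-normal
library-size factors; differential features are planted as a log2
fold-change on the group mean.  Exosomal intensities are log-normal with a
planted shift on the log2 scale.  Everything is a pure function of its
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
import json

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GroundTruth, validate_metadata, write_metadata
from .errors import ConfigurationError, InputError

CONFIDENCE_CLASSES = ("low", "medium", "high", "very high")

# Fraction of exosomal miRNA IDs deliberately emitted with a lowercase
# "hsa-mir-" prefix, mimicking the stem-loop-style names that microarray
# annotations carry; exercises downstream ID harmonization.
LOWERCASE_ID_FRACTION = 0.3


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated expression dataset.

    Defaults reproduce the exosomal cohort imbalance (88 tumor sera vs 11
    healthy controls); use :func:`tissue_default_config` for the tissue
    regime (600 tumors vs 50 normals, loosely echoing combined
    colon/rectal TCGA proportions).
    """

    n_features_mrna: int = 1000
    n_features_mirna: int = 300
    n_tumor: int = 88
    n_control: int = 11
    n_planted_de: int = 30
    planted_log2fc: float = 2.0
    nb_dispersion: float = 0.2
    baseline_mean: float = 100.0
    n_planted_key: int = 5
    exo_noise_sd: float = 1.0
    seed: int = 0
    # SD of the per-sample log library-size factor.
    size_factor_sd: float = 0.2
    # Planted key features carry planted_log2fc * key_effect_multiplier:
    # "key" ground truth is meaningful only if key features are objectively
    # more discriminative than ordinary planted DE features.
    key_effect_multiplier: float = 2.0

    def validate(self, modality: str = "mirna") -> None:
        n_features = self.n_features_mrna if modality == "mrna" else self.n_features_mirna
        if min(self.n_features_mrna, self.n_features_mirna, self.n_tumor, self.n_control) <= 0:
            raise ConfigurationError("feature and sample counts must be positive")
        if not 0 <= self.n_planted_key <= self.n_planted_de <= n_features:
            raise ConfigurationError(
                "need 0 <= n_planted_key <= n_planted_de <= n_features "
                f"({self.n_planted_key}, {self.n_planted_de}, {n_features})"
            )
        for name in ("nb_dispersion", "baseline_mean", "exo_noise_sd", "size_factor_sd"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")


def tissue_default_config(**overrides) -> SimulationConfig:
    """Tissue-cohort defaults: 600 tumors vs 50 normals."""
    base = dict(n_tumor=600, n_control=50, n_planted_de=60, n_planted_key=8)
    base.update(overrides)
    return SimulationConfig(**base)


def _feature_ids(modality: str, n: int) -> list[str]:
    if modality == "mirna":
        return [f"hsa-miR-{k}" for k in range(1, n + 1)]
    return [f"GENE{k:04d}" for k in range(1, n + 1)]


def _sample_ids(prefix: str, n_tumor: int, n_control: int) -> tuple[list[str], list[str]]:
    tumors = [f"{prefix}T{j:03d}" for j in range(1, n_tumor + 1)]
    normals = [f"{prefix}N{j:03d}" for j in range(1, n_control + 1)]
    return tumors, normals


def _plant(rng: np.random.Generator, features: list[str], config: SimulationConfig,
           planted_de=None, planted_key=None) -> tuple[list[str], list[str]]:
    if planted_de is None:
        planted_de = list(rng.choice(features, size=config.n_planted_de, replace=False))
    else:
        planted_de = list(planted_de)
    if planted_key is None:
        planted_key = list(rng.choice(planted_de, size=min(config.n_planted_key, len(planted_de)),
                                      replace=False)) if planted_de else []
    else:
        planted_key = list(planted_key)
    if not set(planted_key) <= set(planted_de):
        raise ConfigurationError("planted key features must be planted DE features")
    return planted_de, planted_key


def _true_lfc(features: list[str], planted_de: list[str], planted_key: list[str],
              config: SimulationConfig) -> np.ndarray:
    lfc = np.zeros(len(features))
    de_set, key_set = set(planted_de), set(planted_key)
    for idx, f in enumerate(features):
        if f in key_set:
            lfc[idx] = config.planted_log2fc * config.key_effect_multiplier
        elif f in de_set:
            lfc[idx] = config.planted_log2fc
    return lfc


def _group_metadata(tumors: list[str], normals: list[str]) -> pd.DataFrame:
    meta = pd.DataFrame(
        {"group": ["tumor"] * len(tumors) + ["normal"] * len(normals)},
        index=tumors + normals,
    )
    meta.index.name = "sample_id"
    return validate_metadata(meta)


def simulate_tissue_counts(config: SimulationConfig, modality: str = "mrna",
                           sample_prefix: str = "", planted_de=None, planted_key=None,
                           ) -> tuple[ExpressionMatrix, GroundTruth, pd.DataFrame]:
    """Negative-binomial tissue counts with planted log2 fold-changes.

    Returns the count matrix (features x samples), the ground truth for
    this modality, and the sample metadata (group labels only).
    """
    config.validate(modality)
    rng = np.random.default_rng(config.seed)
    n_features = config.n_features_mrna if modality == "mrna" else config.n_features_mirna
    features = _feature_ids(modality, n_features)
    planted_de, planted_key = _plant(rng, features, config, planted_de, planted_key)

    tumors, normals = _sample_ids(sample_prefix, config.n_tumor, config.n_control)
    samples = tumors + normals
    n_samples = len(samples)

    # Per-feature baseline mean spread around baseline_mean on the log scale.
    base = config.baseline_mean * np.exp(rng.normal(0.0, 0.7, size=n_features))
    lfc = _true_lfc(features, planted_de, planted_key, config)

    size_factors = np.exp(rng.normal(0.0, config.size_factor_sd, size=n_samples))
    is_tumor = np.array([1.0] * len(tumors) + [0.0] * len(normals))

    mu = base[:, None] * (2.0 ** (lfc[:, None] * is_tumor[None, :])) * size_factors[None, :]
    shape = 1.0 / config.nb_dispersion
    lam = rng.gamma(shape, mu * config.nb_dispersion)
    counts = rng.poisson(lam)

    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=features, columns=samples), modality="counts"
    )
    truth = GroundTruth(
        features={modality: features},
        planted_de={modality: set(planted_de)},
        planted_key={modality: set(planted_key)},
        true_log2fc={modality: dict(zip(features, lfc.tolist()))},
    )
    return matrix, truth, _group_metadata(tumors, normals)


def simulate_exosomal_intensities(config: SimulationConfig, sample_prefix: str = "Exo",
                                  planted_de=None, planted_key=None,
                                  ) -> tuple[ExpressionMatrix, GroundTruth, pd.DataFrame]:
    """Log-normal serum exosomal miRNA intensities with planted log2 shifts.

    miRNA IDs are drawn from the same namespace as the tissue miRNA matrix
    so the tissue/exosomal DE intersection is non-empty by construction; a
    deliberate subset of IDs is emitted with a lowercase "hsa-mir-" prefix
    to exercise identifier harmonization downstream.
    """
    config.validate("mirna")
    rng = np.random.default_rng(config.seed + 1)
    features = _feature_ids("mirna", config.n_features_mirna)
    planted_de, planted_key = _plant(rng, features, config, planted_de, planted_key)

    tumors, normals = _sample_ids(sample_prefix, config.n_tumor, config.n_control)
    samples = tumors + normals
    is_tumor = np.array([1.0] * len(tumors) + [0.0] * len(normals))

    base_log2 = rng.normal(8.0, 2.0, size=config.n_features_mirna)
    lfc = _true_lfc(features, planted_de, planted_key, config)

    log2_int = (base_log2[:, None] + lfc[:, None] * is_tumor[None, :]
                + rng.normal(0.0, config.exo_noise_sd,
                             size=(config.n_features_mirna, len(samples))))
    intensities = 2.0 ** log2_int

    # Deterministic lowercase-ID subset, seeded from the same stream.
    lower_mask = rng.random(config.n_features_mirna) < LOWERCASE_ID_FRACTION
    emitted = [f.replace("hsa-miR-", "hsa-mir-") if low else f
               for f, low in zip(features, lower_mask)]

    matrix = ExpressionMatrix(
        pd.DataFrame(intensities, index=emitted, columns=samples), modality="intensity"
    )
    truth = GroundTruth(
        features={"mirna": features},
        planted_de={"mirna": set(planted_de)},
        planted_key={"mirna": set(planted_key)},
        true_log2fc={"mirna": dict(zip(features, lfc.tolist()))},
    )
    return matrix, truth, _group_metadata(tumors, normals)


def simulate_target_table(truth: GroundTruth, n_sources: int = 3, decoy_rate: float = 0.002,
                          seed: int = 0) -> pd.DataFrame:
    """Multi-source target-prediction table hiding planted edges among decoys.

    Every planted (miRNA, mRNA) edge appears in at least one source with
    confidence class "high".  Each non-planted pair from the generated
    namespaces is additionally included per source with probability
    ``decoy_rate``, carrying a confidence class drawn uniformly from
    {high, medium, low}.
    """
    if not 0.0 <= decoy_rate <= 1.0:
        raise ConfigurationError(f"decoy_rate must lie in [0, 1], got {decoy_rate}")
    if n_sources <= 0:
        raise ConfigurationError("n_sources must be positive")
    mirnas = list(truth.features.get("mirna", []))
    mrnas = list(truth.features.get("mrna", []))
    planted = sorted(truth.planted_edges)
    if not mirnas or not mrnas:
        raise InputError("ground truth must carry both miRNA and mRNA namespaces")
    for mi, mr in planted:
        if mi not in set(mirnas) or mr not in set(mrnas):
            raise InputError(f"planted edge ({mi}, {mr}) references unknown feature IDs")

    rng = np.random.default_rng(seed)
    rows: list[tuple[str, str, str, str]] = []
    sources = [f"source_{s + 1}" for s in range(n_sources)]

    for mi, mr in planted:
        n_hit = 1 + rng.binomial(n_sources - 1, 0.5)
        for src in rng.choice(sources, size=n_hit, replace=False):
            rows.append((src, mi, mr, "high"))

    planted_set = set(truth.planted_edges)
    n_pairs = len(mirnas) * len(mrnas)
    decoy_classes = ("high", "medium", "low")
    for src in sources:
        n_decoys = rng.binomial(n_pairs, decoy_rate)
        if n_decoys == 0:
            continue
        idx = rng.choice(n_pairs, size=n_decoys, replace=False)
        for flat in idx:
            mi = mirnas[flat // len(mrnas)]
            mr = mrnas[flat % len(mrnas)]
            if (mi, mr) in planted_set:
                continue
            rows.append((src, mi, mr, decoy_classes[rng.integers(3)]))

    table = pd.DataFrame(rows, columns=["source", "mirna", "mrna", "confidence"])
    return table.sort_values(["source", "mirna", "mrna"], ignore_index=True)


@dataclass(frozen=True)
class ClinicalConfig:
    """Clinical-covariate generator settings (tumor samples only).

    Survival is exponential with hazard ``baseline_hazard *
    exp(hazard_log_hr * (tertile - 1))`` of the linked feature's
    expression tertile, administratively censored at ``censor_time``
    months.  MSI status is Bernoulli on a logit scale with an optional
    expression-linked shift.
    """

    hazard_feature: str | None = None
    hazard_log_hr: float = 0.0
    baseline_hazard: float = 0.02   # events per month
    censor_time: float = 60.0       # months
    msi_feature: str | None = None
    msi_log_odds: float = 0.0
    msi_base_rate: float = 0.15
    stage_probs: tuple = (0.20, 0.35, 0.30, 0.15)
    seed: int = 0


def _tertile(values: np.ndarray) -> np.ndarray:
    q1, q2 = np.quantile(values, [1 / 3, 2 / 3])
    return np.where(values <= q1, 0, np.where(values <= q2, 1, 2)).astype(float)


def simulate_clinical(matrix: ExpressionMatrix, metadata: pd.DataFrame,
                      config: ClinicalConfig) -> pd.DataFrame:
    """Attach survival, stage and MSI covariates to the tumor samples."""
    missing = [s for s in metadata.index if s not in matrix.samples]
    if missing:
        raise InputError(f"metadata samples absent from the expression matrix: {missing[:5]}")
    rng = np.random.default_rng(config.seed)
    meta = metadata.copy()
    tumors = meta.index[meta["group"] == "tumor"]
    n = len(tumors)

    def linked_tertiles(feature: str | None) -> np.ndarray:
        if feature is None:
            return np.ones(n)
        if feature not in matrix.features:
            raise InputError(f"linked feature {feature!r} not in the expression matrix")
        return _tertile(matrix.data.loc[feature, tumors].to_numpy(float))

    z_surv = linked_tertiles(config.hazard_feature)
    hazard = config.baseline_hazard * np.exp(config.hazard_log_hr * (z_surv - 1.0))
    t_event = rng.exponential(1.0 / hazard)
    event = (t_event <= config.censor_time).astype(int)
    time = np.minimum(t_event, config.censor_time)

    stages = rng.choice(["I", "II", "III", "IV"], size=n, p=config.stage_probs)

    z_msi = linked_tertiles(config.msi_feature)
    logit = np.log(config.msi_base_rate / (1 - config.msi_base_rate)) \
        + config.msi_log_odds * (z_msi - 1.0)
    p_msi = 1.0 / (1.0 + np.exp(-logit))
    msi = np.where(rng.random(n) < p_msi, "MSI-H", "MSS")

    for col in ("survival_time", "event", "stage", "msi"):
        meta[col] = np.nan
    meta["stage"] = meta["stage"].astype(object)
    meta["msi"] = meta["msi"].astype(object)
    meta.loc[tumors, "survival_time"] = np.round(time, 4)
    meta.loc[tumors, "event"] = event
    meta.loc[tumors, "stage"] = stages
    meta.loc[tumors, "msi"] = msi
    return validate_metadata(meta)


@dataclass
class StudyData:
    """The full simulated study: three matrices, metadata, targets, truth."""

    tissue_mrna: ExpressionMatrix
    tissue_mirna: ExpressionMatrix
    exosomal_mirna: ExpressionMatrix
    tissue_metadata: pd.DataFrame
    exosomal_metadata: pd.DataFrame
    target_table: pd.DataFrame
    truth: GroundTruth


def simulate_study(tissue_config: SimulationConfig | None = None,
                   exosomal_config: SimulationConfig | None = None,
                   mirna_config: SimulationConfig | None = None,
                   clinical_config: ClinicalConfig | None = None,
                   n_sources: int = 3, decoy_rate: float = 0.002,
                   seed: int = 0) -> StudyData:
    """Generate a coherent study: shared miRNA truth, linked clinical data.

    The planted DE/key miRNA sets are drawn once and planted in both the
    tissue miRNA counts and the exosomal intensities, so the candidate
    intersection recovers them.  Planted edges connect every planted key
    miRNA and key mRNA (each key mRNA targeted by >= 1 key miRNA).
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) for s in ss.generate_state(6) % (2 ** 31)]

    tissue_config = tissue_config or tissue_default_config(seed=seeds[0])
    mirna_config = mirna_config or replace(
        tissue_config, n_planted_de=30, n_planted_key=5, seed=seeds[1])
    exosomal_config = exosomal_config or SimulationConfig(
        n_features_mirna=mirna_config.n_features_mirna,
        n_planted_de=mirna_config.n_planted_de,
        n_planted_key=mirna_config.n_planted_key,
        planted_log2fc=mirna_config.planted_log2fc,
        seed=seeds[2])

    plan_rng = np.random.default_rng(seeds[3])
    mirna_ids = _feature_ids("mirna", mirna_config.n_features_mirna)
    de_mirnas = list(plan_rng.choice(mirna_ids, size=mirna_config.n_planted_de, replace=False))
    key_mirnas = list(plan_rng.choice(de_mirnas, size=mirna_config.n_planted_key, replace=False))

    tissue_mrna, truth_mrna, tissue_meta = simulate_tissue_counts(
        tissue_config, modality="mrna", sample_prefix="Tis")
    tissue_mirna, truth_mirna_t, _ = simulate_tissue_counts(
        mirna_config, modality="mirna", sample_prefix="Tis",
        planted_de=de_mirnas, planted_key=key_mirnas)
    exo_mirna, truth_mirna_e, exo_meta = simulate_exosomal_intensities(
        exosomal_config, planted_de=de_mirnas, planted_key=key_mirnas)

    truth = truth_mrna.merge(truth_mirna_t)

    # Planted regulatory edges: every key mRNA is targeted by >=1 key miRNA,
    # and every key miRNA targets >=1 key mRNA.
    key_mrnas = sorted(truth.planted_key.get("mrna", set()))
    edges: set[tuple[str, str]] = set()
    if key_mrnas and key_mirnas:
        for i, mr in enumerate(key_mrnas):
            edges.add((key_mirnas[i % len(key_mirnas)], mr))
        for j, mi in enumerate(key_mirnas):
            edges.add((mi, key_mrnas[j % len(key_mrnas)]))
        extra = plan_rng.integers(0, 2, size=(len(key_mirnas), len(key_mrnas)))
        for i, mi in enumerate(key_mirnas):
            for j, mr in enumerate(key_mrnas):
                if extra[i, j]:
                    edges.add((mi, mr))
    truth.planted_edges = edges

    targets = simulate_target_table(truth, n_sources=n_sources,
                                    decoy_rate=decoy_rate, seed=seeds[4])

    if clinical_config is None:
        linked = key_mrnas[0] if key_mrnas else None
        clinical_config = ClinicalConfig(
            hazard_feature=linked, hazard_log_hr=np.log(2.0),
            msi_feature=linked, msi_log_odds=1.0, seed=seeds[5])
    tissue_meta = simulate_clinical(tissue_mrna, tissue_meta, clinical_config)

    return StudyData(tissue_mrna, tissue_mirna, exo_mirna,
                     tissue_meta, exo_meta, targets, truth)


def write_study(study: StudyData, outdir: str | Path) -> dict[str, str]:
    """Write all study tables as TSV/JSON; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tissue_mrna": outdir / "tissue_mrna_counts.tsv",
        "tissue_mirna": outdir / "tissue_mirna_counts.tsv",
        "exosomal_mirna": outdir / "exosomal_mirna_intensity.tsv",
        "tissue_metadata": outdir / "tissue_metadata.tsv",
        "exosomal_metadata": outdir / "exosomal_metadata.tsv",
        "target_table": outdir / "target_predictions.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    study.tissue_mrna.to_tsv(paths["tissue_mrna"])
    study.tissue_mirna.to_tsv(paths["tissue_mirna"])
    study.exosomal_mirna.to_tsv(paths["exosomal_mirna"])
    write_metadata(study.tissue_metadata, paths["tissue_metadata"])
    write_metadata(study.exosomal_metadata, paths["exosomal_metadata"])
    study.target_table.to_csv(paths["target_table"], sep="\t", index=False)
    with open(paths["ground_truth"], "w") as fh:
        json.dump(study.truth.to_json_dict(), fh, indent=1)
    return {k: str(v) for k, v in paths.items()}
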