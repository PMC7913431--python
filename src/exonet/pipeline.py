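"""End-to-end orchestration: simulate -> dea -> candidates -> select -> network -> validate.

Each stage reads its inputs from, and writes its outputs to, a run
directory, so any stage can be re-run standalone on the previous stage's
files.  Stage seeds are derived from the master seed with a fixed counter
scheme; an identical config and seed reproduces every output byte for
byte.  A machine-readable run report (JSON) echoes parameters and
per-stage row counts.
"""

from __future__ import annotations

import copy
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dea, screen, simulate, stability, network, validate as validation
from .containers import ExpressionMatrix, read_metadata
from .errors import ConfigurationError, ExonetError
from .simulate import ClinicalConfig, SimulationConfig, GroundTruth

logger = logging.getLogger(__name__)

STAGE_ORDER = ("simulate", "dea", "candidates", "select", "network", "validate")

DEFAULT_CONFIG: dict = {
    "outdir": "exonet_run",
    "seed": 0,
    "stages": list(STAGE_ORDER),
    "simulate": {
        "tissue": {"n_features_mrna": 1000, "n_features_mirna": 300,
                   "n_tumor": 600, "n_control": 50,
                   "n_planted_de": 60, "n_planted_key": 8,
                   "planted_log2fc": 2.0, "baseline_mean": 100.0,
                   "nb_dispersion": 0.2},
        "mirna": {"n_planted_de": 30, "n_planted_key": 5},
        "exosomal": {"n_tumor": 88, "n_control": 11, "exo_noise_sd": 1.0},
        "n_sources": 3,
        "decoy_rate": 0.002,
        "clinical": {"hazard_log_hr": 0.6931471805599453, "msi_log_odds": 1.0},
    },
    "dea": {"log2fc_cutoff": 1.0, "fdr_cutoff": 0.05, "low_expr_min_cpm": 1.0},
    "candidates": {"strip_arm": False},
    "select": {"B_mirna": 200, "B_mrna": 200, "n_folds": 10,
               "count_threshold": None, "n_lambda": 100,
               "lambda_min_ratio": 0.001},
    "network": {"min_class": "high", "mrna_hub_cutoff": 3},
    "validate": {"n_boot": 500},
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


class RunConfig:
    """Validated pipeline configuration (YAML-backed)."""

    def __init__(self, data: dict | None = None):
        self.data = _deep_merge(DEFAULT_CONFIG, data or {})
        unknown = [s for s in self.data["stages"] if s not in STAGE_ORDER]
        if unknown:
            raise ConfigurationError(f"unknown stage(s) {unknown}")
        if not isinstance(self.data["seed"], int):
            raise ConfigurationError("a master seed (integer) is required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    @property
    def outdir(self) -> Path:
        return Path(self.data["outdir"])

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    @property
    def stages(self) -> list[str]:
        return [s for s in STAGE_ORDER if s in self.data["stages"]]

    def stage_seed(self, stage: str) -> int:
        offset = STAGE_ORDER.index(stage)
        state = np.random.SeedSequence([self.seed, offset]).generate_state(1)
        return int(state[0] % (2 ** 31))

    def __getitem__(self, key: str):
        return self.data[key]


# ---------------------------------------------------------------- stages

def stage_simulate(config: RunConfig) -> dict:
    params = config["simulate"]
    seed = config.stage_seed("simulate")
    ss = np.random.SeedSequence([seed, 1]).generate_state(3) % (2 ** 31)
    tissue = SimulationConfig(**params["tissue"], seed=int(ss[0]))
    mirna_over = dict(params["tissue"])
    mirna_over.update(params["mirna"])
    mirna = SimulationConfig(**mirna_over, seed=int(ss[1]))
    exo_over = {"n_features_mirna": mirna.n_features_mirna,
                "n_planted_de": mirna.n_planted_de,
                "n_planted_key": mirna.n_planted_key,
                "planted_log2fc": mirna.planted_log2fc}
    exo_over.update(params["exosomal"])
    exosomal = SimulationConfig(**exo_over, seed=int(ss[2]))

    study = simulate.simulate_study(
        tissue_config=tissue, mirna_config=mirna, exosomal_config=exosomal,
        n_sources=params["n_sources"], decoy_rate=params["decoy_rate"],
        seed=seed)
    # Clinical link parameters come from the config; re-simulate with them.
    clin = params.get("clinical") or {}
    key_mrnas = sorted(study.truth.planted_key.get("mrna", set()))
    linked = key_mrnas[0] if key_mrnas else None
    clin_cfg = ClinicalConfig(
        hazard_feature=linked, hazard_log_hr=clin.get("hazard_log_hr", 0.0),
        msi_feature=linked, msi_log_odds=clin.get("msi_log_odds", 0.0),
        seed=int(np.random.SeedSequence([seed, 2]).generate_state(1)[0] % (2 ** 31)))
    base_meta = study.tissue_metadata[["group"]]
    study.tissue_metadata = simulate.simulate_clinical(study.tissue_mrna,
                                                       base_meta, clin_cfg)
    paths = simulate.write_study(study, config.outdir)
    return {"paths": paths,
            "n_tissue_samples": study.tissue_mrna.shape[1],
            "n_exosomal_samples": study.exosomal_mirna.shape[1],
            "n_target_rows": len(study.target_table),
            "n_planted_edges": len(study.truth.planted_edges)}


def _read_matrices(outdir: Path):
    return {
        "tissue_mrna": ExpressionMatrix.from_tsv(outdir / "tissue_mrna_counts.tsv", "counts"),
        "tissue_mirna": ExpressionMatrix.from_tsv(outdir / "tissue_mirna_counts.tsv", "counts"),
        "exosomal_mirna": ExpressionMatrix.from_tsv(
            outdir / "exosomal_mirna_intensity.tsv", "intensity"),
    }


def stage_dea(config: RunConfig) -> dict:
    outdir = config.outdir
    params = config["dea"]
    matrices = _read_matrices(outdir)
    meta = {"tissue_mrna": read_metadata(outdir / "tissue_metadata.tsv"),
            "tissue_mirna": read_metadata(outdir / "tissue_metadata.tsv"),
            "exosomal_mirna": read_metadata(outdir / "exosomal_metadata.tsv")}
    merged: dict[str, list[str]] = {}
    counts = {}
    for name, matrix in matrices.items():
        kwargs = {"low_expr_min_cpm": params["low_expr_min_cpm"]} \
            if matrix.modality == "counts" else {}
        result = dea.run_dea(matrix, meta[name],
                             log2fc_cutoff=params["log2fc_cutoff"],
                             fdr_cutoff=params["fdr_cutoff"], **kwargs)
        for method in ("parametric", "rank"):
            result[method].to_csv(outdir / f"de_{name}_{method}.tsv",
                                  sep="\t", index=False)
        result["normalized"].to_tsv(outdir / f"norm_{name}.tsv")
        merged[name] = sorted(result["merged"])
        counts[name] = {
            "n_features_tested": result["parametric"].shape[0],
            "n_called_parametric": int(result["parametric"]["called"].sum()),
            "n_called_rank": int(result["rank"]["called"].sum()),
            "n_merged": len(result["merged"]),
        }
    with open(outdir / "de_merged.json", "w") as fh:
        json.dump(merged, fh, indent=1)
    return counts


def stage_candidates(config: RunConfig) -> dict:
    outdir = config.outdir
    strip_arm = config["candidates"]["strip_arm"]
    with open(outdir / "de_merged.json") as fh:
        merged = json.load(fh)
    targets = pd.read_csv(outdir / "target_predictions.tsv", sep="\t")
    cands = screen.screen_candidates(
        set(merged["tissue_mirna"]), set(merged["exosomal_mirna"]),
        [targets], set(merged["tissue_mrna"]), strip_arm=strip_arm)
    screen.candidates_to_frame(cands).to_csv(outdir / "candidates.tsv",
                                             sep="\t", index=False)
    return {"n_candidate_mirnas": len(cands.candidate_mirnas),
            "n_candidate_mrnas": len(cands.candidate_mrnas)}


def _normalized_index(matrix: ExpressionMatrix, strip_arm: bool) -> ExpressionMatrix:
    renamed = matrix.data.rename(
        index=lambda i: screen.normalize_mirna_id(i, strip_arm))
    return ExpressionMatrix(renamed, matrix.modality)


def stage_select(config: RunConfig) -> dict:
    outdir = config.outdir
    params = config["select"]
    strip_arm = config["candidates"]["strip_arm"]
    cands = pd.read_csv(outdir / "candidates.tsv", sep="\t")
    cand_mirnas = list(cands.loc[cands["kind"] == "mirna", "feature_id"])
    cand_mrnas = list(cands.loc[cands["kind"] == "mrna", "feature_id"])
    seed = config.stage_seed("select")

    runs = {}
    out_counts = {}
    for kind, cand, matrix_name, meta_name, b_key, sub_seed in (
            ("mirna", cand_mirnas, "norm_exosomal_mirna.tsv",
             "exosomal_metadata.tsv", "B_mirna", 1),
            ("mrna", cand_mrnas, "norm_tissue_mrna.tsv",
             "tissue_metadata.tsv", "B_mrna", 2)):
        matrix = ExpressionMatrix.from_tsv(outdir / matrix_name, "log2")
        if kind == "mirna":
            matrix = _normalized_index(matrix, strip_arm)
        matrix = matrix.subset_features(cand)
        meta = read_metadata(outdir / meta_name)
        cfg = stability.StabilityConfig(
            B=params[b_key], n_folds=params["n_folds"],
            count_threshold=params["count_threshold"],
            n_lambda=params["n_lambda"],
            lambda_min_ratio=params["lambda_min_ratio"],
            seed=int(np.random.SeedSequence([seed, sub_seed])
                     .generate_state(1)[0] % (2 ** 31)))
        result = stability.run_stability_selection(matrix, meta, cfg)
        result.table.to_csv(outdir / f"selection_{kind}.tsv", sep="\t", index=False)
        result.rounds.to_csv(outdir / f"selection_{kind}_rounds.tsv",
                             sep="\t", index=False)
        runs[kind] = result
        out_counts[f"n_candidate_{kind}s"] = len(cand)
        out_counts[f"n_key_{kind}s"] = len(result.key_features)
    return out_counts


def _key_sets(outdir: Path) -> tuple[set[str], set[str]]:
    key = {}
    for kind in ("mirna", "mrna"):
        table = pd.read_csv(outdir / f"selection_{kind}.tsv", sep="\t")
        key[kind] = set(table.loc[table["is_key"], "feature_id"])
    return key["mirna"], key["mrna"]


def stage_network(config: RunConfig) -> dict:
    outdir = config.outdir
    params = config["network"]
    strip_arm = config["candidates"]["strip_arm"]
    key_mirnas, key_mrnas = _key_sets(outdir)
    targets = pd.read_csv(outdir / "target_predictions.tsv", sep="\t")
    edges = network.filter_interactions(targets, key_mirnas, key_mrnas,
                                        min_class=params["min_class"],
                                        strip_arm=strip_arm)
    net = network.build_network(edges)
    network.write_sif(net, outdir / "network.sif")
    network.write_graphml(net, outdir / "network.graphml")
    if net.edges:
        report = network.degree_report(net, mrna_hub_cutoff=params["mrna_hub_cutoff"])
        report.to_csv(outdir / "network_degrees.tsv", sep="\t", index=False)
    return {"n_mirna_nodes": len(net.mirna_nodes),
            "n_mrna_nodes": len(net.mrna_nodes),
            "n_edges": net.n_edges}


def stage_validate(config: RunConfig) -> dict:
    outdir = config.outdir
    params = config["validate"]
    strip_arm = config["candidates"]["strip_arm"]
    seed = config.stage_seed("validate")
    key_mirnas, key_mrnas = _key_sets(outdir)

    exo = _normalized_index(
        ExpressionMatrix.from_tsv(outdir / "norm_exosomal_mirna.tsv", "log2"),
        strip_arm)
    exo_meta = read_metadata(outdir / "exosomal_metadata.tsv")
    tissue = ExpressionMatrix.from_tsv(outdir / "norm_tissue_mrna.tsv", "log2")
    tissue_meta = read_metadata(outdir / "tissue_metadata.tsv")

    mirna_table = validation.validate_features(
        exo, exo_meta, sorted(key_mirnas), roc_seed=seed, n_boot=params["n_boot"])
    mrna_table = validation.validate_features(
        tissue, tissue_meta, sorted(key_mrnas), roc_seed=seed,
        n_boot=params["n_boot"])
    mirna_table.to_csv(outdir / "validation_mirna.tsv", sep="\t", index=False)
    mrna_table.to_csv(outdir / "validation_mrna.tsv", sep="\t", index=False)
    summary = {
        "n_validated_mirnas": int(mirna_table.shape[0]),
        "n_validated_mrnas": int(mrna_table.shape[0]),
        "mean_auc_mirna": float(mirna_table["auc"].mean()) if len(mirna_table) else None,
        "mean_auc_mrna": float(mrna_table["auc"].mean()) if len(mrna_table) else None,
    }
    with open(outdir / "validation_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    return summary


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "dea": stage_dea,
    "candidates": stage_candidates,
    "select": stage_select,
    "network": stage_network,
    "validate": stage_validate,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute all enabled stages in order and write report.json."""
    config.outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {},
                    "parameters": {s: config[s] for s in STAGE_ORDER
                                   if s in config.data}}
    for stage in config.stages:
        t0 = time.perf_counter()
        try:
            counts = _STAGE_FUNCS[stage](config)
        except ExonetError:
            raise
        except Exception as exc:  # noqa: BLE001 - annotate the failing stage
            raise ExonetError(f"stage {stage!r} failed: {exc}") from exc
        elapsed = time.perf_counter() - t0
        logger.info("stage %-10s done in %6.1fs: %s", stage, elapsed, counts)
        report["stages"][stage] = {"counts": counts,
                                   "seconds": round(elapsed, 2),
                                   "seed": config.stage_seed(stage)}
    with open(config.outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    return report


def load_truth(outdir: str | Path) -> GroundTruth:
    with open(Path(outdir) / "ground_truth.json") as fh:
        return GroundTruth.from_json_dict(json.load(fh))
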