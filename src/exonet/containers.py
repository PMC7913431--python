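"""In-memory containers for expression data and sample metadata.

Expression tables are features x samples pandas DataFrames wrapped with a
modality tag so downstream stages know whether values are sequencing counts
("counts"), microarray-style intensities ("intensity") or already on a log2
scale ("log2").  Sample metadata is a plain DataFrame indexed by sample ID
with a mandatory ``group`` column (``tumor``/``normal``) and optional
clinical columns (``survival_time``, ``event``, ``stage``, ``msi``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, InputError

MODALITIES = ("counts", "intensity", "log2")

GROUP_TUMOR = "tumor"
GROUP_NORMAL = "normal"

CLINICAL_COLUMNS = ("survival_time", "event", "stage", "msi")


@dataclass
class ExpressionMatrix:
    """A features x samples expression table with a modality tag."""

    data: pd.DataFrame
    modality: str = "counts"

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise FormatError(
                f"unknown modality {self.modality!r}; expected one of {MODALITIES}"
            )
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise FormatError("expression values must be numeric")

    @property
    def features(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_features(self, feature_ids) -> "ExpressionMatrix":
        keep = [f for f in feature_ids if f in self.data.index]
        return ExpressionMatrix(self.data.loc[keep], self.modality)

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, modality: str = "counts") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, modality)


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Check the metadata contract and return the frame unchanged.

    Every sample carries exactly one group label; clinical fields, when
    present, are populated only for tumor samples.
    """
    if "group" not in metadata.columns:
        raise FormatError("metadata is missing required column 'group'")
    bad = set(metadata["group"].unique()) - {GROUP_TUMOR, GROUP_NORMAL}
    if bad:
        raise FormatError(f"unknown group labels {sorted(bad)}")
    if metadata.index.has_duplicates:
        dupes = metadata.index[metadata.index.duplicated()].tolist()
        raise InputError(f"duplicate sample IDs in metadata: {dupes[:5]}")
    normals = metadata["group"] == GROUP_NORMAL
    for col in CLINICAL_COLUMNS:
        if col in metadata.columns and normals.any():
            if metadata.loc[normals, col].notna().any():
                raise InputError(f"clinical column {col!r} populated for normal samples")
    return metadata


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    out = metadata.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    return validate_metadata(meta)


def align_samples(matrix: ExpressionMatrix, metadata: pd.DataFrame) -> pd.DataFrame:
    """Return metadata restricted and ordered to the matrix columns."""
    missing = [s for s in matrix.samples if s not in metadata.index]
    if missing:
        raise InputError(f"samples missing from metadata: {missing[:5]}")
    return metadata.loc[matrix.samples]


@dataclass
class GroundTruth:
    """Planted structure of a simulated study, keyed by modality.

    Modalities are "mrna" and "mirna"; miRNA truth is shared between the
    tissue count matrix and the exosomal intensity matrix by construction,
    which is what makes the candidate intersection non-empty.
    """

    features: dict = field(default_factory=dict)         # modality -> list of IDs
    planted_de: dict = field(default_factory=dict)       # modality -> set of IDs
    planted_key: dict = field(default_factory=dict)      # modality -> set of IDs
    true_log2fc: dict = field(default_factory=dict)      # modality -> {ID: log2fc}
    planted_edges: set = field(default_factory=set)      # {(mirna, mrna)}

    def __post_init__(self) -> None:
        for mod, keys in self.planted_key.items():
            if not set(keys) <= set(self.planted_de.get(mod, set())):
                raise ConfigurationError(
                    "planted key features are not a subset of planted DE "
                    f"features for {mod!r}"
                )

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        out = GroundTruth()
        for attr in ("features", "planted_de", "planted_key", "true_log2fc"):
            d = dict(getattr(self, attr))
            d.update(getattr(other, attr))
            setattr(out, attr, d)
        out.planted_edges = set(self.planted_edges) | set(other.planted_edges)
        return out

    def to_json_dict(self) -> dict:
        return {
            "features": {k: sorted(v) for k, v in self.features.items()},
            "planted_de": {k: sorted(v) for k, v in self.planted_de.items()},
            "planted_key": {k: sorted(v) for k, v in self.planted_key.items()},
            "true_log2fc": self.true_log2fc,
            "planted_edges": sorted(map(list, self.planted_edges)),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            features={k: list(v) for k, v in d.get("features", {}).items()},
            planted_de={k: set(v) for k, v in d.get("planted_de", {}).items()},
            planted_key={k: set(v) for k, v in d.get("planted_key", {}).items()},
            true_log2fc=d.get("true_log2fc", {}),
            planted_edges={tuple(e) for e in d.get("planted_edges", [])},
        )
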