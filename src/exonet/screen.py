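"""Candidate screening: miRNA ID harmonization and set intersections.

Tissue-DE miRNAs and exosomal-DE miRNAs come from different platforms and
carry differently cased names ("hsa-mir-29c" vs "hsa-miR-29c"), so IDs are
canonicalized before the intersection that yields candidate exosomal
miRNAs.  Target predictions from multiple sources are unioned (any source
counts), restricted to the candidate miRNAs, and intersected with the DE
mRNA set to yield candidate mRNAs, with provenance retained throughout.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .errors import FormatError

logger = logging.getLogger(__name__)

_MIRNA_RE = re.compile(r"^hsa[-_](mir|let)[-]?(.+)$", re.IGNORECASE)
_ARM_RE = re.compile(r"-(3p|5p)$", re.IGNORECASE)

TARGET_COLUMNS = ("source", "mirna", "mrna", "confidence")


def normalize_mirna_id(raw_id: str, strip_arm: bool = False) -> str:
    """Canonicalize a human miRNA name to the mature "hsa-miR-..." casing.

    "hsa-mir-29c" -> "hsa-miR-29c"; "hsa-let-7c" keeps its "let" stem.
    With ``strip_arm=True`` a trailing "-3p"/"-5p" arm suffix is removed.
    Idempotent; IDs not matching the miRNA grammar are passed through
    verbatim with a warning.
    """
    if not raw_id:
        raise FormatError("empty miRNA identifier")
    m = _MIRNA_RE.match(raw_id.strip())
    if m is None:
        warnings.warn(f"identifier {raw_id!r} does not match the miRNA grammar; "
                      "passed through verbatim", stacklevel=2)
        return raw_id
    stem = "let" if m.group(1).lower() == "let" else "miR"
    rest = m.group(2)
    if strip_arm:
        rest = _ARM_RE.sub("", rest)
    else:
        rest = _ARM_RE.sub(lambda a: a.group(0).lower(), rest)
    return f"hsa-{stem}-{rest}"


def normalize_mirna_set(ids, strip_arm: bool = False) -> set[str]:
    return {normalize_mirna_id(i, strip_arm) for i in ids}


def intersect_mirnas(tissue_de: set[str], exosomal_de: set[str]) -> set[str]:
    """Candidate exosomal miRNAs: DE in tissue AND in serum exosomes."""
    candidates = set(tissue_de) & set(exosomal_de)
    if not candidates:
        logger.warning("tissue and exosomal DE miRNA sets are disjoint; "
                       "downstream stages need a non-empty candidate set")
    return candidates


def validate_target_table(table: pd.DataFrame) -> pd.DataFrame:
    for col in TARGET_COLUMNS[:3]:
        if col not in table.columns:
            raise FormatError(f"target table is missing required column {col!r}")
    return table


def union_targets(tables: list[pd.DataFrame], mirnas: set[str],
                  strip_arm: bool = False) -> pd.DataFrame:
    """Union of predicted pairs over sources, restricted to given miRNAs.

    Returns one row per (miRNA, mRNA) pair with a sorted ``sources`` list;
    a pair predicted by any source counts (merge, not vote).
    """
    if not tables:
        raise FormatError("at least one target-prediction table is required")
    frames = []
    for t in tables:
        t = validate_target_table(t).copy()
        t["mirna"] = [normalize_mirna_id(i, strip_arm) for i in t["mirna"]]
        frames.append(t[["source", "mirna", "mrna"]])
    merged = pd.concat(frames, ignore_index=True)
    merged = merged[merged["mirna"].isin(set(mirnas))]
    if merged.empty:
        return pd.DataFrame(columns=["mirna", "mrna", "sources"])
    grouped = (merged.groupby(["mirna", "mrna"])["source"]
               .agg(lambda s: sorted(set(s))).reset_index()
               .rename(columns={"source": "sources"}))
    return grouped.sort_values(["mirna", "mrna"], ignore_index=True)


@dataclass
class CandidateSets:
    """Candidate miRNAs/mRNAs with the evidence that produced each."""

    candidate_mirnas: set[str] = field(default_factory=set)
    candidate_mrnas: set[str] = field(default_factory=set)
    # candidate mRNA -> set of candidate miRNAs predicted to target it
    provenance: dict = field(default_factory=dict)


def intersect_targets_with_de(pairs: pd.DataFrame, de_mrnas: set[str],
                              candidate_mirnas: set[str] | None = None) -> CandidateSets:
    """Candidate mRNAs: predicted targets that are also DE mRNAs."""
    if candidate_mirnas is None:
        candidate_mirnas = set(pairs["mirna"]) if len(pairs) else set()
    surviving = pairs[pairs["mrna"].isin(set(de_mrnas))] if len(pairs) else pairs
    provenance: dict[str, set[str]] = {}
    for _, row in surviving.iterrows():
        provenance.setdefault(row["mrna"], set()).add(row["mirna"])
    result = CandidateSets(
        candidate_mirnas=set(candidate_mirnas),
        candidate_mrnas=set(provenance),
        provenance=provenance,
    )
    if not result.candidate_mrnas:
        logger.warning("no predicted target is differentially expressed; "
                       "candidate mRNA set is empty")
    return result


def screen_candidates(tissue_de_mirnas: set[str], exosomal_de_mirnas: set[str],
                      target_tables: list[pd.DataFrame], de_mrnas: set[str],
                      strip_arm: bool = False) -> CandidateSets:
    """Full screen: harmonize, intersect miRNAs, union targets, intersect mRNAs."""
    tissue = normalize_mirna_set(tissue_de_mirnas, strip_arm)
    exosomal = normalize_mirna_set(exosomal_de_mirnas, strip_arm)
    candidate_mirnas = intersect_mirnas(tissue, exosomal)
    pairs = union_targets(target_tables, candidate_mirnas, strip_arm)
    return intersect_targets_with_de(pairs, de_mrnas, candidate_mirnas)


def candidates_to_frame(cands: CandidateSets) -> pd.DataFrame:
    """Flat TSV-friendly view with a semicolon-joined provenance column."""
    rows = [("mirna", mi, "") for mi in sorted(cands.candidate_mirnas)]
    rows += [("mrna", mr, ";".join(sorted(cands.provenance.get(mr, set()))))
             for mr in sorted(cands.candidate_mrnas)]
    return pd.DataFrame(rows, columns=["kind", "feature_id", "evidence"])
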