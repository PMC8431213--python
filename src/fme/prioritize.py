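"""Rule-based imaging-target prioritization of ranked genes.

An imaging target for fluorescence molecular endoscopy must be accessible to
a topically applied tracer and biologically relevant, so the selection rule
over the top-ranked upregulated genes is:

    membrane-localized  AND  carcinogenesis role
    AND (overexpressed in esophageal cancer OR in gastrointestinal cancer)

Membrane localization is required by default (every target retained in the
motivating analysis was membrane-annotated); ``require_membrane=False``
relaxes it to explore intracellular candidates.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FLAG_COLUMNS = [
    "membrane",
    "esophageal_overexpression",
    "gi_overexpression",
    "carcinogenesis",
]


def load_annotations(ann: pd.DataFrame) -> pd.DataFrame:
    """Normalize an annotation table: one row per gene_id, boolean flags."""
    if "gene_id" in ann.columns:
        ann = ann.set_index("gene_id")
    if not ann.index.is_unique:
        raise ValueError("annotation table has duplicate gene ids")
    out = ann.copy()
    for col in FLAG_COLUMNS:
        if col not in out.columns:
            raise ValueError(f"annotation table lacks required column '{col}'")
        out[col] = out[col].astype(bool)
    return out


def _align(ranks: pd.DataFrame, ann: pd.DataFrame, top_n: int) -> pd.DataFrame:
    if top_n > len(ranks):
        raise ValueError(f"top_n={top_n} exceeds rank table size {len(ranks)}")
    top = ranks[ranks["rank"] <= top_n]
    ann = load_annotations(ann)
    merged = top.join(ann[FLAG_COLUMNS + [c for c in ("exclude_reason",) if c in ann.columns]])
    absent = merged["membrane"].isna()
    if absent.any():
        logger.warning(
            "%d of top %d genes absent from annotation table; treated as all-false",
            int(absent.sum()), top_n,
        )
    for col in FLAG_COLUMNS:
        merged[col] = merged[col].map(
            lambda v: bool(v) if pd.notna(v) else False
        ).astype(bool)
    return merged


def select_candidates(
    ranks: pd.DataFrame,
    ann: pd.DataFrame,
    top_n: int = 60,
    require_membrane: bool = True,
) -> pd.DataFrame:
    """Apply the target-selection rule to the top_n ranked genes.

    Returns the qualifying rows of the rank table (order preserved) with the
    annotation flags and, per gene, which rule clauses were satisfied.
    """
    merged = _align(ranks, ann, top_n)
    if merged[FLAG_COLUMNS].to_numpy().sum() == 0:
        logger.warning("annotation table contributes no flags; candidate list empty")
    membrane_ok = merged["membrane"] | (not require_membrane)
    rule = (
        membrane_ok
        & merged["carcinogenesis"]
        & (merged["esophageal_overexpression"] | merged["gi_overexpression"])
    )
    out = merged[rule].copy()
    out["clauses"] = [
        "+".join(
            c for c in FLAG_COLUMNS if row[c]
        )
        for _, row in out.iterrows()
    ]
    return out


def apply_exclusions(candidates: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split candidates on the optional wet-lab ``exclude_reason`` column.

    Returns (retained, excluded); exclusion reflects constraints outside the
    expression analysis (e.g. no validated antibody for IHC).
    """
    if "exclude_reason" not in candidates.columns:
        return candidates, candidates.iloc[0:0]
    reason = candidates["exclude_reason"].fillna("").astype(str)
    excluded = candidates[reason != ""]
    return candidates[reason == ""], excluded


def summarize_annotations(
    ann: pd.DataFrame, ranks: pd.DataFrame, top_n: int = 60
) -> pd.Series:
    """Counts of each annotation flag among the top_n ranked genes."""
    merged = _align(ranks, ann, top_n)
    counts = merged[FLAG_COLUMNS].sum().astype(int)
    counts["top_n"] = int(top_n)
    return counts
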