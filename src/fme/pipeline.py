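"""End-to-end orchestration: discovery and validation arms.

Discovery chains confounder correction -> class comparison -> target
prioritization; validation chains IHC H-score analytics and fluorescence
biopsy quantification.  Each run writes its artifacts plus a JSON report
whose every number is re-derivable by calling the module operations with the
logged parameters.  Reports serialize floats at 10 significant digits so
seeded reruns are byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexpr, fgmrna, fluor, ihc, prioritize, synthetic

logger = logging.getLogger(__name__)


def _round_floats(obj, digits: int = 10):
    if isinstance(obj, dict):
        return {k: _round_floats(v, digits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, digits) for v in obj]
    if isinstance(obj, (bool, np.bool_)):
        return bool(obj)
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    if isinstance(obj, (float, np.floating)):
        return float(f"{float(obj):.{digits}g}")
    return obj


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(_round_floats(report), indent=1, sort_keys=True))


def _require(path, what: str) -> Path:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"{what} not found: {p}")
    return p


def simulate_annotations(
    gene_ids, spiked_genes, seed: int = 0
) -> pd.DataFrame:
    """Synthetic literature-annotation fixture.

    Spiked (true-signal) genes receive imaging-favorable flags; non-spiked
    genes never satisfy the full membrane+carcinogenesis conjunction, so on
    this fixture any selected candidate is a spiked gene by construction.
    """
    rng = np.random.default_rng(seed)
    spiked = set(spiked_genes)
    rows = []
    for g in gene_ids:
        if g in spiked:
            membrane = bool(rng.random() < 0.5)
            carcinogenesis = True
            gi = bool(rng.random() < 0.7)
            eso = bool(rng.random() < 0.4)
        else:
            membrane = bool(rng.random() < 0.25)
            carcinogenesis = bool((not membrane) and rng.random() < 0.4)
            gi = bool(rng.random() < 0.3)
            eso = bool(rng.random() < 0.15)
        rows.append(
            {
                "gene_id": g,
                "membrane": membrane,
                "esophageal_overexpression": eso,
                "gi_overexpression": gi,
                "carcinogenesis": carcinogenesis,
                "localization": "plasma membrane" if membrane else "cytoplasm",
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def run_discovery(config: dict) -> dict:
    """fgmrna -> diffexpr -> prioritize; returns and writes the run report."""
    seed = int(config.get("seed", 0))
    out_dir = Path(config.get("out_dir", "discovery_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "inputs"
    try:
        if config.get("simulate", False):
            sim_kwargs = dict(config.get("simulate_params", {}))
            sim_kwargs.setdefault("seed", seed)
            sim = synthetic.simulate_compendium(synthetic.CompendiumConfig(**sim_kwargs))
            expr, cna, labels = sim.expression, sim.copy_number, sim.class_labels
            ann = simulate_annotations(expr.gene_ids, sim.spiked_genes, seed=seed)
        else:
            expr_df = synthetic.read_matrix_tsv(_require(config["expression"], "expression matrix"))
            cna_df = synthetic.read_matrix_tsv(_require(config["copy_number"], "copy-number matrix"))
            labels = synthetic.read_labels_csv(_require(config["labels"], "labels file"))
            expr = fgmrna.ExpressionMatrix(values=expr_df, class_labels=labels)
            cna = fgmrna.CopyNumberMatrix(values=cna_df)
            ann = pd.read_csv(_require(config["annotations"], "annotation table"))

        stage = "fgmrna"
        profiles, comp = fgmrna.correct(
            expr, cna, k=config.get("k"), alpha=float(config.get("alpha", 0.01))
        )
        stage = "diffexpr"
        stats_df, mvp, ranks = diffexpr.class_comparison(
            profiles,
            labels,
            fdr_target=float(config.get("fdr", 0.01)),
            confidence=float(config.get("confidence", 0.99)),
            n_permutations=int(config.get("n_permutations", 1000)),
            seed=seed,
        )
        stage = "prioritize"
        top_n = min(int(config.get("top_n", 60)), len(ranks))
        candidates = prioritize.select_candidates(
            ranks, ann, top_n=top_n,
            require_membrane=not config.get("relax_membrane", False),
        )
        summary = prioritize.summarize_annotations(ann, ranks, top_n=top_n)
    except Exception as exc:
        raise RuntimeError(f"discovery failed at stage '{stage}': {exc}") from exc

    synthetic.write_matrix_tsv(profiles.values, out_dir / "profiles.tsv")
    ranks.to_csv(out_dir / "ranks.tsv", sep="\t")
    candidates.to_csv(out_dir / "candidates.csv")
    report = {
        "arm": "discovery",
        "seed": seed,
        "parameters": {
            "k": comp.k,
            "alpha": float(config.get("alpha", 0.01)),
            "fdr": float(config.get("fdr", 0.01)),
            "confidence": float(config.get("confidence", 0.99)),
            "n_permutations": mvp.n_permutations,
            "top_n": top_n,
        },
        "counts": {
            "genes": len(expr.gene_ids),
            "samples": len(expr.sample_ids),
            "components_removed": len(profiles.components_removed),
            "significant": len(mvp.significant_ids),
            "upregulated_ranked": int(len(ranks)),
            "candidates": int(len(candidates)),
        },
        "p_threshold": mvp.p_threshold if np.isfinite(mvp.p_threshold) else None,
        "annotation_summary": {k: int(v) for k, v in summary.items()},
        "candidates": list(candidates.index),
    }
    write_report(report, out_dir / "discovery_report.json")
    return report


def run_validation(config: dict) -> dict:
    """IHC and fluorescence stages; returns and writes the validation report."""
    seed = int(config.get("seed", 0))
    out_dir = Path(config.get("out_dir", "validation_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "ihc"
    try:
        if config.get("simulate", False):
            ihc_kwargs = dict(config.get("ihc_params", {}))
            ihc_kwargs.setdefault("seed", seed)
            cohort = synthetic.simulate_ihc_cohort(synthetic.IHCCohortConfig(**ihc_kwargs))
        else:
            cohort = pd.read_csv(_require(config["ihc_cohort"], "IHC cohort table"))
        ihc_summary = ihc.analyze_cohort(cohort)

        stage = "fluor"
        if config.get("simulate", False):
            bio_kwargs = dict(config.get("biopsy_params", {}))
            bio_kwargs.setdefault("seed", seed)
            if "groups" in bio_kwargs:
                bio_kwargs["groups"] = {
                    k: synthetic.BiopsyGroup(**v) for k, v in bio_kwargs["groups"].items()
                }
                records = synthetic.simulate_biopsy_set(
                    synthetic.BiopsyCohortConfig(**bio_kwargs)
                )
            else:
                records = synthetic.simulate_biopsy_set(
                    synthetic.published_biopsy_config(**bio_kwargs)
                )
        elif "biopsy_manifest" in config:
            records = fluor.load_biopsies(_require(config["biopsy_manifest"], "biopsy manifest"))
        else:
            records = []
        if records:
            fluor_summary = fluor.analyze_cohort(
                records,
                cutoff=config.get("cutoff"),
                binarize_rule=config.get("binarize", "otsu"),
            )
            fluor_summary["mfi_table"].to_csv(out_dir / "mfi.csv", index=False)
            fluor_summary["overlap_table"].to_csv(out_dir / "overlap.csv", index=False)
            fluor_report = {
                k: v for k, v in fluor_summary.items()
                if k not in ("mfi_table", "overlap_table")
            }
        else:
            logger.warning("empty biopsy set; fluorescence stage skipped")
            fluor_report = None
    except Exception as exc:
        raise RuntimeError(f"validation failed at stage '{stage}': {exc}") from exc

    report = {
        "arm": "validation",
        "seed": seed,
        "ihc": ihc_summary,
        "fluorescence": fluor_report,
    }
    write_report(report, out_dir / "validation_report.json")
    return report
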