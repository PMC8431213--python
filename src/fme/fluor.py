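"""Fluorescence biopsy quantification.

Biopsies sprayed ex vivo with a NIR glucose-analogue tracer are scanned and
compared with histology: per-biopsy mean fluorescence intensity (MFI) over
the tissue area, Mann-Whitney group comparisons, a ROC curve discriminating
high-grade dysplasia/carcinoma from low-grade dysplasia/normal mucosa with a
cut-off (Youden), and pixel-level overlap between tracer-positive and
target-positive (e.g. GLUT1 IHC) areas on serial slices.

Conventions: a biopsy is called positive when MFI > cutoff (ties count as
negative calls); overlap sensitivity = |tracer+ ∩ target+| / |target+| and
specificity = |tracer- ∩ target- ∩ tissue| / |target- ∩ tissue|, with an
undefined statistic reported as NaN rather than coerced to 0.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import stats
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)

GROUPS = ["normal", "LGD", "HGD", "ESCC"]
POSITIVE_LABELS = frozenset({"HGD", "ESCC"})

EXACT_MW_LIMIT = 400  # exact Mann-Whitney enumeration when n_a * n_b <= this


@dataclass
class BiopsyRecord:
    """One biopsy: fluorescence scan, tissue mask, target-positivity mask."""

    biopsy_id: str
    patient_id: str
    label: str
    fluorescence: np.ndarray
    tissue_mask: np.ndarray
    target_mask: np.ndarray
    mfi_expected: float | None = None  # generator-drawn target MFI, if synthetic

    def __post_init__(self) -> None:
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        self.tissue_mask = np.asarray(self.tissue_mask, dtype=bool)
        self.target_mask = np.asarray(self.target_mask, dtype=bool)
        if not (self.fluorescence.shape == self.tissue_mask.shape == self.target_mask.shape):
            raise ValueError("fluorescence and masks must share one shape")
        if not np.isfinite(self.fluorescence).all():
            raise ValueError("fluorescence contains non-finite values")
        if (self.fluorescence < 0).any():
            raise ValueError("fluorescence must be non-negative")
        if (self.target_mask & ~self.tissue_mask).any():
            raise ValueError("target mask extends outside the tissue mask")


@dataclass
class OverlapStats:
    """Pixel-level tracer-vs-target agreement; NaN marks an undefined ratio."""

    sensitivity: float
    specificity: float


@dataclass
class TracerMask:
    mask: np.ndarray
    rule: str
    threshold: float | None


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    chosen_cutoff: float | None = None
    sens_at_cutoff: float | None = None
    spec_at_cutoff: float | None = None


def load_biopsies(manifest_path) -> list[BiopsyRecord]:
    """Load a biopsy set from a manifest JSON of TIFF triplets.

    The manifest lists, per biopsy, the fluorescence (16-bit) and mask
    (8-bit, >0 interpreted as true) TIFF files relative to its directory.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"biopsy manifest not found: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    records = []
    for entry in manifest["biopsies"]:
        records.append(
            BiopsyRecord(
                biopsy_id=entry["biopsy_id"],
                patient_id=entry.get("patient_id", entry["biopsy_id"]),
                label=entry["label"],
                fluorescence=tifffile.imread(base / entry["fluorescence"]).astype(float),
                tissue_mask=tifffile.imread(base / entry["tissue_mask"]) > 0,
                target_mask=tifffile.imread(base / entry["target_mask"]) > 0,
            )
        )
    return records


def mean_fluorescence(rec: BiopsyRecord, include_background: bool = False) -> float:
    """Mean fluorescence intensity over the tissue mask (or the whole frame)."""
    if include_background:
        return float(rec.fluorescence.mean())
    if not rec.tissue_mask.any():
        raise ValueError(f"biopsy {rec.biopsy_id}: empty tissue mask")
    return float(rec.fluorescence[rec.tissue_mask].mean())


def mfi_table(records, include_background: bool = False) -> pd.DataFrame:
    """Per-biopsy MFI table with columns biopsy_id, patient_id, label, mfi."""
    return pd.DataFrame(
        {
            "biopsy_id": [r.biopsy_id for r in records],
            "patient_id": [r.patient_id for r in records],
            "label": [r.label for r in records],
            "mfi": [mean_fluorescence(r, include_background) for r in records],
        }
    )


def _split(table: pd.DataFrame, positive_labels) -> tuple[np.ndarray, np.ndarray]:
    pos = table.loc[table["label"].isin(positive_labels), "mfi"].to_numpy(float)
    neg = table.loc[~table["label"].isin(positive_labels), "mfi"].to_numpy(float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need at least one positive and one negative biopsy")
    return pos, neg


def compare_mfi_groups(
    table: pd.DataFrame, group_a: str, group_b: str
) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U between the MFI values of two label groups.

    Exact enumeration when n_a * n_b <= 400 and the data are tie-free;
    otherwise the tie-corrected normal approximation.  Groups may also be
    given as collections of labels (e.g. ("HGD", "ESCC")).
    """
    def values(g):
        labels = (g,) if isinstance(g, str) else tuple(g)
        return table.loc[table["label"].isin(labels), "mfi"].to_numpy(float)

    a, b = values(group_a), values(group_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group in Mann-Whitney comparison")
    if a.size < 2 or b.size < 2:
        raise ValueError("p-value computed only when both groups have >= 2 values")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size * b.size <= EXACT_MW_LIMIT and not has_ties) else "asymptotic"
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(u), float(min(p, 1.0))


def roc_auc(
    table: pd.DataFrame, positive_labels=POSITIVE_LABELS
) -> ROCResult:
    """ROC curve and AUC for discriminating positive labels by MFI.

    AUC is the Mann-Whitney concordance P(MFI_pos > MFI_neg) + 0.5 P(tie);
    it equals the trapezoidal area under the curve (asserted to 1e-9).
    """
    pos, neg = _split(table, positive_labels)
    # pair-counting AUC
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    auc = (greater + 0.5 * ties) / (pos.size * neg.size)
    thresholds = np.concatenate([[-np.inf], np.unique(np.concatenate([pos, neg]))])
    sens = np.array([(pos > t).mean() for t in thresholds])
    spec = np.array([(neg <= t).mean() for t in thresholds])
    # trapezoidal area over (FPR, TPR), endpoints (0,0) and (1,1) included
    fpr, tpr = 1.0 - spec, sens
    order = np.lexsort((tpr, fpr))  # valid traversal: both coordinates ascend
    area = abs(float(np.trapezoid(tpr[order], fpr[order])))
    assert abs(area - auc) < 1e-9, "rank AUC and trapezoidal area disagree"
    return ROCResult(
        thresholds=thresholds, sensitivity=sens, specificity=spec, auc=float(auc)
    )


def sens_spec_at_cutoff(
    table: pd.DataFrame, cutoff: float, positive_labels=POSITIVE_LABELS
) -> tuple[float, float]:
    """Sensitivity/specificity of the call "positive iff MFI > cutoff"."""
    pos, neg = _split(table, positive_labels)
    return float((pos > cutoff).mean()), float((neg <= cutoff).mean())


def choose_cutoff(roc: ROCResult, rule: str = "youden") -> float:
    """Select a cutoff from a ROC curve; Youden maximizes sens + spec - 1.

    Ties are broken toward the smallest qualifying threshold.
    """
    if rule != "youden":
        raise ValueError(f"unknown cutoff rule '{rule}'")
    j = roc.sensitivity + roc.specificity - 1.0
    finite = np.isfinite(roc.thresholds)
    j_best = j[finite].max()
    candidates = roc.thresholds[finite & (j >= j_best - 1e-12)]
    return float(candidates.min())


def binarize_fluorescence(
    rec: BiopsyRecord,
    rule: str = "otsu",
    value: float | None = None,
    percentile: float | None = None,
) -> TracerMask:
    """Tracer-positivity mask over tissue pixels.

    Rules: ``otsu`` (threshold from the tissue-pixel histogram, default),
    ``fixed`` (``value`` in fluorescence units), ``percentile`` (of tissue
    pixels).  Positivity is strict: fluorescence > threshold, within tissue.
    """
    tissue_vals = rec.fluorescence[rec.tissue_mask]
    if rule == "otsu":
        if np.all(tissue_vals == tissue_vals[0]):
            logger.warning(
                "biopsy %s: constant image, Otsu undefined; all-negative mask",
                rec.biopsy_id,
            )
            return TracerMask(np.zeros_like(rec.tissue_mask), rule, None)
        thr = float(threshold_otsu(tissue_vals))
    elif rule == "fixed":
        if value is None:
            raise ValueError("fixed rule requires a threshold value")
        thr = float(value)
    elif rule == "percentile":
        if percentile is None:
            raise ValueError("percentile rule requires a percentile")
        thr = float(np.percentile(tissue_vals, percentile))
    else:
        raise ValueError(f"unknown binarization rule '{rule}'")
    mask = (rec.fluorescence > thr) & rec.tissue_mask
    return TracerMask(mask=mask, rule=rule, threshold=thr)


def pixel_overlap(tracer_mask: np.ndarray, rec: BiopsyRecord) -> OverlapStats:
    """Tracer-vs-target overlap within the tissue area.

    sensitivity = |tracer+ ∩ target+| / |target+|;
    specificity = |tracer- ∩ target- ∩ tissue| / |target- ∩ tissue|.
    An empty denominator yields NaN for that statistic (flagged in the log).
    """
    tracer_mask = np.asarray(tracer_mask, dtype=bool)
    if (tracer_mask & ~rec.tissue_mask).any():
        raise ValueError("tracer mask extends outside the tissue mask")
    target_pos = rec.target_mask
    target_neg = rec.tissue_mask & ~rec.target_mask
    n_pos, n_neg = int(target_pos.sum()), int(target_neg.sum())
    if n_pos == 0:
        logger.warning("biopsy %s: no target-positive pixels; sensitivity undefined", rec.biopsy_id)
        sens = float("nan")
    else:
        sens = float((tracer_mask & target_pos).sum() / n_pos)
    if n_neg == 0:
        logger.warning("biopsy %s: no target-negative pixels; specificity undefined", rec.biopsy_id)
        spec = float("nan")
    else:
        spec = float((~tracer_mask & target_neg).sum() / n_neg)
    return OverlapStats(sensitivity=sens, specificity=spec)


def cohort_overlap_summary(
    records, rule: str = "otsu", value: float | None = None, percentile: float | None = None
) -> dict:
    """Median overlap sensitivity/specificity over a biopsy cohort.

    Biopsies whose statistic is undefined are excluded from that median; the
    reported n reflects the exclusions.  Returns the per-biopsy table too.
    """
    rows = []
    for rec in records:
        tracer = binarize_fluorescence(rec, rule=rule, value=value, percentile=percentile)
        ov = pixel_overlap(tracer.mask, rec)
        rows.append(
            {
                "biopsy_id": rec.biopsy_id,
                "label": rec.label,
                "sensitivity": ov.sensitivity,
                "specificity": ov.specificity,
                "threshold": tracer.threshold,
            }
        )
    per_biopsy = pd.DataFrame(rows)
    if per_biopsy.empty:
        raise ValueError("no biopsy records provided")
    sens = per_biopsy["sensitivity"].dropna()
    spec = per_biopsy["specificity"].dropna()
    return {
        "rule": rule,
        "median_sensitivity": float(sens.median()) if len(sens) else float("nan"),
        "median_specificity": float(spec.median()) if len(spec) else float("nan"),
        "n_sensitivity": int(len(sens)),
        "n_specificity": int(len(spec)),
        "per_biopsy": per_biopsy,
    }


def analyze_cohort(
    records,
    cutoff: float | None = None,
    positive_labels=POSITIVE_LABELS,
    binarize_rule: str = "otsu",
) -> dict:
    """Full fluorescence validation: MFI stats, group tests, ROC, overlap."""
    table = mfi_table(records)
    group_stats = {
        g: {
            "n": int((table["label"] == g).sum()),
            "mean": float(table.loc[table["label"] == g, "mfi"].mean()),
            "sd": float(table.loc[table["label"] == g, "mfi"].std(ddof=1)),
        }
        for g in table["label"].unique()
    }
    roc = roc_auc(table, positive_labels)
    chosen = choose_cutoff(roc) if cutoff is None else float(cutoff)
    sens, spec = sens_spec_at_cutoff(table, chosen, positive_labels)
    overlap = cohort_overlap_summary(records, rule=binarize_rule)
    return {
        "n_biopsies": int(len(table)),
        "group_stats": group_stats,
        "auc": roc.auc,
        "cutoff": chosen,
        "cutoff_rule": "youden" if cutoff is None else "fixed",
        "sens_at_cutoff": sens,
        "spec_at_cutoff": spec,
        "overlap": {k: v for k, v in overlap.items() if k != "per_biopsy"},
        "mfi_table": table,
        "overlap_table": overlap["per_biopsy"],
    }
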