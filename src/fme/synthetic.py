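"""Seeded generators for every input of the pipeline.

The generators reproduce the statistical structure the analysis assumes:

* an expression compendium with low-rank non-genetic components plus an
  SCNA-driven tumor spike (and a paired copy-number matrix);
* an IHC cohort whose staining-category mix matches a configured
  distribution, with staining fractions that reproduce each drawn H-score
  exactly;
* per-group biopsy MFI draws calibrated to published group means/SDs
  (normal 1323 +/- 589.7 n=5; LGD 2027 +/- 1190 n=7; HGD 4596 +/- 2135 n=13;
  ESCC 4309 +/- 2657 n=17);
* full synthetic biopsies (fluorescence image, elliptical tissue mask,
  contiguous target-positive blob, optional bright rim artifact) whose
  tissue-mask MFI equals the drawn value up to pixel noise.

All randomness flows from one ``numpy.random.Generator`` seeded per call;
identical seed and config give bit-identical outputs.
"""

from __future__ import annotations

import heapq
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import binary_erosion, gaussian_filter

from . import ihc
from .fgmrna import CopyNumberMatrix, ExpressionMatrix
from .fluor import BiopsyRecord

logger = logging.getLogger(__name__)

CNA_NOISE_SD = 0.05  # jitter on the 0-centered copy-number estimates


def _require_finite(name: str, value: float) -> None:
    if not np.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value}")


# ---------------------------------------------------------------------------
# expression compendium
# ---------------------------------------------------------------------------

@dataclass
class CompendiumConfig:
    """Synthetic tumor/normal expression compendium parameters.

    ``spike_effect`` is added (in expression units) to tumor samples of the
    spiked genes; ``cna_gain`` is the matching copy-number offset.
    ``confounder_class_bias`` shifts confounder scores of tumor samples to
    induce confounder-class correlation (0 = class-independent, the default).
    """

    n_genes: int = 500
    n_tumor: int = 118
    n_normal: int = 120
    n_confounders: int = 5
    confounder_sd: float = 2.0
    n_spiked: int = 20
    spike_effect: float = 3.0
    noise_sd: float = 1.0
    cna_gain: float = 1.0
    confounder_class_bias: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("confounder_sd", "spike_effect", "noise_sd", "cna_gain",
                     "confounder_class_bias"):
            _require_finite(name, getattr(self, name))
        if min(self.n_genes, self.n_tumor, self.n_normal) < 1:
            raise ValueError("n_genes, n_tumor, n_normal must be >= 1")
        if self.n_spiked < 0 or self.n_spiked > self.n_genes:
            raise ValueError("need 0 <= n_spiked <= n_genes")
        if self.n_confounders < 0:
            raise ValueError("n_confounders must be >= 0")
        if self.confounder_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")


@dataclass
class SimulatedCompendium:
    """Generator output plus the ground truth the simulation used."""

    expression: ExpressionMatrix
    copy_number: CopyNumberMatrix
    class_labels: pd.Series
    spiked_genes: list[str]
    confounder_loadings: np.ndarray  # genes x n_confounders
    confounder_scores: np.ndarray  # samples x n_confounders


def simulate_compendium(config: CompendiumConfig) -> SimulatedCompendium:
    """Low-rank confounders + tumor spike + i.i.d. Gaussian noise.

    expression(g, s) = sum_k loading(g,k) * score(s,k)
                       + spike_effect * [g spiked and s tumor] + noise;
    confounder scores are N(0,1) per sample, loadings N(0, confounder_sd^2),
    so the expected extra variance of gene g is sum_k loading(g,k)^2.
    """
    rng = np.random.default_rng(config.seed)
    g, nt, nn = config.n_genes, config.n_tumor, config.n_normal
    n = nt + nn
    gene_ids = [f"G{i + 1:04d}" for i in range(g)]
    sample_ids = [f"T{i + 1:03d}" for i in range(nt)] + [f"N{i + 1:03d}" for i in range(nn)]
    labels = pd.Series(["tumor"] * nt + ["normal"] * nn, index=sample_ids, name="class")
    is_tumor = (labels == "tumor").to_numpy().astype(float)
    spiked = np.zeros(g)
    spiked[: config.n_spiked] = 1.0

    loadings = rng.normal(0.0, config.confounder_sd, size=(g, config.n_confounders))
    scores = rng.standard_normal((n, config.n_confounders))
    scores = scores + config.confounder_class_bias * is_tumor[:, None]
    expr = loadings @ scores.T
    expr += config.spike_effect * np.outer(spiked, is_tumor)
    expr += rng.normal(0.0, config.noise_sd, size=(g, n))

    cna = config.cna_gain * np.outer(spiked, is_tumor)
    cna += rng.normal(0.0, CNA_NOISE_SD, size=(g, n))

    expr_df = pd.DataFrame(expr, index=gene_ids, columns=sample_ids)
    cna_df = pd.DataFrame(cna, index=gene_ids, columns=sample_ids)
    return SimulatedCompendium(
        expression=ExpressionMatrix(values=expr_df, class_labels=labels),
        copy_number=CopyNumberMatrix(values=cna_df),
        class_labels=labels,
        spiked_genes=gene_ids[: config.n_spiked],
        confounder_loadings=loadings,
        confounder_scores=scores,
    )


# ---------------------------------------------------------------------------
# IHC cohort
# ---------------------------------------------------------------------------

@dataclass
class IHCCohortConfig:
    """Case/control cohort with configured staining-category probabilities.

    Defaults reproduce the validation cohort mix: 30 carcinoma samples of
    which 25 stain intermediate-to-high, against 27 adjacent-normal samples
    that are all negative/low.
    """

    n_case: int = 30
    n_control: int = 27
    case_category_probs: tuple[float, float, float] = (5 / 30, 12 / 30, 13 / 30)
    control_category_probs: tuple[float, float, float] = (1.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 0 or self.n_control < 0:
            raise ValueError("cohort sizes must be >= 0")
        for name in ("case_category_probs", "control_category_probs"):
            p = np.asarray(getattr(self, name), dtype=float)
            if p.size != 3 or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a 3-vector of probabilities summing to 1")


def _fractions_for_h(h: float, rng: np.random.Generator) -> tuple[float, float, float]:
    """Random valid (weak, moderate, strong) fractions with the exact H-score.

    With v = h/100, solves w + 2m + 3s = v under w, m, s >= 0 and
    w + m + s <= 1 by sampling s then m uniformly within their feasible
    intervals.
    """
    v = h / 100.0
    s_lo, s_hi = max(0.0, v - 2.0), min(1.0, v / 3.0)
    s = rng.uniform(s_lo, s_hi)
    rem = v - 3.0 * s
    m_lo, m_hi = max(0.0, rem - (1.0 - s)), rem / 2.0
    m = rng.uniform(m_lo, m_hi)
    w = rem - 2.0 * m
    return max(w, 0.0), m, s


def simulate_ihc_cohort(config: IHCCohortConfig) -> pd.DataFrame:
    """Per-sample staining fractions drawn to match the category mix.

    Each sample's category is drawn from its group's probabilities, a target
    H-score uniformly within that category's band, and staining fractions
    that reproduce the H-score exactly.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for group, n, probs in (
        ("case", config.n_case, config.case_category_probs),
        ("control", config.n_control, config.control_category_probs),
    ):
        for i in range(n):
            cat = ihc.CATEGORIES[rng.choice(3, p=np.asarray(probs, dtype=float))]
            lo, hi = ihc.CATEGORY_BANDS[cat]
            h = rng.uniform(lo, hi)
            w, m, s = _fractions_for_h(h, rng)
            rows.append(
                {
                    "sample_id": f"{group[0].upper()}{i + 1:03d}",
                    "group": group,
                    "frac_weak": w,
                    "frac_moderate": m,
                    "frac_strong": s,
                    "h_score": ihc.h_score(w, m, s),
                    "category": cat,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "group", "frac_weak", "frac_moderate",
                 "frac_strong", "h_score", "category"],
    )


# ---------------------------------------------------------------------------
# biopsy cohort (MFI draws and full images)
# ---------------------------------------------------------------------------

@dataclass
class BiopsyGroup:
    n: int
    mfi_mean: float
    mfi_sd: float
    positive_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("group size must be >= 0")
        if self.mfi_sd <= 0:
            raise ValueError("mfi_sd must be > 0")
        if not 0 <= self.positive_fraction <= 1:
            raise ValueError("positive_fraction must be in [0, 1]")
        _require_finite("mfi_mean", self.mfi_mean)


@dataclass
class BiopsyCohortConfig:
    """Per-group MFI distributions and image-rendering parameters.

    ``signal_contrast`` is the ratio of the target-positive level to the
    tissue background; ``rim_boost`` the rim/background ratio of the optional
    2-pixel edge artifact; ``noise_sd`` is absolute pixel noise (fluorescence
    units).  Levels are solved so the tissue-mask mean equals the drawn MFI.
    """

    groups: dict[str, BiopsyGroup] = field(default_factory=dict)
    image_shape: tuple[int, int] = (64, 64)
    edge_artifact: bool = False
    noise_sd: float = 50.0
    signal_contrast: float = 3.0
    rim_boost: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.image_shape) < 16:
            raise ValueError("image_shape must be at least (16, 16)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.signal_contrast <= 0 or self.rim_boost <= 0:
            raise ValueError("signal_contrast and rim_boost must be > 0")


def published_biopsy_config(seed: int = 0, **kwargs) -> BiopsyCohortConfig:
    """Cohort calibrated to the published per-group MFI statistics."""
    groups = {
        "normal": BiopsyGroup(5, 1323.0, 589.7, positive_fraction=0.02),
        "LGD": BiopsyGroup(7, 2027.0, 1190.0, positive_fraction=0.10),
        "HGD": BiopsyGroup(13, 4596.0, 2135.0, positive_fraction=0.30),
        "ESCC": BiopsyGroup(17, 4309.0, 2657.0, positive_fraction=0.40),
    }
    return BiopsyCohortConfig(groups=groups, seed=seed, **kwargs)


def _draw_mfi(mean: float, sd: float, rng: np.random.Generator) -> float:
    """Normal draw truncated at 0 by redraw (keeps the distribution unimodal)."""
    while True:
        v = rng.normal(mean, sd)
        if v > 0:
            return float(v)


def simulate_mfi_cohort(config: BiopsyCohortConfig) -> pd.DataFrame:
    """Table (biopsy_id, label, mfi) of truncated-normal per-group draws."""
    rng = np.random.default_rng(config.seed)
    rows = []
    i = 0
    for label, grp in config.groups.items():
        for _ in range(grp.n):
            i += 1
            rows.append(
                {
                    "biopsy_id": f"B{i:03d}",
                    "label": label,
                    "mfi": _draw_mfi(grp.mfi_mean, grp.mfi_sd, rng),
                }
            )
    return pd.DataFrame(rows, columns=["biopsy_id", "label", "mfi"])


def _ellipse_mask(shape: tuple[int, int]) -> np.ndarray:
    rows, cols = shape
    r, c = np.ogrid[:rows, :cols]
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    return ((r - cy) / (0.42 * rows)) ** 2 + ((c - cx) / (0.42 * cols)) ** 2 <= 1.0


def _grow_blob(
    field: np.ndarray, tissue: np.ndarray, count: int
) -> np.ndarray:
    """Contiguous region of ``count`` tissue pixels grown by field priority.

    Seeded at the field maximum within the tissue; neighbors join in order of
    decreasing field value, which yields a single connected blob of exactly
    the requested size (a contiguous 'tumor area').
    """
    blob = np.zeros_like(tissue, dtype=bool)
    if count <= 0:
        return blob
    masked = np.where(tissue, field, -np.inf)
    start = np.unravel_index(int(np.argmax(masked)), field.shape)
    heap = [(-field[start], start)]
    queued = {start}
    taken = 0
    while heap and taken < count:
        _, (i, j) = heapq.heappop(heap)
        blob[i, j] = True
        taken += 1
        for ni, nj in ((i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1)):
            if (
                0 <= ni < field.shape[0]
                and 0 <= nj < field.shape[1]
                and tissue[ni, nj]
                and (ni, nj) not in queued
            ):
                queued.add((ni, nj))
                heapq.heappush(heap, (-field[ni, nj], (ni, nj)))
    return blob


def simulate_biopsy_set(config: BiopsyCohortConfig) -> list[BiopsyRecord]:
    """Full synthetic biopsies: image + tissue mask + target mask per draw.

    The tissue mask is a centered ellipse; the target mask a contiguous blob
    covering the group's positive fraction of tissue pixels; intensity levels
    (background, optional bright rim, target signal) are solved so the
    tissue-mask mean equals the MFI drawn from the group's distribution, then
    Gaussian pixel noise is added.
    """
    rng = np.random.default_rng(config.seed)
    tissue = _ellipse_mask(config.image_shape)
    n_tissue = int(tissue.sum())
    interior = binary_erosion(tissue, iterations=2)
    rim = tissue & ~interior
    records: list[BiopsyRecord] = []
    i = 0
    for label, grp in config.groups.items():
        for _ in range(grp.n):
            i += 1
            mfi = _draw_mfi(grp.mfi_mean, grp.mfi_sd, rng)
            if grp.positive_fraction == 0 and config.signal_contrast != 1.0:
                logger.warning(
                    "biopsy B%03d: positive_fraction=0, signal term skipped", i
                )
            field = gaussian_filter(
                rng.standard_normal(config.image_shape),
                sigma=min(config.image_shape) / 8.0,
            )
            n_pos = int(round(grp.positive_fraction * n_tissue))
            target = _grow_blob(field, tissue, n_pos)
            rim_only = rim & ~target if config.edge_artifact else np.zeros_like(tissue)
            bg_only = tissue & ~target & ~rim_only
            weights = (
                int(bg_only.sum())
                + config.rim_boost * int(rim_only.sum())
                + config.signal_contrast * int(target.sum())
            )
            base = mfi * n_tissue / weights
            img = np.zeros(config.image_shape, dtype=float)
            img[bg_only] = base
            img[rim_only] = config.rim_boost * base
            img[target] = config.signal_contrast * base
            if config.noise_sd > 0:
                img[tissue] += rng.normal(0.0, config.noise_sd, size=n_tissue)
                img = np.clip(img, 0.0, None)
            records.append(
                BiopsyRecord(
                    biopsy_id=f"B{i:03d}",
                    patient_id=f"P{i:03d}",
                    label=label,
                    fluorescence=img,
                    tissue_mask=tissue,
                    target_mask=target,
                    mfi_expected=mfi,
                )
            )
    return records


# ---------------------------------------------------------------------------
# on-disk formats
# ---------------------------------------------------------------------------

def write_matrix_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_labels_csv(labels: pd.Series, path) -> None:
    labels.rename("class").to_frame().to_csv(path, index_label="sample_id")


def read_labels_csv(path) -> pd.Series:
    return pd.read_csv(path, index_col="sample_id")["class"]


def write_compendium(sim: SimulatedCompendium, outdir) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix_tsv(sim.expression.values, outdir / "expression.tsv")
    write_matrix_tsv(sim.copy_number.values, outdir / "copy_number.tsv")
    write_labels_csv(sim.class_labels, outdir / "labels.csv")
    manifest = {
        "expression": "expression.tsv",
        "copy_number": "copy_number.tsv",
        "labels": "labels.csv",
        "spiked_genes": sim.spiked_genes,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def write_biopsy_set(records: list[BiopsyRecord], outdir, seed: int | None = None) -> dict:
    """16-bit fluorescence TIFFs, 8-bit (0/255) mask TIFFs, and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in records:
        stem = rec.biopsy_id
        tifffile.imwrite(
            outdir / f"{stem}_fluor.tif",
            np.clip(np.rint(rec.fluorescence), 0, 65535).astype(np.uint16),
        )
        tifffile.imwrite(
            outdir / f"{stem}_tissue.tif", (rec.tissue_mask * 255).astype(np.uint8)
        )
        tifffile.imwrite(
            outdir / f"{stem}_target.tif", (rec.target_mask * 255).astype(np.uint8)
        )
        entries.append(
            {
                "biopsy_id": rec.biopsy_id,
                "patient_id": rec.patient_id,
                "label": rec.label,
                "fluorescence": f"{stem}_fluor.tif",
                "tissue_mask": f"{stem}_tissue.tif",
                "target_mask": f"{stem}_target.tif",
            }
        )
    manifest = {"seed": seed, "biopsies": entries}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
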