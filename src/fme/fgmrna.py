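"""Functional-genomic mRNA (FGmRNA) style confounder correction.

Bulk expression of tumor vs. normal tissue mixes the downstream effect of
somatic copy-number alterations (SCNAs) with non-genetic transcriptional
components (physiology, metabolism, batch).  The correction scheme here
re-creates, at the scale of the input matrix itself, the published three-step
contract:

1. decompose the gene-centered expression matrix into principal components;
2. flag each component as *genetic* or *non-genetic* by correlating its gene
   loadings with the per-gene mean tumor copy-number offset;
3. regress every gene on the non-genetic component scores and keep the
   residuals ("FGmRNA profiles"), which retain SCNA-driven class signal while
   shedding shared non-genetic variation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

TUMOR = "tumor"
NORMAL = "normal"


def _check_labels(labels: pd.Series, sample_ids) -> pd.Series:
    labels = pd.Series(labels)
    missing = [s for s in sample_ids if s not in labels.index]
    if missing:
        raise ValueError(f"class labels missing for samples: {missing[:5]}")
    bad = set(labels.unique()) - {TUMOR, NORMAL}
    if bad:
        raise ValueError(f"class labels must be 'tumor'/'normal', got {sorted(bad)}")
    return labels.reindex(sample_ids)


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values (log scale) with optional class labels."""

    values: pd.DataFrame
    class_labels: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("gene ids must be unique")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression matrix contains non-finite values")
        if self.class_labels is not None:
            self.class_labels = _check_labels(self.class_labels, self.values.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def centered(self) -> pd.DataFrame:
        """Row-centered values (per-gene mean removed across samples)."""
        return self.values.sub(self.values.mean(axis=1), axis=0)


@dataclass
class CopyNumberMatrix:
    """Gene x sample copy-number estimates, 0-centered (0 = diploid baseline)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("gene ids must be unique")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("copy-number matrix contains non-finite values")


@dataclass
class ComponentSet:
    """Principal components of an expression compendium.

    ``scores`` are sample x k with unit variance per component; ``loadings``
    are gene x k, scaled so loadings @ scores.T reconstructs the centered
    matrix.  Components are ordered by decreasing variance explained.
    ``genetic_flag`` starts all-True and is assigned by :func:`flag_nongenetic`.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_explained: np.ndarray
    genetic_flag: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.genetic_flag is None:
            self.genetic_flag = np.ones(self.scores.shape[1], dtype=bool)

    @property
    def k(self) -> int:
        return self.scores.shape[1]

    def nongenetic_scores(self) -> pd.DataFrame:
        return self.scores.loc[:, ~self.genetic_flag]


@dataclass
class FGmRNAProfileMatrix:
    """Residual expression after removing non-genetic components."""

    values: pd.DataFrame
    k_used: int
    components_removed: list[str]
    class_labels: pd.Series | None = None


def default_k(n_samples: int) -> int:
    return min(n_samples - 1, 50)


def estimate_components(expr: ExpressionMatrix, k: int) -> ComponentSet:
    """Top-k principal components of the gene-centered expression matrix.

    Raises ``ValueError`` when k is not below ``min(n_genes, n_samples)``.
    """
    n_genes, n_samples = expr.values.shape
    bound = min(n_genes, n_samples)
    if not 1 <= k < bound:
        raise ValueError(f"k must satisfy 1 <= k < min(n_genes, n_samples) = {bound}")
    x = expr.centered().to_numpy()
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    total = float((s**2).sum())
    if total == 0.0:
        raise ValueError("expression matrix is constant per gene; no components")
    var_explained = s[:k] ** 2 / total
    # scores with unit sample variance; loadings absorb the singular values
    scale = np.sqrt(n_samples - 1)
    scores = vt[:k].T * scale
    loadings = u[:, :k] * (s[:k] / scale)
    names = [f"PC{i + 1}" for i in range(k)]
    return ComponentSet(
        scores=pd.DataFrame(scores, index=expr.values.columns, columns=names),
        loadings=pd.DataFrame(loadings, index=expr.values.index, columns=names),
        variance_explained=var_explained,
    )


def flag_nongenetic(
    comp: ComponentSet,
    cna: CopyNumberMatrix,
    class_labels: pd.Series | None = None,
    alpha: float = 0.01,
) -> ComponentSet:
    """Flag components whose loadings do not correlate with SCNA dosage.

    The per-gene SCNA summary is the mean copy-number offset over tumor
    samples (over all samples when no labels are given).  A component whose
    Pearson correlation with that summary has p >= ``alpha`` is considered
    non-genetic.  Nothing is removed here; only the flags change.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    genes = comp.loadings.index
    common = genes.intersection(cna.values.index)
    if len(common) < len(genes):
        logger.warning(
            "copy-number matrix misses %d of %d genes; flagging on the intersection",
            len(genes) - len(common), len(genes),
        )
    if len(common) < 3:
        raise ValueError("need at least 3 shared genes to correlate loadings with SCNAs")
    cna_vals = cna.values.loc[common]
    if class_labels is not None:
        labels = _check_labels(class_labels, cna_vals.columns)
        tumor_cols = labels[labels == TUMOR].index
        offset = cna_vals[tumor_cols].mean(axis=1) if len(tumor_cols) else cna_vals.mean(axis=1)
    else:
        offset = cna_vals.mean(axis=1)
    offset_arr = offset.to_numpy()
    flags = np.zeros(comp.k, dtype=bool)
    if np.std(offset_arr) == 0:
        logger.warning("copy-number offset is constant; all components flagged non-genetic")
        return replace(comp, genetic_flag=flags)
    loadings = comp.loadings.loc[common]
    for j in range(comp.k):
        lo = loadings.iloc[:, j].to_numpy()
        if np.std(lo) == 0:
            continue  # degenerate component: non-genetic
        _, p = stats.pearsonr(lo, offset_arr)
        flags[j] = p < alpha
    return replace(comp, genetic_flag=flags)


def residualize(expr: ExpressionMatrix, comp: ComponentSet) -> FGmRNAProfileMatrix:
    """Regress each gene on the non-genetic component scores; keep residuals.

    With no non-genetic components the row-centered expression is returned
    unchanged (logged).  Residuals are orthogonal to every removed score
    vector by construction of the least-squares fit.
    """
    if list(comp.scores.index) != list(expr.values.columns):
        raise ValueError("component scores and expression matrix cover different samples")
    xc = expr.centered()
    removed = [c for c, g in zip(comp.scores.columns, comp.genetic_flag) if not g]
    if not removed:
        logger.info("no non-genetic components; returning centered expression unchanged")
        return FGmRNAProfileMatrix(
            values=xc, k_used=comp.k, components_removed=[],
            class_labels=expr.class_labels,
        )
    s = comp.scores[removed].to_numpy()  # samples x m
    beta, *_ = np.linalg.lstsq(s, xc.to_numpy().T, rcond=None)
    resid = xc.to_numpy() - (s @ beta).T
    return FGmRNAProfileMatrix(
        values=pd.DataFrame(resid, index=xc.index, columns=xc.columns),
        k_used=comp.k,
        components_removed=removed,
        class_labels=expr.class_labels,
    )


def correct(
    expr: ExpressionMatrix,
    cna: CopyNumberMatrix,
    k: int | None = None,
    alpha: float = 0.01,
) -> tuple[FGmRNAProfileMatrix, ComponentSet]:
    """Full pipeline: estimate components, flag, residualize."""
    if k is None:
        k = default_k(len(expr.sample_ids))
    comp = estimate_components(expr, k)
    comp = flag_nongenetic(comp, cna, class_labels=expr.class_labels, alpha=alpha)
    return residualize(expr, comp), comp
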