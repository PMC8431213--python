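"""Immunohistochemistry H-score analytics.

The H-score summarizes staining of epithelial cells scored on a 0-3
intensity scale:

    H = 100 * (1 * frac_weak + 2 * frac_moderate + 3 * frac_strong)

on a 0-300 scale (fractions of cells staining weakly/moderately/strongly;
the remainder is unstained).  Scores fall into three bands: negative/low
(0-100], intermediate (100-200], high (200-300]; the integer band edges are
generalized to real scores as closed at the upper edge.  Group comparison
uses the Kruskal-Wallis test (kept even for two groups), significant at
p < 0.01.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

NEGATIVE_LOW = "negative/low"
INTERMEDIATE = "intermediate"
HIGH = "high"
CATEGORIES = [NEGATIVE_LOW, INTERMEDIATE, HIGH]

#: (lower-exclusive, upper-inclusive) H-score band per category; 0 belongs
#: to negative/low.
CATEGORY_BANDS = {
    NEGATIVE_LOW: (0.0, 100.0),
    INTERMEDIATE: (100.0, 200.0),
    HIGH: (200.0, 300.0),
}

ALPHA = 0.01  # significance threshold for H-score group comparisons

_SUM_TOL = 1e-9


def h_score(frac_weak: float, frac_moderate: float, frac_strong: float) -> float:
    """H-score on the 0-300 scale from staining-intensity cell fractions."""
    w, m, s = float(frac_weak), float(frac_moderate), float(frac_strong)
    for name, f in (("frac_weak", w), ("frac_moderate", m), ("frac_strong", s)):
        if not 0 <= f <= 1:
            raise ValueError(f"{name}={f} outside [0, 1]")
    if w + m + s > 1 + _SUM_TOL:
        raise ValueError(f"staining fractions sum to {w + m + s} > 1")
    return 100.0 * (w + 2.0 * m + 3.0 * s)


def categorize(h: float) -> str:
    """Band of an H-score: negative/low (<=100), intermediate (<=200), high."""
    if not 0 <= h <= 300:
        raise ValueError(f"H-score {h} outside [0, 300]")
    if h <= 100:
        return NEGATIVE_LOW
    if h <= 200:
        return INTERMEDIATE
    return HIGH


def compare_groups(scores_by_group) -> tuple[float, float]:
    """Kruskal-Wallis H (midranks, tie-corrected) and chi-square p-value.

    ``scores_by_group``: mapping group -> score array, or a sequence of
    arrays.  All-identical values give (H=0, p=1) by convention.
    """
    if hasattr(scores_by_group, "values") and not isinstance(scores_by_group, pd.DataFrame):
        groups = [np.asarray(v, dtype=float) for v in scores_by_group.values()]
    else:
        groups = [np.asarray(v, dtype=float) for v in scores_by_group]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if g.size < 2:
            raise ValueError("each group needs at least 2 samples")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def cohort_scores(cohort: pd.DataFrame) -> pd.DataFrame:
    """Attach h_score and category columns derived from the fractions."""
    out = cohort.copy()
    out["h_score"] = [
        h_score(r.frac_weak, r.frac_moderate, r.frac_strong)
        for r in cohort.itertuples()
    ]
    out["category"] = out["h_score"].map(categorize)
    return out


def category_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Counts and within-group proportions per group x category.

    Expects columns ``group`` and ``category``.  Proportions are exact
    fractions; rounding happens only at presentation.
    """
    if samples.empty:
        return pd.DataFrame(columns=["group", "category", "count", "proportion"])
    counts = (
        samples.groupby(["group", "category"], observed=False)
        .size()
        .rename("count")
        .reset_index()
    )
    # include zero cells so proportions are over the full category set
    full = pd.MultiIndex.from_product(
        [sorted(samples["group"].unique()), CATEGORIES], names=["group", "category"]
    )
    counts = (
        counts.set_index(["group", "category"])
        .reindex(full, fill_value=0)
        .reset_index()
    )
    totals = counts.groupby("group")["count"].transform("sum")
    counts["proportion"] = counts["count"] / totals
    return counts


def analyze_cohort(cohort: pd.DataFrame) -> dict:
    """Full IHC summary: H-scores, category table, Kruskal-Wallis test."""
    scored = cohort_scores(cohort) if "h_score" not in cohort.columns else cohort
    by_group = {
        g: sub["h_score"].to_numpy() for g, sub in scored.groupby("group")
    }
    h, p = compare_groups(by_group)
    table = category_table(scored)
    return {
        "n_samples": int(len(scored)),
        "groups": {g: int(v.size) for g, v in by_group.items()},
        "median_h_score": {g: float(np.median(v)) for g, v in by_group.items()},
        "kruskal_wallis": {"H": h, "p": p, "significant": bool(p < ALPHA)},
        "category_table": table.to_dict(orient="records"),
    }
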