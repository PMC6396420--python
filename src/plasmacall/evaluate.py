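"""Evaluation of fetal genotype calls against known truth.

Per inheritance category we report accuracy (called genotype equals truth) and
a ROC-AUC.  Where a single parent is heterozygous the fetal call reduces to a
binary het-vs-homozygous outcome (baseline accuracy 0.5); at double-het sites
all three genotypes are possible (baseline 1/3) and the binary ROC outcome is
het vs homozygous-either.  In all categories the heterozygous posterior q01
serves as the ranking score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .bayes import PosteriorResult
from .sites import CALLING_CATEGORIES, VariantSite


@dataclass
class CategoryMetrics:
    category: str
    n_sites: int
    accuracy: float | None
    auc: float | None


def apply_call_filters(
    results: list[PosteriorResult],
    min_depth: int | None = None,
    max_depth: int | None = None,
    min_pp: float | None = None,
) -> list[PosteriorResult]:
    """Post-hoc depth / posterior-probability filters (never inside the caller)."""
    kept = results
    if min_depth is not None:
        kept = [r for r in kept if r.n_obs >= min_depth]
    if max_depth is not None:
        kept = [r for r in kept if r.n_obs <= max_depth]
    if min_pp is not None:
        kept = [r for r in kept if r.max_posterior > min_pp]
    return kept


def evaluate(
    results: list[PosteriorResult],
    sites: list[VariantSite],
    truth: dict[str, int],
    min_depth: int | None = None,
    max_depth: int | None = None,
    min_pp: float | None = None,
) -> pd.DataFrame:
    """Per-category accuracy and ROC-AUC of calls against true fetal genotypes.

    ``truth`` maps site_id to the true fetal genotype (0/1/2 alt alleles) and
    must cover every evaluated site.  Returns a tidy frame with one row per
    calling category (maternal-only het, paternal-only het, double het).
    """
    site_by_id = {s.site_id: s for s in sites}
    results = apply_call_filters(results, min_depth, max_depth, min_pp)
    rows = []
    by_cat: dict[str, list[PosteriorResult]] = {c.value: [] for c in CALLING_CATEGORIES}
    for r in results:
        site = site_by_id.get(r.site_id)
        if site is None or site.category.value not in by_cat:
            continue
        if r.site_id not in truth:
            raise KeyError(f"truth table does not cover evaluated site {r.site_id}")
        by_cat[site.category.value].append(r)
    for cat, cat_results in by_cat.items():
        n = len(cat_results)
        if n == 0:
            rows.append(CategoryMetrics(cat, 0, None, None))
            continue
        true_g = np.array([truth[r.site_id] for r in cat_results])
        called = np.array([r.called for r in cat_results])
        accuracy = float(np.mean(called == true_g))
        labels = (true_g == 1).astype(int)  # het vs homozygous (either)
        scores = np.array([r.posteriors[1] for r in cat_results])
        auc = float(roc_auc_score(labels, scores)) if len(np.unique(labels)) == 2 else None
        rows.append(CategoryMetrics(cat, n, accuracy, auc))
    return pd.DataFrame([vars(m) for m in rows])


def summarize(metrics: pd.DataFrame) -> str:
    """Human-readable per-category summary table."""
    lines = [f"{'category':<22}{'n':>8}  {'accuracy':>9}  {'auc':>7}"]
    for _, row in metrics.iterrows():
        acc = f"{row.accuracy:.4f}" if row.accuracy is not None and not pd.isna(row.accuracy) else "-"
        auc = f"{row.auc:.4f}" if row.auc is not None and not pd.isna(row.auc) else "-"
        lines.append(f"{row.category:<22}{row.n_sites:>8}  {acc:>9}  {auc:>7}")
    total = int(metrics.n_sites.sum())
    lines.append(f"{'TOTAL':<22}{total:>8}")
    return "\n".join(lines)
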