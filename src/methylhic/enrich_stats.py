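"""Threshold filters for differential tables, Fisher/BH functional
enrichment, and the small validation statistics (2^-ddCT, Pearson r).

Two filtering conventions coexist, mirroring common omics practice:
transcript-level calls use the adjusted p-value (FDR <= 0.05) with a
2.0-fold change, protein-level calls use the raw p-value (< 0.05) with a
1.2-fold change.  Category enrichment is a two-sided Fisher exact test per
category with Benjamini-Hochberg correction across categories.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GenomeAnnotation

__all__ = [
    "EnrichmentRow",
    "filter_differential",
    "fisher_two_sided",
    "bh_adjust",
    "category_enrichment",
    "ddct",
    "pearson_r",
]

_REQUIRED_COLUMNS = ("id", "log2fc", "p", "padj")


@dataclass(frozen=True)
class EnrichmentRow:
    """2x2 enrichment result for one category.

    k = DE genes in category, K = category size, n = DE total,
    N = background size.
    """

    category: str
    k: int
    K: int
    n: int
    N: int
    odds_ratio: float
    p: float
    q: float

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def filter_differential(
    table: pd.DataFrame, fc_threshold: float, use: str = "padj"
) -> tuple[list[str], list[str]]:
    """Split a differential table into up- and down-regulated id lists.

    ``use="padj"`` applies padj <= 0.05 (the FDR rule for transcripts);
    ``use="p"`` applies raw p < 0.05 (the rule for proteins).  A row is up
    iff log2fc >= log2(fc_threshold) and the significance criterion holds;
    down is symmetric.
    """
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must be > 1")
    missing = [c for c in _REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"differential table missing columns {missing}")
    if use == "padj":
        sig = table["padj"] <= 0.05
    elif use == "p":
        sig = table["p"] < 0.05
    else:
        raise ValueError(f"use must be 'padj' or 'p', got {use!r}")
    lfc = math.log2(fc_threshold)
    up = table.loc[sig & (table["log2fc"] >= lfc), "id"].tolist()
    down = table.loc[sig & (table["log2fc"] <= -lfc), "id"].tolist()
    return up, down


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Probability-mass rule: sum hypergeometric probabilities of all tables
    with the same margins whose probability does not exceed the observed
    one (with a small relative slack for float ties).
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("table entries must be nonnegative integers")
    if a + b + c + d == 0:
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def category_enrichment(
    de_ids, annotation: GenomeAnnotation, key: str = "cog"
) -> list[EnrichmentRow]:
    """Fisher/BH enrichment of DE genes across functional categories.

    Background = all genes in the annotation.  Per category the 2x2 table is
    (k, n-k, K-k, N-K-n+k); p from the two-sided Fisher exact test, q by
    Benjamini-Hochberg across the tested categories.  The odds ratio is the
    sample cross-product ratio (inf when the off-diagonal is empty).
    """
    if key not in ("ko", "cog"):
        raise ValueError(f"key must be 'ko' or 'cog', got {key!r}")
    all_ids = {g.gene_id for g in annotation.genes}
    if not all_ids:
        raise ValueError("empty background annotation")
    de_set = set(de_ids)
    stray = de_set - all_ids
    if stray:
        raise ValueError(f"DE ids not in background: {sorted(stray)[:5]} ...")
    tag_of = {
        g.gene_id: (g.ko_id if key == "ko" else g.cog_letter) for g in annotation.genes
    }
    categories = sorted({t for t in tag_of.values() if t is not None})
    n_untagged = sum(1 for t in tag_of.values() if t is None)
    if n_untagged:
        warnings.warn(f"{n_untagged} genes without a {key!r} tag excluded from categories")
    N = len(all_ids)
    n = len(de_set)
    rows = []
    for cat in categories:
        members = {gid for gid, t in tag_of.items() if t == cat}
        K = len(members)
        k = len(de_set & members)
        table = (k, n - k, K - k, N - K - n + k)
        p = fisher_two_sided(*table)
        if (n - k) * (K - k) > 0:
            odds = (k * (N - K - n + k)) / ((n - k) * (K - k))
        elif k * (N - K - n + k) > 0:
            odds = float("inf")
        else:
            odds = float("nan")
        rows.append((cat, k, K, n, N, odds, p))
    qvals = bh_adjust([r[6] for r in rows])
    return [
        EnrichmentRow(category=cat, k=k, K=K, n=n_, N=N_, odds_ratio=odds, p=p, q=float(q))
        for (cat, k, K, n_, N_, odds, p), q in zip(rows, qvals)
    ]


def ddct(
    ct_target_test: float,
    ct_ref_test: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression by the comparative threshold-cycle method.

    2^-[(CT_target,test - CT_ref,test) - (CT_target,ctrl - CT_ref,ctrl)].
    """
    for ct in (ct_target_test, ct_ref_test, ct_target_ctrl, ct_ref_ctrl):
        if ct <= 0:
            raise ValueError("CT values must be positive")
    ddct_value = (ct_target_test - ct_ref_test) - (ct_target_ctrl - ct_ref_ctrl)
    return 2.0 ** (-ddct_value)


def pearson_r(x, y) -> float:
    """Sample Pearson correlation of two equal-length vectors (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    return float(stats.pearsonr(x, y)[0])
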