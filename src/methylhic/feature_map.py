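"""Map methylated sites and motif occurrences onto the CDS/intergenic
partition and onto functional categories (COG letters, KO ids).

The central objects are degenerate IUPAC motifs (palindromic pairs written
"forward/reverse", e.g. ``GCCAT/ATGGC``) and per-base 6mA calls.  Occurrence
scanning reports all overlapping matches on both strands; a motif whose
reverse complement equals itself is reported once per dyad, matching the
one-count-per-motif convention of methylome summary tables.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GenomeAnnotation, Interval, MethylationCall

__all__ = [
    "IUPAC_CODES",
    "IupacMotif",
    "SiteClassification",
    "DensityRow",
    "iupac_revcomp",
    "find_motif_occurrences",
    "classify_sites",
    "methylation_density",
    "density_by_category",
    "motif_methylation_summary",
]

IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_IUPAC_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def iupac_revcomp(motif: str) -> str:
    """Reverse complement of a degenerate IUPAC string."""
    try:
        return "".join(_IUPAC_COMPLEMENT[c] for c in reversed(motif))
    except KeyError as exc:
        raise ValueError(f"illegal IUPAC character {exc.args[0]!r} in {motif!r}") from exc


@dataclass(frozen=True)
class IupacMotif:
    """A degenerate methylation motif, optionally with its reverse partner.

    ``methylated_offset`` is the 0-based index of the methylated adenine
    within ``forward``; for palindromic pairs the partner adenine on the
    opposite strand is implied by reverse complementation.
    """

    forward: str
    reverse: str | None = None
    methylated_offset: int | None = None
    motif_id: str | None = None

    def __post_init__(self) -> None:
        if not self.forward:
            raise ValueError("empty motif")
        for c in self.forward:
            if c not in IUPAC_CODES:
                raise ValueError(f"illegal IUPAC character {c!r} in {self.forward!r}")
        if self.reverse is not None and self.reverse != iupac_revcomp(self.forward):
            raise ValueError(
                f"reverse partner {self.reverse!r} is not the IUPAC reverse "
                f"complement of {self.forward!r}"
            )
        if self.methylated_offset is not None:
            if not 0 <= self.methylated_offset < len(self.forward):
                raise ValueError("methylated_offset outside motif")
            if "A" not in IUPAC_CODES[self.forward[self.methylated_offset]]:
                raise ValueError("methylated_offset does not address an adenine-compatible base")

    @classmethod
    def from_string(cls, text: str, methylated_offset: int | None = None,
                    motif_id: str | None = None) -> "IupacMotif":
        """Parse ``"GCCAT"`` or the dyad form ``"GCCAT/ATGGC"``."""
        if "/" in text:
            fwd, rev = text.split("/", 1)
            return cls(fwd, rev, methylated_offset, motif_id)
        return cls(text, None, methylated_offset, motif_id)

    def __len__(self) -> int:
        return len(self.forward)

    @property
    def is_self_revcomp(self) -> bool:
        return iupac_revcomp(self.forward) == self.forward


def _iupac_regex(motif: str) -> re.Pattern:
    body = "".join(
        c if len(IUPAC_CODES[c]) == 1 else "[" + IUPAC_CODES[c] + "]" for c in motif
    )
    # lookahead so overlapping matches are all reported
    return re.compile(f"(?=({body}))")


def find_motif_occurrences(
    seq: str, motif: IupacMotif | str
) -> list[tuple[Interval, str]]:
    """All occurrences of a degenerate motif in ``seq``, both strands.

    Plus-strand matches of ``forward`` are reported with strand '+', matches
    of its reverse complement with strand '-'.  Overlapping matches are all
    reported, ordered by start (then '+' before '-').  For motifs that are
    their own reverse complement the two scans would duplicate every dyad,
    so only the '+' scan is reported.
    """
    if isinstance(motif, str):
        motif = IupacMotif.from_string(motif)
    k = len(motif)
    if k > len(seq):
        return []
    hits: list[tuple[Interval, str]] = []
    for m in _iupac_regex(motif.forward).finditer(seq):
        hits.append((Interval(m.start(), m.start() + k, "+"), "+"))
    if not motif.is_self_revcomp:
        for m in _iupac_regex(iupac_revcomp(motif.forward)).finditer(seq):
            hits.append((Interval(m.start(), m.start() + k, "-"), "-"))
    hits.sort(key=lambda h: (h[0].start, 0 if h[1] == "+" else 1))
    return hits


@dataclass
class SiteClassification:
    """Counts of calls inside vs outside CDS, plus per-gene counts.

    ``n_cds + n_ig`` always equals the number of classified calls; a call
    inside two overlapping genes is counted once at class level but once per
    gene in ``per_gene``.
    """

    n_cds: int
    n_ig: int
    per_gene: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return self.n_cds + self.n_ig


def classify_sites(
    calls: list[MethylationCall], annotation: GenomeAnnotation
) -> SiteClassification:
    """Partition calls into CDS vs intergenic by position (strand-agnostic)."""
    positions = np.array([c.position for c in calls], dtype=np.int64)
    if positions.size and (positions.max() >= annotation.genome_length):
        raise ValueError("call position beyond genome length")
    merged = annotation.merged_cds_intervals()
    starts = np.array([iv.start for iv in merged], dtype=np.int64)
    ends = np.array([iv.end for iv in merged], dtype=np.int64)
    if positions.size and starts.size:
        idx = np.searchsorted(starts, positions, side="right") - 1
        in_cds = (idx >= 0) & (positions < ends[np.clip(idx, 0, None)])
        n_cds = int(in_cds.sum())
    else:
        n_cds = 0
    per_gene: dict[str, int] = {}
    if positions.size:
        sorted_pos = np.sort(positions)
        for g in annotation.genes:
            lo = np.searchsorted(sorted_pos, g.interval.start, side="left")
            hi = np.searchsorted(sorted_pos, g.interval.end, side="left")
            per_gene[g.gene_id] = int(hi - lo)
    else:
        per_gene = {g.gene_id: 0 for g in annotation.genes}
    return SiteClassification(n_cds=n_cds, n_ig=len(calls) - n_cds, per_gene=per_gene)


@dataclass(frozen=True)
class DensityRow:
    """Methylation density of a unit (gene, class, or category group)."""

    unit_id: str
    site_count: int
    length_bp: int

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"unit {self.unit_id!r} has non-positive length")
        if self.site_count < 0:
            raise ValueError("negative site count")

    @property
    def density_per_kb(self) -> float:
        return 1000.0 * self.site_count / self.length_bp


def methylation_density(
    calls: list[MethylationCall], intervals: list[Interval], unit_id: str = "region"
) -> DensityRow:
    """Sites per kb over a set of non-overlapping intervals."""
    ivs = sorted(intervals, key=lambda iv: iv.start)
    for a, b in zip(ivs, ivs[1:]):
        if b.start < a.end:
            raise ValueError("intervals overlap")
    total_len = sum(iv.length for iv in ivs)
    if total_len == 0:
        raise ValueError("zero total interval length")
    starts = np.array([iv.start for iv in ivs], dtype=np.int64)
    ends = np.array([iv.end for iv in ivs], dtype=np.int64)
    positions = np.array([c.position for c in calls], dtype=np.int64)
    if positions.size:
        idx = np.searchsorted(starts, positions, side="right") - 1
        inside = (idx >= 0) & (positions < ends[np.clip(idx, 0, None)])
        count = int(inside.sum())
    else:
        count = 0
    return DensityRow(unit_id=unit_id, site_count=count, length_bp=total_len)


def density_by_category(
    calls: list[MethylationCall],
    annotation: GenomeAnnotation,
    key: str = "ko",
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Per-gene methylation densities grouped by KO or COG category.

    Returns ``(gene_table, group_summary, n_untagged)``.  ``group_summary``
    reports the median per-gene density per category, sorted descending, the
    convention used when ranking carbohydrate-metabolism KO groups by
    methylation density.  Genes without the requested tag are skipped and
    counted in ``n_untagged``; genes with zero sites contribute density 0.
    """
    if key not in ("ko", "cog"):
        raise ValueError(f"key must be 'ko' or 'cog', got {key!r}")
    classification = classify_sites(calls, annotation)
    rows = []
    n_untagged = 0
    for g in annotation.genes:
        tag = g.ko_id if key == "ko" else g.cog_letter
        if tag is None:
            n_untagged += 1
            continue
        count = classification.per_gene.get(g.gene_id, 0)
        rows.append(
            {
                "category": tag,
                "gene_id": g.gene_id,
                "site_count": count,
                "length_bp": g.interval.length,
                "density_per_kb": 1000.0 * count / g.interval.length,
            }
        )
    gene_table = pd.DataFrame(
        rows, columns=["category", "gene_id", "site_count", "length_bp", "density_per_kb"]
    )
    if gene_table.empty:
        raise ValueError(f"no gene carries a {key!r} tag")
    summary = (
        gene_table.groupby("category")["density_per_kb"]
        .agg(median_density="median", n_genes="size")
        .reset_index()
        .sort_values("median_density", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )
    return gene_table, summary, n_untagged


def motif_methylation_summary(n_methylated: int, n_total: int) -> float:
    """Percent of motif occurrences called methylated, to 2 decimals.

    This is the "proportion of methylated motifs (%)" column of a methylome
    summary table: 100 * n_methylated / n_total.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_methylated <= n_total:
        raise ValueError("need 0 <= n_methylated <= n_total")
    return round(100.0 * n_methylated / n_total, 2)
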