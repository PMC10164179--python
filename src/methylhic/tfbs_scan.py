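"""PWM construction, upstream-region extraction, exhaustive PWM scanning
with exact p-values, and intersection of hits with methylation calls.

Scores are log2 odds against an order-0 background.  The p-value of a score
is exact under the background model: the null score distribution is computed
by dynamic programming over integer-quantized column scores (quantization
step 1/1000 bit), the same construction used by standard motif-scanning
tools, so p-values for all offsets of a scan are available at once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .enrich_stats import bh_adjust
from .io_formats import GenomeAnnotation, Interval, MethylationCall, SequenceRecord

__all__ = [
    "PWM",
    "UpstreamRegion",
    "TfbsHit",
    "build_pwm",
    "extract_upstream",
    "scan_pwm",
    "qualify_hits",
    "methylation_overlap",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

QUANT_STEP = 1e-3  # bits; integer quantization step of the score DP


def _revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


@dataclass(frozen=True)
class PWM:
    """Position probability matrix with its background distribution.

    ``probs`` has shape (w, 4) over A,C,G,T; each row sums to 1.
    """

    probs: np.ndarray
    background: np.ndarray
    pseudocount: float

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def score_matrix(self) -> np.ndarray:
        """Per-position log2-odds scores, shape (w, 4); -inf where p = 0."""
        with np.errstate(divide="ignore"):
            return np.log2(self.probs) - np.log2(self.background)[None, :]

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in np.argmax(self.probs, axis=1))

    def information_content(self) -> float:
        """Total information content in bits relative to the background."""
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = self.probs * (np.log2(self.probs) - np.log2(self.background)[None, :])
        return float(np.nansum(terms))


def build_pwm(
    site_seqs: list[str],
    pseudocount: float = 0.1,
    background: np.ndarray | tuple[float, ...] | None = None,
) -> PWM:
    """PWM from aligned binding-site sequences.

    Column probability of base b is (count(b) + pseudocount*background(b))
    / (n_sites + pseudocount).
    """
    if not site_seqs:
        raise ValueError("no site sequences")
    w = len(site_seqs[0])
    if w < 4:
        raise ValueError("sites must be at least 4 bp")
    if any(len(s) != w for s in site_seqs):
        raise ValueError("site sequences have unequal lengths")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    if bg.shape != (4,) or abs(bg.sum() - 1.0) > 1e-9:
        raise ValueError("background must be 4 probabilities summing to 1")
    counts = np.zeros((w, 4), dtype=float)
    for s in site_seqs:
        for j, c in enumerate(s.upper()):
            if c not in _BASE_INDEX:
                raise ValueError(f"illegal base {c!r} in site sequence")
            counts[j, _BASE_INDEX[c]] += 1.0
    probs = (counts + pseudocount * bg[None, :]) / (len(site_seqs) + pseudocount)
    return PWM(probs=probs, background=bg, pseudocount=pseudocount)


@dataclass(frozen=True)
class UpstreamRegion:
    """An extracted upstream region in gene orientation.

    ``seq`` reads 5'->3' on the gene's coding strand; ``interval`` is the
    genomic span the sequence was cut from.
    """

    gene_id: str
    seq: str
    interval: Interval
    gene_strand: str


def extract_upstream(
    annotation: GenomeAnnotation,
    genome: SequenceRecord,
    min_len: int = 50,
    max_len: int = 300,
) -> tuple[list[UpstreamRegion], int]:
    """Upstream regions of 50-300 bp (defaults) for every gene.

    For a + gene the region is the up-to-``max_len`` bp ending at the gene
    start, truncated at the nearest upstream feature end; for a - gene the
    mirrored downstream-in-coordinates stretch, reverse-complemented.
    Regions shorter than ``min_len`` are dropped; the count of dropped
    regions is returned alongside.
    """
    merged = annotation.merged_cds_intervals()
    ends = np.array([iv.end for iv in merged], dtype=np.int64)
    starts = np.array([iv.start for iv in merged], dtype=np.int64)
    regions: list[UpstreamRegion] = []
    n_dropped = 0
    for g in annotation.genes:
        iv = g.interval
        if iv.strand == "-":
            # upstream lies after the gene in genome coordinates
            idx = np.searchsorted(starts, iv.end, side="left")
            next_start = int(starts[idx]) if idx < len(starts) else annotation.genome_length
            lo = iv.end
            hi = min(next_start, iv.end + max_len)
        else:
            idx = np.searchsorted(ends, iv.start, side="right") - 1
            prev_end = int(ends[idx]) if idx >= 0 else 0
            # a merged interval containing the gene start itself is the
            # gene's own block; step back one
            if idx >= 0 and starts[idx] <= iv.start < ends[idx]:
                prev_end = int(ends[idx - 1]) if idx >= 1 else 0
            lo = max(prev_end, iv.start - max_len)
            hi = iv.start
        if hi - lo < min_len:
            n_dropped += 1
            continue
        seq = genome.seq[lo:hi]
        if iv.strand == "-":
            seq = _revcomp(seq)
        regions.append(
            UpstreamRegion(
                gene_id=g.gene_id,
                seq=seq,
                interval=Interval(lo, hi, iv.strand if iv.strand in "+-" else "+"),
                gene_strand=iv.strand,
            )
        )
    return regions, n_dropped


@dataclass(frozen=True)
class TfbsHit:
    """One PWM hit, in genome coordinates."""

    region_id: str
    interval: Interval
    strand: str
    score: float
    p: float
    q: float | None = None
    methylation_status: str | None = None


def score_distribution(pwm: PWM) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of the integer-quantized PWM score.

    Returns (support, pmf): integer score values (units of QUANT_STEP bits)
    and their probabilities under the background model.  Impossible words
    (zero PWM probability) are collected in a single lowest bucket.
    """
    sm = pwm.score_matrix()
    q = np.where(np.isfinite(sm), np.rint(sm / QUANT_STEP).astype(np.int64), 0)
    # DP over columns: dict int_score -> prob; separate -inf mass
    dist: dict[int, float] = {0: 1.0}
    minus_inf_mass = 0.0
    for j in range(pwm.width):
        new: dict[int, float] = {}
        col_inf_mass = 0.0
        for b in range(4):
            pb = float(pwm.background[b])
            if not np.isfinite(sm[j, b]):
                col_inf_mass += pb
                continue
            step = int(q[j, b])
            for s, prob in dist.items():
                key = s + step
                new[key] = new.get(key, 0.0) + prob * pb
        minus_inf_mass += col_inf_mass * sum(dist.values())
        dist = new
    support = np.array(sorted(dist), dtype=np.int64)
    pmf = np.array([dist[s] for s in support], dtype=float)
    if minus_inf_mass > 0:
        support = np.concatenate(([support.min() - 1 if support.size else -1], support))
        pmf = np.concatenate(([minus_inf_mass], pmf))
    return support, pmf


def _pvalue_lookup(pwm: PWM):
    """Return a function mapping an integer-quantized score to its exact
    upper-tail p (the same per-column quantization as the DP, so lookups
    land exactly on the distribution's support)."""
    support, pmf = score_distribution(pwm)
    tail = np.cumsum(pmf[::-1])[::-1]  # P(S >= support[i])

    def pvalue(qscore: int) -> float:
        idx = np.searchsorted(support, qscore, side="left")
        if idx >= len(support):
            return 0.0
        return float(tail[idx])

    return pvalue


def scan_pwm(region: UpstreamRegion, pwm: PWM) -> tuple[list[TfbsHit], int]:
    """Score every offset of a region on both strands with exact p-values.

    Windows containing a non-ACGT character are skipped; the count of
    skipped windows is returned alongside the hits.  Hit intervals are in
    genome coordinates; the hit strand is reported relative to the genome
    (the region's own orientation is folded in).
    """
    w = pwm.width
    seq = region.seq.upper()
    if len(seq) < w:
        raise ValueError(f"region {region.gene_id} shorter than PWM width {w}")
    sm = pwm.score_matrix()
    qsm = np.where(np.isfinite(sm), np.rint(sm / QUANT_STEP), np.nan)
    pvalue = _pvalue_lookup(pwm)
    hits: list[TfbsHit] = []
    n_skipped = 0
    enc = np.array([_BASE_INDEX.get(c, -1) for c in seq], dtype=np.int64)
    cols = np.arange(w)
    for off in range(len(seq) - w + 1):
        window = enc[off:off + w]
        if (window < 0).any():
            n_skipped += 1
            continue
        for scan_strand in ("+", "-"):
            idx = window if scan_strand == "+" else 3 - window[::-1]
            score = float(sm[cols, idx].sum())
            qscore = qsm[cols, idx].sum()
            if not math.isfinite(score):
                continue
            # map region offset -> genome coordinates
            if region.gene_strand == "-":
                g_start = region.interval.end - off - w
            else:
                g_start = region.interval.start + off
            genome_strand = scan_strand
            if region.gene_strand == "-":
                genome_strand = "-" if scan_strand == "+" else "+"
            hits.append(
                TfbsHit(
                    region_id=region.gene_id,
                    interval=Interval(g_start, g_start + w, genome_strand),
                    strand=genome_strand,
                    score=score,
                    p=pvalue(int(qscore)),
                )
            )
    return hits, n_skipped


def qualify_hits(hits: list[TfbsHit], q_threshold: float = 0.05) -> list[TfbsHit]:
    """BH-adjust p-values across all scanned offsets; keep q <= threshold.

    The adjustment spans every hit passed in (i.e. every offset of the
    analysis), approximating the q-value machinery of standard scanners.
    """
    if not hits:
        return []
    qvals = bh_adjust([h.p for h in hits])
    return [
        replace(h, q=float(q)) for h, q in zip(hits, qvals) if q <= q_threshold
    ]


def methylation_overlap(
    hits: list[TfbsHit], calls: list[MethylationCall]
) -> list[TfbsHit]:
    """Label each hit methylated iff >= 1 call position lies inside it.

    Calls on either strand count; the call must fall within the half-open
    hit interval (flanking calls do not count).
    """
    positions = np.sort(np.array([c.position for c in calls], dtype=np.int64))
    out = []
    for h in hits:
        if positions.size:
            lo = np.searchsorted(positions, h.interval.start, side="left")
            hi = np.searchsorted(positions, h.interval.end, side="left")
            status = "methylated" if hi > lo else "non_methylated"
        else:
            status = "non_methylated"
        out.append(replace(h, methylation_status=status))
    return out
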