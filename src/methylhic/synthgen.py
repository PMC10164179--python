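"""Synthetic-data generator with known ground truth.

Every downstream stage of the pipeline is exercised on data produced here:
a single circular bacterial chromosome with Markov base composition,
planted degenerate-motif occurrences methylated at class-specific rates
(CDS vs intergenic), differential-expression tables with one functional
category planted at elevated odds, and symmetric Hi-C contact matrices with
power-law distance decay, planted self-associating block domains and
planted differential contacts between two conditions.

Defaults emulate the desk-scale study conditions: a 200 kb chromosome at
~46% GC, the GCCAT/ATGGC dyad motif planted at 0.96 / 0.77 occurrences per
kb in CDS / intergenic sequence with 99% of occurrences called methylated
(so methylated-site densities land near 0.95 and 0.76 per kb), 400 Hi-C
bins with contact decay ~ d^-1, four tiling interaction domains at 2x
self-association, and eight 20x differential contacts.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .feature_map import IUPAC_CODES, IupacMotif, iupac_revcomp
from .io_formats import (
    Gene,
    GenomeAnnotation,
    Interval,
    MethylationCall,
    SequenceRecord,
)

__all__ = [
    "SynthConfig",
    "PlantedMotifInstance",
    "TruthTable",
    "gen_genome",
    "gen_annotation",
    "plant_methylation",
    "gen_hic_pair",
    "gen_de_table",
    "generate_all",
]

_BASES = "ACGT"

# COG letters used as the category palette (the letters of the study's
# functional-category figures); 'G' is carbohydrate transport & metabolism.
DEFAULT_PALETTE = tuple("CDEFGHIJKLMOPSTUV")


@dataclass(frozen=True)
class SynthConfig:
    """All knobs of the generator; defaults are the study conditions."""

    seed: int = 0
    genome_length: int = 200_000
    markov_order: int = 0
    # order-0 default: ~46% GC, typical of the study organism
    base_probs: tuple[float, ...] = (0.27, 0.23, 0.23, 0.27)
    transition_probs: tuple | None = None  # 4^m x 4 rows for order m >= 1
    n_genes: int = 120
    gene_length_range: tuple[int, int] = (600, 1400)
    motif: IupacMotif = field(
        default_factory=lambda: IupacMotif.from_string(
            "GCCAT/ATGGC", methylated_offset=3, motif_id="motif_017"
        )
    )
    rate_cds: float = 0.96  # planted occurrences per kb of CDS
    rate_ig: float = 0.77  # planted occurrences per kb of intergenic
    meth_fraction: float = 0.99  # P(planted occurrence is called methylated)
    category_palette: tuple[str, ...] = DEFAULT_PALETTE
    category_probs: tuple[float, ...] | None = None  # None: uniform palette
    # Hi-C
    hic_bins: int = 400
    hic_bin_size: int = 1000
    contact_scale: float = 100.0  # C in mu(i,j) = C * d^-alpha
    decay_exponent: float = 1.0
    cid_blocks: tuple[tuple[int, int, float], ...] = (
        (0, 100, 2.0),
        (100, 200, 2.0),
        (200, 300, 2.0),
        (300, 400, 2.0),
    )
    diff_contacts: tuple[tuple[int, int, float], ...] = (
        (10, 40, 20.0),
        (60, 130, 20.0),
        (150, 190, 20.0),
        (205, 260, 20.0),
        (230, 300, 20.0),
        (280, 330, 20.0),
        (310, 370, 20.0),
        (350, 20, 20.0),
    )
    # test-only boundary near the shared junction at bin 100: differential
    # insulation is detectable where profiles carry shared structure, and a
    # domain split typically appears at the flank of an existing boundary
    boundaries_test: tuple[tuple[int, float, int], ...] = ((110, 0.1, 15),)
    # optional shared short-range texture: locus-specific compaction
    # modulating near-diagonal contacts identically in both conditions
    # (off by default; enables maps with structure along the whole circle)
    texture_amp: float = 0.0
    texture_scale_bins: int = 5
    texture_taper_bins: int = 20
    # differential expression
    de_frac: float = 0.05
    enriched_category: str = "G"
    enrichment_odds: float = 8.0

    def validate(self) -> None:
        if self.markov_order > 5:
            raise ValueError("Markov order > 5 unsupported")
        if self.markov_order < 0:
            raise ValueError("Markov order must be >= 0")
        if min(self.rate_cds, self.rate_ig) < 0:
            raise ValueError("rates must be >= 0")
        if not 0 <= self.meth_fraction <= 1:
            raise ValueError("meth_fraction must be in [0,1]")
        if not 0 <= self.de_frac <= 1:
            raise ValueError("de_frac must be in [0,1]")
        if self.decay_exponent <= 0:
            raise ValueError("decay exponent alpha must be > 0")
        if self.hic_bins < 20:
            raise ValueError("need at least 20 Hi-C bins")
        for s, e, _ in self.cid_blocks:
            if not (0 <= s < e <= self.hic_bins):
                raise ValueError(f"CID block [{s},{e}) outside [0,{self.hic_bins})")
        if abs(sum(self.base_probs) - 1.0) > 1e-9:
            raise ValueError("base_probs must sum to 1")
        if self.category_probs is not None:
            if len(self.category_probs) != len(self.category_palette):
                raise ValueError("category_probs length must match palette")
            if abs(sum(self.category_probs) - 1.0) > 1e-9:
                raise ValueError("category_probs must sum to 1")


@dataclass(frozen=True)
class PlantedMotifInstance:
    """One planted motif occurrence and its methylation status."""

    start: int  # 0-based start of the forward-oriented written word
    strand: str
    region_class: str  # "CDS" or "IG"
    methylated: bool
    call_position: int  # 0-based position of the 6mA adenine
    call_strand: str


@dataclass
class TruthTable:
    """Ground truth for everything the generator planted."""

    motif_instances: list[PlantedMotifInstance] = field(default_factory=list)
    cid_boundaries: list[int] = field(default_factory=list)
    cid_boundaries_test_extra: list[int] = field(default_factory=list)
    diff_contacts: list[tuple[int, int, float]] = field(default_factory=list)
    de_gene_ids: list[str] = field(default_factory=list)
    enriched_category: str | None = None

    def to_dict(self) -> dict:
        return {
            "motif_instances": [
                {
                    "start": m.start,
                    "strand": m.strand,
                    "region_class": m.region_class,
                    "methylated": m.methylated,
                    "call_position": m.call_position,
                    "call_strand": m.call_strand,
                }
                for m in self.motif_instances
            ],
            "cid_boundaries": self.cid_boundaries,
            "cid_boundaries_test_extra": self.cid_boundaries_test_extra,
            "diff_contacts": [list(d) for d in self.diff_contacts],
            "de_gene_ids": self.de_gene_ids,
            "enriched_category": self.enriched_category,
        }


def _rng(config: SynthConfig, stream: str) -> np.random.Generator:
    # zlib.crc32 is a stable hash (unlike hash()), so streams are
    # reproducible across processes and platforms
    key = zlib.crc32(stream.encode()) % (2**31)
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(key,))
    )


def gen_genome(config: SynthConfig) -> SequenceRecord:
    """Markov-sampled circular chromosome sequence (deterministic per seed)."""
    config.validate()
    rng = _rng(config, "genome")
    L = config.genome_length
    m = config.markov_order
    if m == 0:
        idx = rng.choice(4, size=L, p=np.asarray(config.base_probs))
    else:
        trans = np.asarray(config.transition_probs, dtype=float)
        if trans.shape != (4**m, 4):
            raise ValueError(f"transition_probs must have shape ({4 ** m}, 4)")
        idx = np.empty(L, dtype=np.int64)
        idx[:m] = rng.choice(4, size=m, p=np.asarray(config.base_probs))
        ctx = 0
        for j in range(m):
            ctx = ctx * 4 + int(idx[j])
        u = rng.random(L)
        cum = np.cumsum(trans, axis=1)
        mod = 4**m
        for i in range(m, L):
            idx[i] = int(np.searchsorted(cum[ctx], u[i], side="right"))
            ctx = (ctx * 4 + int(idx[i])) % mod
    seq = "".join(_BASES[i] for i in idx)
    return SequenceRecord(id=f"synthetic_chr_seed{config.seed}", seq=seq)


def gen_annotation(config: SynthConfig, genome: SequenceRecord | None = None) -> GenomeAnnotation:
    """Non-overlapping CDS intervals with alternating strands and random gaps.

    Gene lengths are uniform over ``gene_length_range``; the leftover
    genome is split into uniform-random intergenic gaps (multinomial over
    the n_genes+1 gap slots).  Category tags (a COG letter and a synthetic
    KO id derived from it) are assigned round-robin-free, uniformly at
    random from the palette.
    """
    config.validate()
    L = len(genome.seq) if genome is not None else config.genome_length
    rng = _rng(config, "annotation")
    n = config.n_genes
    if n == 0:
        return GenomeAnnotation(genome_length=L, genes=[])
    lo, hi = config.gene_length_range
    if n * hi >= L:
        raise ValueError(
            f"cannot pack {n} genes of length up to {hi} into {L} bp"
        )
    lengths = rng.integers(lo, hi + 1, size=n)
    leftover = L - int(lengths.sum())
    if leftover < 0:
        raise ValueError("gene lengths exceed genome length")
    gaps = rng.multinomial(leftover, np.full(n + 1, 1.0 / (n + 1)))
    genes = []
    cursor = 0
    for i in range(n):
        cursor += int(gaps[i])
        start = cursor
        end = start + int(lengths[i])
        strand = "+" if i % 2 == 0 else "-"
        cog = str(
            rng.choice(
                list(config.category_palette),
                p=None if config.category_probs is None else np.asarray(config.category_probs),
            )
        )
        ko = f"K{ord(cog):05d}"  # synthetic KO id, one per COG letter
        genes.append(
            Gene(
                gene_id=f"gene_{i + 1:04d}",
                interval=Interval(start, end, strand),
                cog_letter=cog,
                ko_id=ko,
            )
        )
        cursor = end
    return GenomeAnnotation(genome_length=L, genes=genes)


def _concretize(rng: np.random.Generator, motif: str) -> str:
    """Resolve degenerate positions to a concrete word, uniformly."""
    out = []
    for c in motif:
        opts = IUPAC_CODES[c]
        out.append(opts if len(opts) == 1 else opts[int(rng.integers(len(opts)))])
    return "".join(out)


def plant_methylation(
    config: SynthConfig,
    genome: SequenceRecord,
    annotation: GenomeAnnotation,
) -> tuple[SequenceRecord, list[MethylationCall], TruthTable]:
    """Write motif instances into the sequence and emit methylation calls.

    Instance counts per class are Poisson with mean rate * class-kb;
    positions are uniform within the class (the whole instance must fit in
    one class interval), re-drawn on collision with a previously planted
    instance.  Each instance is concretized (degenerate positions sampled),
    written on a random strand, and emitted as a methylated call at the
    motif's 6mA adenine with probability ``meth_fraction``.
    """
    config.validate()
    motif = config.motif
    k = len(motif)
    if motif.methylated_offset is None:
        raise ValueError("planting requires motif.methylated_offset")
    rng = _rng(config, "methylation")
    seq = np.frombuffer(genome.seq.encode(), dtype=np.uint8).copy()

    classes = {
        "CDS": annotation.merged_cds_intervals(),
        "IG": annotation.intergenic_intervals(),
    }
    rates = {"CDS": config.rate_cds, "IG": config.rate_ig}
    occupied = np.zeros(len(seq), dtype=bool)
    truth = TruthTable()
    calls: list[MethylationCall] = []

    for cls_name, intervals in classes.items():
        usable = [iv for iv in intervals if iv.length >= k]
        if not usable:
            continue
        lengths = np.array([iv.length - k + 1 for iv in usable], dtype=float)
        total_kb = sum(iv.length for iv in usable) / 1000.0
        n_target = int(rng.poisson(rates[cls_name] * total_kb))
        probs = lengths / lengths.sum()
        placed = 0
        budget = 50 * max(1, n_target)
        while placed < n_target and budget > 0:
            budget -= 1
            iv = usable[int(rng.choice(len(usable), p=probs))]
            start = int(rng.integers(iv.start, iv.end - k + 1))
            if occupied[start:start + k].any():
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            word = _concretize(rng, motif.forward)
            written = word if strand == "+" else _revcomp_concrete(word)
            seq[start:start + k] = np.frombuffer(written.encode(), dtype=np.uint8)
            occupied[start:start + k] = True
            if strand == "+":
                call_pos = start + motif.methylated_offset
                call_strand = "+"
            else:
                call_pos = start + (k - 1 - motif.methylated_offset)
                call_strand = "-"
            methylated = bool(rng.random() < config.meth_fraction)
            truth.motif_instances.append(
                PlantedMotifInstance(
                    start=start,
                    strand=strand,
                    region_class=cls_name,
                    methylated=methylated,
                    call_position=call_pos,
                    call_strand=call_strand,
                )
            )
            if methylated:
                calls.append(
                    MethylationCall(
                        position=call_pos,
                        strand=call_strand,
                        motif_id=motif.motif_id,
                        score=float(rng.integers(30, 200)),
                    )
                )
            placed += 1
        if placed < n_target:
            raise RuntimeError(
                f"could not place {n_target} motif instances in class {cls_name} "
                f"within the retry budget (placed {placed})"
            )
    calls.sort(key=lambda c: c.position)
    truth.motif_instances.sort(key=lambda m: m.start)
    new_genome = SequenceRecord(id=genome.id, seq=seq.tobytes().decode())
    return new_genome, calls, truth


def _revcomp_concrete(word: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[c] for c in reversed(word))


def _circular_distance(n: int) -> np.ndarray:
    """Matrix of circular bin distances d(i,j) on an n-bin circle."""
    idx = np.arange(n)
    diff = np.abs(idx[:, None] - idx[None, :])
    return np.minimum(diff, n - diff)


def expected_contact_matrices(config: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """Expected (Poisson mean) matrices for the reference and test conditions."""
    n = config.hic_bins
    d = _circular_distance(n).astype(float)
    np.fill_diagonal(d, 1.0)
    d[d == 0] = 1.0
    mu = config.contact_scale * d ** (-config.decay_exponent)
    if config.texture_amp > 0:
        rng_tex = _rng(config, "hic_texture")
        white = rng_tex.normal(size=n)
        s_tex = max(1, config.texture_scale_bins)
        offs = np.arange(-3 * s_tex, 3 * s_tex + 1)
        kern = np.exp(-0.5 * (offs / s_tex) ** 2)
        kern /= kern.sum()
        field = np.zeros(n)
        for o, kv in zip(offs, kern):
            field += kv * np.roll(white, o)
        field = (field - field.mean()) / field.std()
        taper = config.texture_taper_bins
        idx = np.arange(n)
        for dd in range(taper + 1):
            j = (idx + dd) % n
            mid = (idx + dd // 2) % n
            factor = np.clip(
                1.0 + config.texture_amp * field[mid] * (1.0 - dd / taper), 0.05, None
            )
            mu[idx, j] *= factor
            if dd:
                mu[j, idx] *= factor
    for s, e, boost in config.cid_blocks:
        block = np.zeros(n, dtype=bool)
        block[s:e] = True
        mask = np.outer(block, block)
        mu[mask] *= boost
    mu_test = mu.copy()
    for i, j, boost in config.diff_contacts:
        mu_test[i, j] *= boost
        mu_test[j, i] *= boost
    for b, depth, halfwidth in config.boundaries_test:
        # deplete pairs straddling the edge between bins b-1 and b with both
        # ends within halfwidth bins of the boundary
        for u in range(1, halfwidth + 1):
            i = (b - u) % n
            for v in range(halfwidth):
                j = (b + v) % n
                mu_test[i, j] *= depth
                mu_test[j, i] *= depth
    return mu, mu_test


def gen_hic_pair(
    config: SynthConfig,
) -> tuple[np.ndarray, np.ndarray, TruthTable]:
    """Poisson-sampled symmetric contact matrices for two conditions.

    The test matrix shares the reference draw wherever the expected values
    coincide, so with no planted differences the two are identical; pairs
    whose expectation differs (boosted differential contacts, test-only
    boundary depletions) are re-sampled from an independent stream.
    """
    config.validate()
    n = config.hic_bins
    mu_ref, mu_test = expected_contact_matrices(config)
    rng_ref = _rng(config, "hic_ref")
    rng_diff = _rng(config, "hic_diff")
    iu = np.triu_indices(n)
    ref = np.zeros((n, n), dtype=np.int64)
    ref[iu] = rng_ref.poisson(mu_ref[iu])
    ref = np.maximum(ref, ref.T)
    test = ref.copy()
    changed = mu_test[iu] != mu_ref[iu]
    if changed.any():
        new_counts = rng_diff.poisson(mu_test[iu][changed])
        tmp = test[iu]
        tmp[changed] = new_counts
        test = np.zeros((n, n), dtype=np.int64)
        test[iu] = tmp
        test = np.maximum(test, test.T)
    boundaries = sorted({s for s, _, _ in config.cid_blocks} | {e % n for _, e, _ in config.cid_blocks})
    truth = TruthTable(
        cid_boundaries=boundaries,
        cid_boundaries_test_extra=[b for b, _, _ in config.boundaries_test],
        diff_contacts=[(min(i, j), max(i, j), boost) for i, j, boost in config.diff_contacts],
    )
    return ref, test, truth


def gen_de_table(
    config: SynthConfig, annotation: GenomeAnnotation
) -> tuple["pd.DataFrame", TruthTable]:
    """Differential-expression table with one category planted at higher odds.

    Each gene is flagged DE with baseline probability ``de_frac``; genes in
    ``enriched_category`` have their odds multiplied by ``enrichment_odds``.
    log2 fold changes and adjusted p-values are back-filled from the flags:
    |log2FC| >= 1 and padj <= 0.05 iff flagged.
    """
    import pandas as pd

    config.validate()
    rng = _rng(config, "de_table")
    base_odds = config.de_frac / (1.0 - config.de_frac) if config.de_frac < 1 else np.inf
    rows = []
    truth = TruthTable(enriched_category=config.enriched_category)
    for g in annotation.genes:
        odds = base_odds
        if g.cog_letter == config.enriched_category:
            odds = base_odds * config.enrichment_odds
        p_de = odds / (1.0 + odds) if np.isfinite(odds) else 1.0
        is_de = bool(rng.random() < p_de)
        if is_de:
            sign = 1.0 if rng.random() < 0.8 else -1.0  # mostly upregulation
            log2fc = sign * (1.0 + rng.exponential(1.0))
            padj = float(rng.uniform(0.0, 0.05))
            p = float(rng.uniform(0.0, 1.0)) * padj
            truth.de_gene_ids.append(g.gene_id)
        else:
            log2fc = float(np.clip(rng.normal(0.0, 0.4), -0.99, 0.99))
            padj = float(rng.uniform(0.051, 1.0))
            p = float(rng.uniform(0.0, 1.0)) * padj
        rows.append({"id": g.gene_id, "log2fc": log2fc, "p": p, "padj": padj})
    return pd.DataFrame(rows), truth


def generate_all(config: SynthConfig) -> dict:
    """Run the whole generator; returns all in-memory products and truth."""
    genome = gen_genome(config)
    annotation = gen_annotation(config, genome)
    genome, calls, meth_truth = plant_methylation(config, genome, annotation)
    ref, test, hic_truth = gen_hic_pair(config)
    de_table, de_truth = gen_de_table(config, annotation)
    return {
        "config": config,
        "genome": genome,
        "annotation": annotation,
        "calls": calls,
        "meth_truth": meth_truth,
        "hic_ref": ref,
        "hic_test": test,
        "hic_truth": hic_truth,
        "de_table": de_table,
        "de_truth": de_truth,
    }


def with_seed(config: SynthConfig, seed: int) -> SynthConfig:
    """Convenience: same conditions, different random seed."""
    return replace(config, seed=seed)
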