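"""Planted-signal recovery benchmarks at the study's desk-scale conditions.

Each function simulates under the generator defaults (200 kb genomes,
400-bin contact maps), runs the corresponding analysis stage, and measures
how well the planted ground truth is recovered.  The same entry points back
both the acceptance test suite and the reproduction script, so the numbers
they report are always recomputed from scratch.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import enrich_stats, feature_map, hic_compare, motif_bias, synthgen

__all__ = [
    "seed_stream",
    "density_recovery",
    "motif_bias_sign_recovery",
    "hic_recovery",
    "enrichment_power",
    "enrichment_type1",
]


def seed_stream(base_seed: int, n: int) -> list[int]:
    """n child seeds derived reproducibly from one base seed (< 2^31)."""
    ss = np.random.SeedSequence(base_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def density_recovery(base_seed: int = 0, n_seeds: int = 20) -> dict:
    """Mean methylated-site densities (per kb) in CDS vs intergenic under
    the default planted rates, and the proportion of planted motif
    occurrences called methylated."""
    cds, ig, n_meth, n_tot = [], [], 0, 0
    for seed in seed_stream(base_seed, n_seeds):
        cfg = synthgen.SynthConfig(seed=seed)
        genome = synthgen.gen_genome(cfg)
        ann = synthgen.gen_annotation(cfg, genome)
        genome, calls, truth = synthgen.plant_methylation(cfg, genome, ann)
        cds.append(
            feature_map.methylation_density(calls, ann.merged_cds_intervals()).density_per_kb
        )
        ig.append(
            feature_map.methylation_density(calls, ann.intergenic_intervals()).density_per_kb
        )
        n_meth += sum(1 for m in truth.motif_instances if m.methylated)
        n_tot += len(truth.motif_instances)
    return {
        "cds_density_per_kb": float(np.mean(cds)),
        "ig_density_per_kb": float(np.mean(ig)),
        "proportion_methylated_pct": feature_map.motif_methylation_summary(n_meth, n_tot),
        "n_seeds": n_seeds,
    }


def motif_bias_sign_recovery(
    base_seed: int = 0, n_seeds: int = 100, rate_cds: float = 1.2, rate_ig: float = 0.6
) -> dict:
    """Fraction of seeds in which the usage-bias statistic recovers the
    planted CDS skew (b < 0) when rate_cds = 2 * rate_ig."""
    negative = 0
    for seed in seed_stream(base_seed, n_seeds):
        cfg = synthgen.SynthConfig(seed=seed, rate_cds=rate_cds, rate_ig=rate_ig)
        genome = synthgen.gen_genome(cfg)
        ann = synthgen.gen_annotation(cfg, genome)
        genome, _, _ = synthgen.plant_methylation(cfg, genome, ann)
        res = motif_bias.compute_bias(genome, ann, cfg.motif, order=2)
        negative += res.b < 0
    return {"sign_recovery_frac": negative / n_seeds, "n_seeds": n_seeds}


def hic_recovery(base_seed: int = 0, n_seeds: int = 100) -> dict:
    """End-to-end comparative Hi-C recovery at the default conditions.

    Per seed: generate the reference/test matrix pair, balance, call
    significant interactions, detect CIDs and compare insulation.  Reports
    (i) the worst distance from any planted CID boundary to the nearest
    called boundary, (ii) the fraction of planted differential contacts
    recovered as test-unique interactions, (iii) the mean count of unique
    pairs not attributable to any planted difference, and (iv) the fraction
    of seeds in which the unique insulation regions cover the planted
    test-only boundary.
    """
    n_rec = n_planted = 0
    false_counts = []
    max_offsets = []
    boundary_covered = 0
    for seed in seed_stream(base_seed, n_seeds):
        cfg = synthgen.SynthConfig(seed=seed)
        n = cfg.hic_bins
        ref, test, truth = synthgen.gen_hic_pair(cfg)
        raw_r = hic_compare.ContactMatrix(ref)
        raw_t = hic_compare.ContactMatrix(test)
        bal_r, _ = hic_compare.ice_balance(raw_r)
        bal_t, _ = hic_compare.ice_balance(raw_t)
        sig_r = hic_compare.call_significant(raw_r, bal_r)
        sig_t = hic_compare.call_significant(raw_t, bal_t)
        uniq = hic_compare.unique_elements(sig_r, sig_t)
        planted = {(i, j) for i, j, _ in truth.diff_contacts}
        unique_test = set(uniq["interactions_unique_b"])
        n_rec += len(planted & unique_test)
        n_planted += len(planted)

        def near_test_boundary(pair):
            i, j = pair
            for b, _, hw in cfg.boundaries_test:
                di = min((i - b) % n, (b - i) % n)
                dj = min((j - b) % n, (b - j) % n)
                if di <= hw and dj <= hw:
                    return True
            return False

        stray = [
            p
            for p in (unique_test - planted) | set(uniq["interactions_unique_a"])
            if not near_test_boundary(p)
        ]
        false_counts.append(len(stray))

        prof_r = hic_compare.insulation_profile(bal_r)
        prof_t = hic_compare.insulation_profile(bal_t)
        called = sorted({c.start % n for c in hic_compare.call_cids(prof_r)})
        offs = [
            min(min(abs(b - t), n - abs(b - t)) for b in called)
            for t in truth.cid_boundaries
        ]
        max_offsets.append(max(offs))
        regions = hic_compare.unique_insulation_regions(prof_r, prof_t)
        extra = truth.cid_boundaries_test_extra[0]
        boundary_covered += any((extra - r.start) % n < r.length for r in regions)
    return {
        "diff_recovery_frac": n_rec / n_planted,
        "false_pairs_mean": float(np.mean(false_counts)),
        "cid_boundary_max_offset_bins": int(max(max_offsets)),
        "unique_boundary_coverage_frac": boundary_covered / n_seeds,
        "n_seeds": n_seeds,
    }


def _de_base_config() -> synthgen.SynthConfig:
    """DE-scale conditions: ~3 Mb annotation, 2000 genes, the planted
    category holding a 10% share (category size ~200)."""
    probs = tuple(
        0.1 if c == "G" else 0.9 / 16 for c in synthgen.DEFAULT_PALETTE
    )
    return synthgen.SynthConfig(
        genome_length=3_000_000, n_genes=2000, category_probs=probs
    )


def enrichment_power(base_seed: int = 0, n_seeds: int = 100, odds: float = 8.0) -> dict:
    """Fraction of seeds in which the planted category is flagged at
    q < 0.05 by the Fisher/BH enrichment pipeline."""
    base = replace(_de_base_config(), enrichment_odds=odds)
    flagged = 0
    for seed in seed_stream(base_seed, n_seeds):
        cfg = replace(base, seed=seed)
        ann = synthgen.gen_annotation(cfg)
        table, _ = synthgen.gen_de_table(cfg, ann)
        up, down = enrich_stats.filter_differential(table, 2.0, use="padj")
        rows = enrich_stats.category_enrichment(up + down, ann, key="cog")
        q = next(r.q for r in rows if r.category == cfg.enriched_category)
        flagged += q < 0.05
    return {"power_frac": flagged / n_seeds, "n_seeds": n_seeds}


def enrichment_type1(base_seed: int = 0, n_seeds: int = 400) -> dict:
    """Type-I error of the enrichment test on the planted category at
    odds 1 (no signal): fraction of seeds with raw p < 0.05."""
    base = replace(_de_base_config(), enrichment_odds=1.0)
    hits = 0
    for seed in seed_stream(base_seed, n_seeds):
        cfg = replace(base, seed=seed)
        ann = synthgen.gen_annotation(cfg)
        table, _ = synthgen.gen_de_table(cfg, ann)
        up, down = enrich_stats.filter_differential(table, 2.0, use="padj")
        rows = enrich_stats.category_enrichment(up + down, ann, key="cog")
        p = next(r.p for r in rows if r.category == cfg.enriched_category)
        hits += p < 0.05
    return {"type1_rate": hits / n_seeds, "n_seeds": n_seeds}
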