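"""PWM building, upstream extraction, exact-p scanning, overlap labeling."""

import itertools

import numpy as np
import pytest

from methylhic.io_formats import Gene, GenomeAnnotation, Interval, MethylationCall, SequenceRecord
from methylhic.tfbs_scan import (
    PWM,
    QUANT_STEP,
    TfbsHit,
    UpstreamRegion,
    build_pwm,
    extract_upstream,
    methylation_overlap,
    qualify_hits,
    scan_pwm,
    score_distribution,
)

_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


class TestBuildPwm:
    def test_zero_pseudocount(self):
        pwm = build_pwm(["ACAC", "ACAC"], pseudocount=0.0)
        assert pwm.probs[0, 0] == pytest.approx(1.0)
        assert pwm.probs[1, 1] == pytest.approx(1.0)

    def test_pseudocount_formula(self):
        # col A: (2 + 1*0.25) / (2 + 1) = 0.75
        pwm = build_pwm(["ACGT", "ACGT"], pseudocount=1.0)
        assert pwm.probs[0, 0] == pytest.approx(0.75)

    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(0)
        sites = ["".join(rng.choice(list("ACGT"), size=8)) for _ in range(12)]
        pwm = build_pwm(sites, pseudocount=0.3, background=(0.3, 0.2, 0.2, 0.3))
        assert np.allclose(pwm.probs.sum(axis=1), 1.0, atol=1e-9)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            build_pwm(["ACGT", "ACG"])


class TestExtractUpstream:
    def _annotation(self):
        return GenomeAnnotation(
            genome_length=2000,
            genes=[
                Gene("up", Interval(100, 300, "+")),
                Gene("plus", Interval(500, 800, "+")),
                Gene("minus", Interval(900, 1200, "-")),
                Gene("next", Interval(1600, 1900, "+")),
            ],
        )

    def test_plus_gene_truncated_at_upstream_feature(self):
        genome = SequenceRecord("chr", "A" * 2000)
        regions, _ = extract_upstream(self._annotation(), genome, max_len=300)
        plus = next(r for r in regions if r.gene_id == "plus")
        assert (plus.interval.start, plus.interval.end) == (300, 500)
        assert len(plus.seq) == 200

    def test_minus_gene_reverse_complemented(self):
        seq = "A" * 1200 + "CGTT" + "A" * 784
        genome = SequenceRecord("chr", seq)
        regions, _ = extract_upstream(self._annotation(), genome, max_len=300)
        minus = next(r for r in regions if r.gene_id == "minus")
        # region [1200, 1500) on the genome, reverse-complemented
        assert (minus.interval.start, minus.interval.end) == (1200, 1500)
        assert minus.seq.endswith("AACG")
        assert len(minus.seq) == 300

    def test_short_gap_dropped(self):
        ann = GenomeAnnotation(
            genome_length=1000,
            genes=[Gene("a", Interval(100, 300, "+")), Gene("b", Interval(330, 600, "+"))],
        )
        genome = SequenceRecord("chr", "A" * 1000)
        regions, n_dropped = extract_upstream(ann, genome, min_len=50, max_len=300)
        assert "b" not in {r.gene_id for r in regions}
        assert n_dropped == 1

    def test_regions_never_overlap_cds(self):
        ann = self._annotation()
        genome = SequenceRecord("chr", "A" * 2000)
        regions, _ = extract_upstream(ann, genome)
        for r in regions:
            for iv in ann.merged_cds_intervals():
                assert r.interval.end <= iv.start or iv.end <= r.interval.start


def enumeration_distribution(pwm):
    """Oracle: the null score distribution by enumerating all 4^w words
    under the background, with the same per-column integer quantization."""
    sm = pwm.score_matrix()
    q = np.rint(sm / QUANT_STEP).astype(np.int64)
    w = pwm.width
    dist = {}
    for word in itertools.product(range(4), repeat=w):
        s = int(sum(q[j, b] for j, b in enumerate(word)))
        p = float(np.prod([pwm.background[b] for b in word]))
        dist[s] = dist.get(s, 0.0) + p
    return dist


def enumeration_tail(pwm):
    dist = enumeration_distribution(pwm)
    def pvalue(qscore):
        return sum(p for s, p in dist.items() if s >= qscore)
    return pvalue


class TestScanPwm:
    def test_single_column_pvalue(self):
        pwm = PWM(
            probs=np.array([[0.97, 0.01, 0.01, 0.01]]),
            background=np.full(4, 0.25),
            pseudocount=0.0,
        )
        support, pmf = score_distribution(pwm)
        tail = np.cumsum(pmf[::-1])[::-1]
        assert tail[-1] == pytest.approx(0.25)  # only A reaches the best score

    @pytest.mark.parametrize("width", [2, 4, 6])
    def test_dp_matches_enumeration(self, width):
        rng = np.random.default_rng(width)
        if width >= 4:
            sites = ["".join(rng.choice(list("ACGT"), size=width)) for _ in range(6)]
            pwm = build_pwm(sites, pseudocount=0.5, background=(0.3, 0.2, 0.2, 0.3))
        else:
            probs = rng.dirichlet(np.ones(4), size=width)
            pwm = PWM(probs=probs, background=np.array([0.3, 0.2, 0.2, 0.3]),
                      pseudocount=0.0)
        # (a) the DP's full null distribution equals enumeration exactly
        support, pmf = score_distribution(pwm)
        oracle_dist = enumeration_distribution(pwm)
        assert sorted(oracle_dist) == list(support)
        assert pmf == pytest.approx([oracle_dist[s] for s in support], rel=1e-9)
        # (b) every reported hit p equals the enumeration tail at the hit's
        # quantized window score
        oracle = enumeration_tail(pwm)
        seq = "".join(rng.choice(list("ACGT"), size=60))
        region = UpstreamRegion("r", seq, Interval(0, 60, "+"), "+")
        hits, _ = scan_pwm(region, pwm)
        q = np.rint(pwm.score_matrix() / QUANT_STEP).astype(np.int64)
        for h in hits:
            window = np.array([_BASE_INDEX[c] for c in seq[h.interval.start:h.interval.end]])
            if h.strand == "-":
                window = 3 - window[::-1]
            qscore = int(q[np.arange(width), window].sum())
            assert h.p == pytest.approx(oracle(qscore), rel=1e-9, abs=1e-15)

    def test_revcomp_region_preserves_hits_swaps_strands(self):
        rng = np.random.default_rng(7)
        sites = ["".join(rng.choice(list("ACGT"), size=5)) for _ in range(8)]
        pwm = build_pwm(sites)
        seq = "".join(rng.choice(list("ACGT"), size=80))
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc = "".join(comp[c] for c in reversed(seq))
        fwd = UpstreamRegion("r", seq, Interval(0, 80, "+"), "+")
        # same genomic span presented in the opposite orientation
        rev = UpstreamRegion("r", rc, Interval(0, 80, "-"), "-")
        h_fwd, _ = scan_pwm(fwd, pwm)
        h_rev, _ = scan_pwm(rev, pwm)
        key = lambda h: (h.interval.start, h.strand, round(h.score, 6))
        assert sorted(map(key, h_fwd)) == sorted(map(key, h_rev))

    def test_n_windows_skipped(self):
        pwm = build_pwm(["ACGT"] * 3, pseudocount=0.5)
        region = UpstreamRegion("r", "ACGTNNACGT", Interval(0, 10, "+"), "+")
        hits, n_skipped = scan_pwm(region, pwm)
        assert n_skipped == 5  # every window touching an N
        assert {h.interval.start for h in hits} == {0, 6}

    def test_planted_consensus_is_top_hit(self):
        """A high-information consensus planted in random sequence is the
        best-scoring hit in nearly all seeds."""
        site = "TGTAAGCGCTTACA"
        rng0 = np.random.default_rng(0)
        sites = []
        for _ in range(40):
            s = list(site)
            for j in range(len(s)):
                if rng0.random() < 0.05:
                    s[j] = "ACGT"[rng0.integers(4)]
            sites.append("".join(s))
        pwm = build_pwm(sites)
        assert pwm.information_content() >= 10
        wins = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            seq = "".join(rng.choice(list("ACGT"), size=200))
            pos = int(rng.integers(0, 200 - len(site)))
            seq = seq[:pos] + site + seq[pos + len(site):]
            region = UpstreamRegion("r", seq, Interval(0, 200, "+"), "+")
            hits, _ = scan_pwm(region, pwm)
            top = max(hits, key=lambda h: h.score)
            wins += top.interval.start == pos and top.strand == "+"
        assert wins >= 38


class TestQualifyHits:
    def _hit(self, p, start=0):
        return TfbsHit("r", Interval(start, start + 4), "+", 1.0, p)

    def test_single_hit_kept(self):
        kept = qualify_hits([self._hit(0.01)])
        assert len(kept) == 1 and kept[0].q == pytest.approx(0.01)

    def test_all_p_one_none_kept(self):
        assert qualify_hits([self._hit(1.0, i) for i in range(5)]) == []

    def test_null_scan_keeps_almost_nothing(self):
        """Scanning random regions with an informative PWM: essentially no
        offsets survive the q <= 0.05 filter."""
        rng = np.random.default_rng(1)
        sites = ["TGTAAGCGCTTACA"] * 20
        pwm = build_pwm(sites, pseudocount=1.0)
        all_hits = []
        for i in range(30):
            seq = "".join(rng.choice(list("ACGT"), size=150))
            region = UpstreamRegion(f"r{i}", seq, Interval(0, 150, "+"), "+")
            hits, _ = scan_pwm(region, pwm)
            all_hits.extend(hits)
        kept = qualify_hits(all_hits)
        assert len(kept) <= 2


class TestMethylationOverlap:
    def test_call_inside_hit(self):
        hits = [TfbsHit("r", Interval(100, 110), "+", 1.0, 0.01)]
        out = methylation_overlap(hits, [MethylationCall(105, "+")])
        assert out[0].methylation_status == "methylated"

    def test_half_open_end_excluded(self):
        hits = [TfbsHit("r", Interval(100, 110), "+", 1.0, 0.01)]
        out = methylation_overlap(hits, [MethylationCall(110, "-")])
        assert out[0].methylation_status == "non_methylated"

    def test_no_calls(self):
        hits = [TfbsHit("r", Interval(0, 5), "+", 1.0, 0.5)]
        assert methylation_overlap(hits, [])[0].methylation_status == "non_methylated"
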