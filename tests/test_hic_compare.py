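"""Hi-C binning, balancing, interaction calling, insulation and CIDs."""

import math

import numpy as np
import pytest

from methylhic.hic_compare import (
    Cid,
    ContactMatrix,
    InsulationProfile,
    bin_contacts,
    call_cids,
    call_significant,
    genes_in_regions,
    ice_balance,
    insulation_profile,
    unique_cids,
    unique_elements,
    unique_insulation_regions,
)
from methylhic.io_formats import Gene, GenomeAnnotation, Interval
from methylhic.synthgen import SynthConfig, gen_hic_pair


def two_block_matrix(n=100, within=10.0, between=1.0):
    """Deterministic two-domain matrix: blocks [0,50) and [50,100)."""
    m = np.full((n, n), between)
    half = n // 2
    m[:half, :half] = within
    m[half:, half:] = within
    return ContactMatrix(m, balanced=True)


class TestBinContacts:
    def test_symmetric_accumulation(self):
        m = bin_contacts([(3, 5, 2), (5, 3, 1)], 10)
        assert m.counts[3, 5] == 3 and m.counts[5, 3] == 3

    def test_empty(self):
        assert bin_contacts([], 5).counts.sum() == 0

    def test_mass_conserved(self):
        rng = np.random.default_rng(0)
        pairs = [
            (int(i), int(j), int(c))
            for i, j, c in zip(
                rng.integers(0, 20, 50), rng.integers(0, 20, 50), rng.integers(1, 9, 50)
            )
        ]
        m = bin_contacts(pairs, 20)
        upper = np.triu(m.counts).sum()
        assert upper == sum(c for _, _, c in pairs)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            bin_contacts([(0, 10, 1)], 10)


class TestIceBalance:
    def test_constant_matrix_unchanged(self):
        m = ContactMatrix(np.full((8, 8), 5))
        bal, bias = ice_balance(m)
        s = bal.counts.sum(axis=1)
        assert np.std(s) / np.mean(s) < 1e-5
        assert np.allclose(bal.counts / bal.counts[0, 0], np.ones((8, 8)))

    def test_two_by_two_row_sums_equalize(self):
        m = ContactMatrix(np.array([[4, 2], [2, 1]]))
        bal, bias = ice_balance(m, tol=1e-8)
        s = bal.counts.sum(axis=1)
        assert s[0] == pytest.approx(s[1], rel=1e-6)
        # bias reconstruction: M_bal = M / outer(b, b)
        recon = m.counts / np.outer(bias, bias)
        assert np.allclose(recon, bal.counts)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        raw = rng.poisson(10, size=(30, 30))
        raw = np.triu(raw) + np.triu(raw, 1).T
        bal, _ = ice_balance(ContactMatrix(raw), tol=1e-8)
        bal2, bias2 = ice_balance(
            ContactMatrix(bal.counts, balanced=True), tol=1e-8
        )
        assert np.allclose(bal2.counts, bal.counts, rtol=1e-4)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            ice_balance(ContactMatrix(np.zeros((4, 4), dtype=int)))


def binomial_tail_oracle(k, n, p):
    """Exact upper-tail P(X >= k) by direct log-space summation."""
    total = 0.0
    for x in range(k, n + 1):
        lp = (
            math.lgamma(n + 1) - math.lgamma(x + 1) - math.lgamma(n - x + 1)
            + x * math.log(p) + (n - x) * math.log1p(-p)
        )
        term = math.exp(lp)
        total += term
        if x > n * p and term < 1e-18 * total:
            break
    return min(total, 1.0)


class TestCallSignificant:
    def _pair(self, seed=0, **kw):
        cfg = SynthConfig(seed=seed, **kw)
        ref, test, truth = gen_hic_pair(cfg)
        return ref, test, truth

    def test_uniform_decay_no_calls(self):
        """No planted structure: the caller returns (almost) nothing."""
        cfg = SynthConfig(seed=4, cid_blocks=(), diff_contacts=(), boundaries_test=())
        ref, _, _ = gen_hic_pair(cfg)
        raw = ContactMatrix(ref)
        bal, _ = ice_balance(raw)
        assert len(call_significant(raw, bal)) <= 1

    def test_planted_spike_called(self):
        """A 20x spike at circular distance 50 passes all three filters."""
        cfg = SynthConfig(
            seed=5, cid_blocks=(), boundaries_test=(),
            diff_contacts=((100, 150, 20.0),),
        )
        _, test, _ = gen_hic_pair(cfg)
        raw = ContactMatrix(test)
        bal, _ = ice_balance(raw)
        sig = call_significant(raw, bal)
        assert {(s.bin_i, s.bin_j) for s in sig} == {(100, 150)}

    def test_low_count_excluded_regardless_of_p(self):
        """The raw-count > 2 filter removes spikes with count <= 2."""
        n = 60
        m = np.zeros((n, n), dtype=int)
        rng = np.random.default_rng(6)
        # sparse background so that a count of 2 is nominally extreme
        iu = np.triu_indices(n, k=1)
        m[iu] = rng.poisson(0.05, size=len(iu[0]))
        m = np.maximum(m, m.T)
        m[10, 40] = m[40, 10] = 2
        raw = ContactMatrix(m)
        bal = ContactMatrix(m.astype(float), balanced=True)
        sig = call_significant(raw, bal, min_distance=2)
        assert (10, 40) not in {(s.bin_i, s.bin_j) for s in sig}

    def test_pvalues_match_binomial_oracle(self):
        """Caller p-values equal exact binomial tails to 1e-10."""
        cfg = SynthConfig(seed=7, hic_bins=60, contact_scale=5.0,
                          cid_blocks=(), diff_contacts=((5, 35, 10.0),),
                          boundaries_test=())
        _, test, _ = gen_hic_pair(cfg)
        raw = ContactMatrix(test)
        bal, _ = ice_balance(raw)
        # thresholds above 1 disable the filters so every tested pair with
        # a nonzero count is reported
        sig = call_significant(raw, bal, p_threshold=2.0, q_threshold=2.0,
                               min_count=0, min_distance=20)
        n = raw.n_bins
        d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
        d = np.minimum(d, n - d)
        iu_all = np.triu_indices(n, k=1)
        far = d[iu_all] >= 20
        obs = raw.counts[iu_all][far]
        n_total = int(obs.sum())
        checked = 0
        for s in sig[:50]:
            p_pair = s.expected / n_total
            oracle = binomial_tail_oracle(s.count, n_total, p_pair)
            assert s.p == pytest.approx(oracle, abs=1e-10)
            checked += 1
        assert checked > 10


class TestInsulation:
    def test_constant_matrix_flat_profile(self):
        prof = insulation_profile(two_block_matrix(within=3.0, between=3.0), w=5)
        assert np.allclose(prof.normalized, 0.0)

    def test_two_block_minima_at_junctions(self):
        prof = insulation_profile(two_block_matrix(), w=10)
        n = prof.normalized
        lowest = set(np.argsort(n)[:2])
        assert lowest == {0, 50}

    def test_rotation_invariance(self):
        m = two_block_matrix()
        shift = 17
        rolled = ContactMatrix(
            np.roll(np.roll(m.counts, shift, axis=0), shift, axis=1), balanced=True
        )
        p0 = insulation_profile(m, w=8).score
        p1 = insulation_profile(rolled, w=8).score
        assert np.allclose(np.roll(p0, shift), p1)

    def test_window_validation(self):
        with pytest.raises(ValueError):
            insulation_profile(two_block_matrix(), w=1)


class TestCallCids:
    def test_two_block_boundaries(self):
        prof = insulation_profile(two_block_matrix(), w=10)
        cids = call_cids(prof)
        starts = sorted(c.start % 100 for c in cids)
        assert len(cids) == 2
        assert all(min(abs(s - t), 100 - abs(s - t)) <= 2 for s, t in zip(starts, [0, 50]))

    def test_flat_profile_single_cid(self):
        prof = InsulationProfile(score=np.ones(60), window=5)
        cids = call_cids(prof)
        assert len(cids) == 1 and cids[0].length == 60

    def test_cids_tile_the_circle(self):
        cfg = SynthConfig(seed=9)
        ref, _, _ = gen_hic_pair(cfg)
        bal, _ = ice_balance(ContactMatrix(ref))
        cids = call_cids(insulation_profile(bal))
        assert sum(c.length for c in cids) == cfg.hic_bins


class TestUniqueElements:
    def _sig(self, i, j):
        from methylhic.hic_compare import SignificantInteraction

        return SignificantInteraction(i, j, 10, 1.0, 1e-9, 1e-6)

    def test_interaction_set_difference(self):
        a = [self._sig(1, 5), self._sig(2, 8)]
        b = [self._sig(2, 8)]
        out = unique_elements(a, b)
        assert out["interactions_unique_a"] == [(1, 5)]
        assert out["interactions_unique_b"] == []

    def test_identical_cids_no_uniques(self):
        cids = [Cid(0, 50, 100), Cid(50, 100, 100)]
        assert unique_cids(cids, list(cids)) == []

    def test_reciprocal_overlap_rule(self):
        a = [Cid(0, 100, 400)]
        b = [Cid(0, 98, 400)]
        assert unique_cids(a, b) == []  # 98/100 >= 0.8 both ways
        c = [Cid(0, 60, 400)]
        assert unique_cids(a, c) == a  # 60/100 < 0.8


class TestUniqueInsulationRegions:
    def test_identical_profiles_no_regions(self):
        rng = np.random.default_rng(0)
        s = rng.uniform(1, 2, size=80)
        p = InsulationProfile(score=s, window=5)
        assert unique_insulation_regions(p, p, window_bins=10) == []

    def test_anticorrelated_profiles_whole_circle(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=80)
        pa = InsulationProfile(score=np.exp(x), window=5)
        pb = InsulationProfile(score=np.exp(-x), window=5)
        regions = unique_insulation_regions(pa, pb, window_bins=10)
        assert sum(iv.length for iv in regions) == 80

    def test_shifted_boundary_covered_elsewhere_empty(self):
        """Noiseless two-block profiles with the boundary shifted by 5 bins
        in B: returned regions cover the shifted junction only."""
        n = 100
        sa = np.ones(n)
        sb = np.ones(n)
        for prof, start in ((sa, 50), (sb, 55)):
            prof[start - 3 : start + 3] = 0.3  # V-shaped dip at the junction
            prof[0:3] = 0.3
            prof[n - 3 :] = 0.3
        pa = InsulationProfile(score=sa, window=5)
        pb = InsulationProfile(score=sb, window=5)
        regions = unique_insulation_regions(pa, pb, window_bins=20)
        covered = set()
        for iv in regions:
            covered.update(int(b) % n for b in range(iv.start, iv.end))
        assert {50, 55} <= covered  # both junction positions flagged
        assert 25 not in covered and 80 not in covered  # far bins untouched


class TestGenesInRegions:
    def _annotation(self):
        return GenomeAnnotation(
            genome_length=20_000,
            genes=[
                Gene("in", Interval(11_500, 11_800)),
                Gene("edge", Interval(12_000, 12_500)),
                Gene("far", Interval(18_000, 18_500)),
            ],
        )

    def test_overlap_and_half_open(self):
        regions = [Interval(10, 12)]  # bins -> bp [10000, 12000)
        ids = genes_in_regions(regions, 1000, self._annotation())
        assert ids == ["in"]

    def test_deduplicated_across_regions(self):
        regions = [Interval(11, 12), Interval(10, 12)]
        ids = genes_in_regions(regions, 1000, self._annotation())
        assert ids == ["in"]

    def test_wrapped_region(self):
        regions = [Interval(18, 22)]  # wraps: [18000,20000) + [0,2000)
        ann = GenomeAnnotation(
            genome_length=20_000,
            genes=[Gene("a", Interval(500, 900)), Gene("b", Interval(5000, 6000))],
        )
        assert genes_in_regions(regions, 1000, ann) == ["a"]
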