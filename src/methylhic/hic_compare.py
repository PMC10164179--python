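"""Comparative Hi-C on a circular bacterial chromosome: binning, iterative
(ICE) balancing, distance-stratified significant-interaction calling,
insulation-score profiles, chromosomal interaction domain (CID) detection,
and the differential procedures (unique interactions, unique CIDs, unique
insulation regions, genes in regions).

Significance follows a simplified distance-stratified binomial model: the
expected contact probability of a pair is the per-circular-distance mean of
the balanced map normalized over all pairs, and the p-value is the upper
binomial tail of the observed raw count out of the total contact count.
Interactions pass iff p < 0.01, q < 0.01 (Benjamini-Hochberg across all
tested pairs) and raw count > 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .enrich_stats import bh_adjust
from .io_formats import GenomeAnnotation, Interval

__all__ = [
    "ContactMatrix",
    "InsulationProfile",
    "SignificantInteraction",
    "Cid",
    "bin_contacts",
    "ice_balance",
    "call_significant",
    "insulation_profile",
    "call_cids",
    "unique_elements",
    "unique_cids",
    "unique_insulation_regions",
    "genes_in_regions",
]


@dataclass
class ContactMatrix:
    """Symmetric binned contact matrix on a (by default circular) chromosome."""

    counts: np.ndarray
    bin_size: int = 1000
    circular: bool = True
    balanced: bool = False
    bias: np.ndarray | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.counts)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.allclose(m, m.T):
            raise ValueError("contact matrix must be symmetric")
        if not self.balanced:
            if np.any(m < 0) or not np.all(np.equal(np.mod(m, 1), 0)):
                raise ValueError("raw contact matrix must hold nonnegative integers")
        self.counts = m

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]


def bin_contacts(
    pairs: list[tuple[int, int, int]],
    n_bins: int,
    bin_size: int = 1000,
    circular: bool = True,
) -> ContactMatrix:
    """Accumulate (bin_i, bin_j, count) pairs into a symmetric matrix."""
    m = np.zeros((n_bins, n_bins), dtype=np.int64)
    for i, j, c in pairs:
        if not (0 <= i < n_bins and 0 <= j < n_bins):
            raise ValueError(f"bin index ({i},{j}) out of range for {n_bins} bins")
        if c < 0:
            raise ValueError("negative contact count")
        m[i, j] += c
        if i != j:
            m[j, i] += c
    return ContactMatrix(counts=m, bin_size=bin_size, circular=circular)


def ice_balance(
    matrix: ContactMatrix, max_iter: int = 200, tol: float = 1e-5
) -> tuple[ContactMatrix, np.ndarray]:
    """Iterative correction: equalize bin coverage.

    Repeatedly divides by row/column sums until the coefficient of
    variation of the (unmasked) row sums drops below ``tol``.  All-zero
    bins are masked out of the iteration and carry bias NaN.  Returns the
    balanced matrix and the per-bin bias b with
    M_bal[i,j] = M[i,j] / (b_i * b_j).
    """
    m = matrix.counts.astype(float).copy()
    n = m.shape[0]
    mask = m.sum(axis=1) > 0
    if not mask.any():
        raise ValueError("matrix has no nonzero rows")
    bias = np.ones(n)
    work = m[np.ix_(mask, mask)]
    b_work = np.ones(work.shape[0])
    cv = np.inf
    for _ in range(max_iter):
        s = work.sum(axis=1)
        if np.any(s == 0):
            raise ValueError("row became all-zero during balancing")
        cv = float(np.std(s) / np.mean(s))
        if cv < tol:
            break
        scale = s / np.mean(s)
        work = work / np.outer(scale, scale)
        b_work *= scale
    else:
        raise RuntimeError(f"ICE did not converge in {max_iter} iterations (CV {cv:.2e})")
    bal = np.zeros_like(m)
    bal[np.ix_(mask, mask)] = work
    bias[:] = np.nan
    bias[mask] = b_work
    return (
        ContactMatrix(
            counts=bal,
            bin_size=matrix.bin_size,
            circular=matrix.circular,
            balanced=True,
            bias=bias,
        ),
        bias,
    )


@dataclass(frozen=True)
class SignificantInteraction:
    bin_i: int
    bin_j: int
    count: int
    expected: float
    p: float
    q: float


def _circular_distances(n: int, circular: bool) -> np.ndarray:
    idx = np.arange(n)
    diff = np.abs(idx[:, None] - idx[None, :])
    return np.minimum(diff, n - diff) if circular else diff


def call_significant(
    raw: ContactMatrix,
    balanced: ContactMatrix,
    p_threshold: float = 0.01,
    q_threshold: float = 0.01,
    min_count: int = 2,
    min_distance: int = 20,
) -> list[SignificantInteraction]:
    """Distance-stratified binomial calling of significant interactions.

    Off-diagonal pairs at circular distance >= ``min_distance`` bins are
    tested; the near-diagonal regime is excluded because there contact
    frequency is dominated by domain-scale structure rather than discrete
    looping, so the flat per-distance expectation is misspecified — that
    regime belongs to the insulation analysis, and standard callers
    likewise drop or spline-refine short-range contacts.  Keeps pairs with
    p < p_threshold, q < q_threshold and raw count > min_count (defaults
    match the standard filter: p, q < 0.01 and count > 2).
    """
    if raw.counts.shape != balanced.counts.shape:
        raise ValueError("matrices must have the same shape")
    n = raw.n_bins
    if n == 0 or raw.counts.sum() == 0:
        return []
    d = _circular_distances(n, raw.circular)
    iu_all = np.triu_indices(n, k=1)
    far = d[iu_all] >= min_distance
    iu = (iu_all[0][far], iu_all[1][far])
    dist = d[iu]
    bal = balanced.counts[iu]
    obs = raw.counts[iu]
    # mean balanced contact per distance stratum
    max_d = dist.max()
    sums = np.bincount(dist, weights=bal, minlength=max_d + 1)
    cnts = np.bincount(dist, minlength=max_d + 1)
    mean_at = np.divide(sums, cnts, out=np.zeros_like(sums), where=cnts > 0)
    expected_weight = mean_at[dist]
    total_weight = expected_weight.sum()
    if total_weight == 0:
        return []
    p_pair = expected_weight / total_weight
    n_total = int(obs.sum())
    pvals = stats.binom.sf(obs - 1, n_total, p_pair)
    qvals = bh_adjust(pvals)
    keep = (pvals < p_threshold) & (qvals < q_threshold) & (obs > min_count)
    out = [
        SignificantInteraction(
            bin_i=int(i),
            bin_j=int(j),
            count=int(o),
            expected=float(n_total * pp),
            p=float(p),
            q=float(q),
        )
        for i, j, o, pp, p, q in zip(
            iu[0][keep], iu[1][keep], obs[keep], p_pair[keep], pvals[keep], qvals[keep]
        )
    ]
    return out


@dataclass
class InsulationProfile:
    """Per-bin insulation score and its log2-normalized form."""

    score: np.ndarray  # s(i): mean contact in the w x w inter-window square
    window: int

    @property
    def n_bins(self) -> int:
        return self.score.shape[0]

    @property
    def normalized(self) -> np.ndarray:
        """n(i) = log2(s(i) / mean(s))."""
        mean = self.score.mean()
        with np.errstate(divide="ignore"):
            return np.log2(self.score / mean)


def insulation_profile(balanced: ContactMatrix, w: int = 10) -> InsulationProfile:
    """Insulation score: mean contact across each bin's boundary.

    s(i) averages the w x w square of contacts between the w bins upstream
    of i (i-w..i-1) and bin i plus the w-1 bins downstream (i..i+w-1),
    i.e. the contacts crossing the edge immediately 5' of bin i, with
    circular wrap.  Minima of the normalized profile mark CID boundaries.
    """
    if w < 2:
        raise ValueError("window must be >= 2 bins")
    n = balanced.n_bins
    if n <= 2 * w:
        raise ValueError("need n_bins > 2*w")
    m = balanced.counts
    scores = np.empty(n)
    for i in range(n):
        rows = (np.arange(i - w, i)) % n
        cols = (np.arange(i, i + w)) % n
        scores[i] = m[np.ix_(rows, cols)].mean()
    return InsulationProfile(score=scores, window=w)


@dataclass(frozen=True)
class Cid:
    """A chromosomal interaction domain as an arc of bins.

    ``start`` is the first bin; ``end`` is exclusive and may exceed n_bins
    for an arc wrapping the origin (length = end - start).
    """

    start: int
    end: int
    n_bins_total: int
    boundary_strength_left: float = float("nan")
    boundary_strength_right: float = float("nan")

    @property
    def length(self) -> int:
        return self.end - self.start

    def bins(self) -> np.ndarray:
        return np.arange(self.start, self.end) % self.n_bins_total


def _local_minima_circular(x: np.ndarray) -> list[int]:
    """Indices of local minima on a circular profile; plateau centers."""
    n = x.size
    minima = []
    i = 0
    while i < n:
        j = i
        while (x[(j + 1) % n] == x[i]) and j < i + n - 1:
            j += 1
        left = x[(i - 1) % n]
        right = x[(j + 1) % n]
        if x[i] < left and x[i] < right:
            minima.append(((i + j) // 2) % n)
        i = j + 1
    return sorted(set(minima))


def call_cids(
    profile: InsulationProfile,
    delta_span: int = 10,
    strength_min: float = 0.3,
) -> list[Cid]:
    """CIDs as arcs between consecutive insulation-minimum boundaries.

    A boundary is a local minimum of the normalized profile whose strength
    — (mean of n over delta_span bins to the left - n at the minimum) +
    (right-side analog) — is at least ``strength_min``.  With no qualifying
    boundary the whole circle is one CID.
    """
    n_prof = profile.normalized
    n = n_prof.size
    boundaries = []
    strengths = {}
    for b in _local_minima_circular(n_prof):
        left = n_prof[(np.arange(b - delta_span, b)) % n].mean() - n_prof[b]
        right = n_prof[(np.arange(b + 1, b + 1 + delta_span)) % n].mean() - n_prof[b]
        strength = left + right
        if strength >= strength_min:
            boundaries.append(b)
            strengths[b] = (left, right)
    if not boundaries:
        return [Cid(start=0, end=n, n_bins_total=n)]
    boundaries.sort()
    cids = []
    for a, b in zip(boundaries, boundaries[1:] + [boundaries[0] + n]):
        cids.append(
            Cid(
                start=a,
                end=b,
                n_bins_total=n,
                boundary_strength_left=sum(strengths[a % n]),
                boundary_strength_right=sum(strengths[b % n]),
            )
        )
    return cids


def _arc_overlap(a: Cid, b: Cid) -> int:
    """Overlap in bins of two circular arcs on the same circle."""
    n = a.n_bins_total
    bins_a = set(int(x) for x in a.bins())
    bins_b = set(int(x) for x in b.bins())
    _ = n
    return len(bins_a & bins_b)


def unique_cids(
    cids_a: list[Cid], cids_b: list[Cid], reciprocal_overlap: float = 0.8
) -> list[Cid]:
    """CIDs of A with no reciprocal-overlap >= threshold match in B."""
    out = []
    for ca in cids_a:
        matched = False
        for cb in cids_b:
            ov = _arc_overlap(ca, cb)
            if ov >= reciprocal_overlap * ca.length and ov >= reciprocal_overlap * cb.length:
                matched = True
                break
        if not matched:
            out.append(ca)
    return out


def unique_elements(
    interactions_a: list[SignificantInteraction],
    interactions_b: list[SignificantInteraction],
    cids_a: list[Cid] | None = None,
    cids_b: list[Cid] | None = None,
    cid_reciprocal_overlap: float = 0.8,
) -> dict:
    """Interactions (and optionally CIDs) unique to each condition.

    An interaction is unique to A iff its (bin_i, bin_j) pair passes the
    significance filters in A but not in B; CID uniqueness uses reciprocal
    arc overlap >= ``cid_reciprocal_overlap``.
    """
    keys_a = {(s.bin_i, s.bin_j) for s in interactions_a}
    keys_b = {(s.bin_i, s.bin_j) for s in interactions_b}
    result = {
        "interactions_unique_a": sorted(keys_a - keys_b),
        "interactions_unique_b": sorted(keys_b - keys_a),
    }
    if cids_a is not None and cids_b is not None:
        result["cids_unique_a"] = unique_cids(cids_a, cids_b, cid_reciprocal_overlap)
        result["cids_unique_b"] = unique_cids(cids_b, cids_a, cid_reciprocal_overlap)
    return result


def unique_insulation_regions(
    profile_a: InsulationProfile,
    profile_b: InsulationProfile,
    window_bins: int = 40,
    r_threshold: float = 0.6,
) -> list[Interval]:
    """Bins whose insulation disagrees between conditions.

    Sliding windows (length ``window_bins``, step 1, circular) over the two
    normalized profiles are marked concordant when their Pearson
    correlation exceeds ``r_threshold`` (a zero-variance window is
    concordant iff both windows are flat).  Bins covered by any concordant
    window are merged away; maximal runs of the remaining bins are returned
    (an arc wrapping the origin is reported with end > n_bins).
    """
    na, nb = profile_a.normalized, profile_b.normalized
    if na.size != nb.size:
        raise ValueError("profiles must have the same length")
    n = na.size
    if window_bins < 3 or window_bins > n:
        raise ValueError("window_bins must be in [3, n_bins]")
    concordant_bins = np.zeros(n, dtype=bool)
    for start in range(n):
        idx = np.arange(start, start + window_bins) % n
        wa, wb = na[idx], nb[idx]
        sa, sb = wa.std(), wb.std()
        # tolerance so that a numerically-flat window counts as flat
        flat_a = sa <= 1e-9 * max(1.0, float(np.abs(wa).max()))
        flat_b = sb <= 1e-9 * max(1.0, float(np.abs(wb).max()))
        if flat_a or flat_b:
            ok = flat_a and flat_b
        else:
            ok = float(np.corrcoef(wa, wb)[0, 1]) > r_threshold
        if ok:
            concordant_bins[idx] = True
    remaining = ~concordant_bins
    if not remaining.any():
        return []
    if remaining.all():
        return [Interval(0, n)]
    # maximal circular runs of remaining bins
    regions = []
    # rotate so position 0 is concordant, then find linear runs
    first_conc = int(np.argmax(~remaining))
    rot = np.roll(remaining, -first_conc)
    start = None
    for i in range(n + 1):
        val = rot[i % n] if i < n else False
        if val and start is None:
            start = i
        elif not val and start is not None:
            s = (start + first_conc) % n
            e = s + (i - start)
            regions.append(Interval(s, e))
            start = None
    regions.sort(key=lambda iv: iv.start)
    return regions


def genes_in_regions(
    regions: list[Interval],
    bin_size: int,
    annotation: GenomeAnnotation,
) -> list[str]:
    """Gene ids overlapping any region's bp span by >= 1 bp, deduplicated.

    Regions are in bin coordinates (end exclusive, possibly wrapping past
    n_bins for circular arcs); spans wrap modulo the genome length.
    """
    L = annotation.genome_length
    spans: list[tuple[int, int]] = []  # linear bp pieces, half-open
    for reg in regions:
        bp_start = reg.start * bin_size
        bp_end = reg.end * bin_size
        if bp_end <= L:
            spans.append((bp_start, bp_end))
        else:  # arc wrapping the origin
            spans.append((bp_start, L))
            spans.append((0, min(bp_end - L, L)))
    gene_ids = []
    seen = set()
    for g in annotation.genes:
        gs, ge = g.interval.start, g.interval.end
        for s, e in spans:
            if gs < e and s < ge:
                if g.gene_id not in seen:
                    seen.add(g.gene_id)
                    gene_ids.append(g.gene_id)
                break
    return gene_ids
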