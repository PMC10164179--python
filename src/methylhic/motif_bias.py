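"""Markov-model expected motif frequencies and the CDS-vs-intergenic
usage-bias statistic.

A motif's expected occurrence count in a region class is computed under a
Markov model of that class's base composition; the bias score

    b = log2(O_ig / E_ig) - log2(O_cds / E_cds)

is negative when the motif is used more than expected in coding sequence
relative to intergenic sequence (skew toward CDS) and positive for the
opposite skew.  Expected counts are computed exactly by a positional dynamic
program over the degenerate motif — the motif is never expanded to its
concrete words, so arbitrary runs of N are cheap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .feature_map import IUPAC_CODES, IupacMotif, find_motif_occurrences, iupac_revcomp
from .io_formats import GenomeAnnotation, SequenceRecord

__all__ = [
    "MarkovModel",
    "BiasResult",
    "train_markov",
    "expected_count",
    "expected_count_both_strands",
    "usage_bias",
    "class_sequences",
    "compute_bias",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass
class MarkovModel:
    """Order-m Markov model of DNA composition.

    ``initial[s]`` is the empirical frequency of m-mer ``s`` (a length-m
    tuple of base indices; the empty tuple for order 0).  ``transition`` has
    shape (4^m, 4): row ``s`` is P(next base | preceding m-mer s), with the
    m-mer encoded base-4 most-significant-first.
    """

    order: int
    initial: dict[tuple[int, ...], float]
    transition: np.ndarray
    pseudocount: float

    def context_index(self, ctx: tuple[int, ...]) -> int:
        idx = 0
        for b in ctx:
            idx = idx * 4 + b
        return idx


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def train_markov(
    seqs: Iterable[str | SequenceRecord], order: int = 2, pseudocount: float = 1.0
) -> MarkovModel:
    """Maximum-likelihood Markov model with additive pseudocount.

    Each sequence is treated as an independent fragment (no transitions
    across fragment boundaries).  Positions containing N are dropped from
    the counts.  The initial distribution is the empirical m-mer frequency.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    if order > 5:
        raise ValueError("orders above 5 are not supported")
    n_ctx = 4**order
    trans_counts = np.zeros((n_ctx, 4), dtype=np.float64)
    init_counts: dict[tuple[int, ...], float] = {}
    total_len = 0
    for s in seqs:
        text = s.seq if isinstance(s, SequenceRecord) else s
        total_len += len(text)
        enc = _encode(text)
        valid = enc >= 0
        # transition counts: windows of (order+1) consecutive valid bases
        if len(enc) >= order + 1:
            win = np.lib.stride_tricks.sliding_window_view(enc, order + 1)
            ok = np.all(win >= 0, axis=1)
            win = win[ok]
            if win.size:
                ctx_idx = np.zeros(len(win), dtype=np.int64)
                for j in range(order):
                    ctx_idx = ctx_idx * 4 + win[:, j]
                np.add.at(trans_counts, (ctx_idx, win[:, order]), 1.0)
        # initial m-mer counts
        if order == 0:
            init_counts[()] = 1.0
        elif len(enc) >= order:
            win0 = np.lib.stride_tricks.sliding_window_view(enc, order)
            ok0 = np.all(win0 >= 0, axis=1)
            win0 = win0[ok0]
            for row in win0:
                key = tuple(int(x) for x in row)
                init_counts[key] = init_counts.get(key, 0.0) + 1.0
        _ = valid
    if total_len < order + 1:
        raise ValueError(
            f"training length {total_len} too small for order {order}"
        )
    trans = trans_counts + pseudocount
    row_sums = trans.sum(axis=1, keepdims=True)
    zero_rows = row_sums[:, 0] == 0
    trans[zero_rows] = 0.25  # unseen context with zero pseudocount: uniform
    row_sums[zero_rows] = 1.0
    trans = trans / row_sums
    if order == 0:
        initial = {(): 1.0}
    else:
        tot = sum(init_counts.values())
        initial = {k: v / tot for k, v in init_counts.items()}
    return MarkovModel(order=order, initial=initial, transition=trans, pseudocount=pseudocount)


def _motif_classes(motif: str) -> list[list[int]]:
    out = []
    for c in motif:
        if c not in IUPAC_CODES:
            raise ValueError(f"illegal IUPAC character {c!r}")
        out.append([_BASE_INDEX[b] for b in IUPAC_CODES[c]])
    return out


def motif_probability(model: MarkovModel, motif: str) -> float:
    """P(a window of length |motif| matches the degenerate motif).

    Computed by summing the Markov chain probability over all concrete words
    in the motif's expansion via a dynamic program over m-mer states; cost is
    O(k * 4^m * 4), independent of the expansion size.
    """
    classes = _motif_classes(motif)
    k = len(classes)
    m = model.order
    if m == 0:
        p = 1.0
        marg = model.transition[0]
        for cls in classes:
            p *= float(sum(marg[b] for b in cls))
        return p
    if k <= m:
        # window shorter than the model order: marginalize the initial
        # m-mer distribution over compatible prefixes
        total = 0.0
        for mer, prob in model.initial.items():
            if all(mer[j] in classes[j] for j in range(k)):
                total += prob
        return total
    # states: last m emitted bases
    state_mass: dict[tuple[int, ...], float] = {}
    for mer, prob in model.initial.items():
        if all(mer[j] in classes[j] for j in range(m)):
            state_mass[mer] = state_mass.get(mer, 0.0) + prob
    for j in range(m, k):
        new_mass: dict[tuple[int, ...], float] = {}
        for state, mass in state_mass.items():
            row = model.transition[model.context_index(state)]
            for b in classes[j]:
                p = mass * float(row[b])
                if p > 0.0:
                    key = state[1:] + (b,)
                    new_mass[key] = new_mass.get(key, 0.0) + p
        state_mass = new_mass
    return sum(state_mass.values())


def expected_count(
    model: MarkovModel,
    motif: IupacMotif | str,
    fragment_lengths: Sequence[int],
) -> float:
    """Expected occurrence count of the forward motif string, one strand.

    E = sum over fragments of (L_f - k + 1) * P_model(motif); fragments
    shorter than the motif contribute 0 windows.
    """
    text = motif.forward if isinstance(motif, IupacMotif) else motif
    k = len(text)
    p = motif_probability(model, text)
    windows = sum(max(0, lf - k + 1) for lf in fragment_lengths)
    return windows * p


def expected_count_both_strands(
    model: MarkovModel,
    motif: IupacMotif | str,
    fragment_lengths: Sequence[int],
) -> float:
    """Expected dyad occurrences on both strands, matching the scanner.

    Scores the forward string and its reverse complement separately and
    sums; self-reverse-complement motifs are scored once, mirroring
    :func:`methylhic.feature_map.find_motif_occurrences`.
    """
    if isinstance(motif, str):
        motif = IupacMotif.from_string(motif)
    e = expected_count(model, motif.forward, fragment_lengths)
    if not motif.is_self_revcomp:
        e += expected_count(model, iupac_revcomp(motif.forward), fragment_lengths)
    return e


@dataclass(frozen=True)
class BiasResult:
    """Observed/expected motif counts per class and the bias score b."""

    motif_id: str
    o_cds: float
    e_cds: float
    o_ig: float
    e_ig: float
    b: float
    skew_class: str  # {"CDS", "IG", "none"}
    pseudo_observation: bool = False


def usage_bias(
    o_cds: float,
    e_cds: float,
    o_ig: float,
    e_ig: float,
    motif_id: str = "",
    tol: float = 1e-9,
) -> BiasResult:
    """Bias score b = log2(O_ig/E_ig) - log2(O_cds/E_cds).

    b < 0 means the motif is over-used in CDS relative to intergenic
    sequence (skew toward CDS); b > 0 the opposite.  A zero observed count
    is replaced by a 0.5 pseudo-observation and flagged.
    """
    if e_cds <= 0 or e_ig <= 0:
        raise ValueError("expected counts must be positive")
    if o_cds < 0 or o_ig < 0:
        raise ValueError("observed counts must be nonnegative")
    pseudo = False
    if o_cds == 0:
        o_cds, pseudo = 0.5, True
    if o_ig == 0:
        o_ig, pseudo = 0.5, True
    b = math.log2(o_ig / e_ig) - math.log2(o_cds / e_cds)
    if abs(b) < tol:
        skew = "none"
    elif b < 0:
        skew = "CDS"
    else:
        skew = "IG"
    return BiasResult(
        motif_id=motif_id, o_cds=o_cds, e_cds=e_cds, o_ig=o_ig, e_ig=e_ig,
        b=b, skew_class=skew, pseudo_observation=pseudo,
    )


def class_sequences(
    genome: SequenceRecord, annotation: GenomeAnnotation
) -> tuple[list[str], list[str]]:
    """CDS and intergenic fragment sequences (merged CDS union, complement)."""
    cds = [genome.seq[iv.start:iv.end] for iv in annotation.merged_cds_intervals()]
    ig = [genome.seq[iv.start:iv.end] for iv in annotation.intergenic_intervals()]
    return cds, ig


def compute_bias(
    genome: SequenceRecord,
    annotation: GenomeAnnotation,
    motif: IupacMotif | str,
    order: int = 2,
    pseudocount: float = 1.0,
) -> BiasResult:
    """Full observed/expected bias for one motif on one genome.

    A class-specific Markov model is trained on the concatenation of each
    class's fragments and evaluated on its own class, so the expectation
    controls for class composition.  Observed counts are dyad occurrences
    fully inside a fragment (matches cannot span fragment boundaries, which
    matches the windows counted by the expectation).
    """
    if isinstance(motif, str):
        motif = IupacMotif.from_string(motif)
    cds_seqs, ig_seqs = class_sequences(genome, annotation)
    model_cds = train_markov(cds_seqs, order=order, pseudocount=pseudocount)
    model_ig = train_markov(ig_seqs, order=order, pseudocount=pseudocount)
    o_cds = sum(len(find_motif_occurrences(s, motif)) for s in cds_seqs)
    o_ig = sum(len(find_motif_occurrences(s, motif)) for s in ig_seqs)
    e_cds = expected_count_both_strands(model_cds, motif, [len(s) for s in cds_seqs])
    e_ig = expected_count_both_strands(model_ig, motif, [len(s) for s in ig_seqs])
    return usage_bias(
        o_cds, e_cds, o_ig, e_ig,
        motif_id=motif.motif_id or motif.forward,
    )
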