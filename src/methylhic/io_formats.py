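"""Readers and writers for the on-disk formats of the pipeline.

All coordinates are 0-based half-open internally; conversion to and from the
1-based inclusive conventions of GFF3 (and the simplified PacBio
``modifications.gff`` dialect) happens only at the file boundary.  Parsing is
strict: malformed lines raise :class:`FormatError` rather than being skipped,
because every input here is generated and silent loss would hide bugs.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "FormatError",
    "SequenceRecord",
    "Interval",
    "Gene",
    "GenomeAnnotation",
    "MethylationCall",
    "MotifSummaryRow",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_methylation",
    "write_mods_gff",
    "write_motifs_csv",
    "read_contacts",
    "write_contacts",
]

DNA_ALPHABET = frozenset("ACGTN")


class FormatError(ValueError):
    """Raised on malformed input files or records."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence over the alphabet {A,C,G,T,N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise FormatError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"sequence {self.id!r} contains illegal characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open genomic interval with strand."""

    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(f"bad interval [{self.start},{self.end})")
        if self.strand not in ("+", "-", "."):
            raise FormatError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end


@dataclass(frozen=True)
class Gene:
    gene_id: str
    interval: Interval
    cog_letter: str | None = None
    ko_id: str | None = None


@dataclass
class GenomeAnnotation:
    """CDS intervals with strand and functional-category tags.

    Induces the CDS/intergenic partition of the genome: a position is CDS
    iff it lies inside any gene interval (strand-agnostic), otherwise
    intergenic.
    """

    genome_length: int
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: (g.interval.start, g.interval.end))
        for g in self.genes:
            if g.interval.end > self.genome_length:
                raise FormatError(
                    f"gene {g.gene_id} extends past genome length {self.genome_length}"
                )

    def cds_intervals(self) -> list[Interval]:
        return [g.interval for g in self.genes]

    def merged_cds_intervals(self) -> list[Interval]:
        """Union of gene intervals as maximal disjoint intervals."""
        merged: list[list[int]] = []
        for g in self.genes:
            iv = g.interval
            if merged and iv.start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], iv.end)
            else:
                merged.append([iv.start, iv.end])
        return [Interval(s, e) for s, e in merged]

    def intergenic_intervals(self) -> list[Interval]:
        """Complement of the merged CDS union within [0, genome_length)."""
        out: list[Interval] = []
        cursor = 0
        for iv in self.merged_cds_intervals():
            if iv.start > cursor:
                out.append(Interval(cursor, iv.start))
            cursor = max(cursor, iv.end)
        if cursor < self.genome_length:
            out.append(Interval(cursor, self.genome_length))
        return out


@dataclass(frozen=True)
class MethylationCall:
    """One 6mA call: the 0-based position of the methylated adenine."""

    position: int
    strand: str
    motif_id: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"methylation call needs a defined strand, got {self.strand!r}")
        if self.position < 0:
            raise FormatError(f"negative call position {self.position}")


@dataclass(frozen=True)
class MotifSummaryRow:
    """One row of the simplified motifs.csv summary (fields kept verbatim)."""

    motif_string: str
    center_pos: int
    fraction: float
    n_detected: int
    n_genome: int


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read a FASTA file; lowercase is normalized to uppercase.

    Strict dialect: any character outside {A,C,G,T,N} (including internal
    whitespace) is a :class:`FormatError`.
    """
    # Bio.SeqIO silently drops internal whitespace; reject it up front
    with open(path) as handle:
        for ln, line in enumerate(handle, 1):
            stripped = line.rstrip("\n")
            if not stripped.startswith(">") and stripped.strip() != stripped.strip().replace(" ", ""):
                raise FormatError(f"{path}:{ln}: whitespace inside sequence line")
    records = []
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            records.append(SequenceRecord(rec.id, str(rec.seq).upper()))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(path: str | os.PathLike, records: list[SequenceRecord], width: int = 70) -> None:
    bio = [_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as handle:
        SeqIO.write(bio, handle, "fasta")
    _ = width  # Bio.SeqIO wraps at 60; width retained for interface stability


# ---------------------------------------------------------------------------
# GFF3 (CDS annotation)


def read_gff3(path: str | os.PathLike, genome_length: int) -> GenomeAnnotation:
    """Read CDS features from a GFF3 file into a :class:`GenomeAnnotation`.

    GFF3 1-based inclusive coordinates are converted to 0-based half-open.
    Recognized attributes: ``ID`` (gene id), ``cog`` (single COG letter),
    ``ko`` (KEGG Orthology id).
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises assorted exceptions on bad input
        raise FormatError(f"{path}: cannot parse GFF3 ({exc})") from exc

    genes: list[Gene] = []
    for feat in db.features_of_type("CDS"):
        if feat.end < feat.start:
            raise FormatError(f"{path}: CDS end {feat.end} < start {feat.start}")
        if feat.end > genome_length:
            raise FormatError(
                f"{path}: CDS end {feat.end} beyond genome length {genome_length}"
            )
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        cog = feat.attributes.get("cog", [None])[0]
        ko = feat.attributes.get("ko", [None])[0]
        strand = feat.strand if feat.strand in ("+", "-") else "."
        genes.append(
            Gene(
                gene_id=gene_id,
                interval=Interval(feat.start - 1, feat.end, strand),
                cog_letter=cog,
                ko_id=ko,
            )
        )
    return GenomeAnnotation(genome_length=genome_length, genes=genes)


def write_gff3(path: str | os.PathLike, annotation: GenomeAnnotation, seqid: str = "chr") -> None:
    """Write CDS features back out (0-based half-open -> 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {seqid} 1 {annotation.genome_length}\n")
        for g in annotation.genes:
            attrs = [f"ID={g.gene_id}"]
            if g.cog_letter is not None:
                attrs.append(f"cog={g.cog_letter}")
            if g.ko_id is not None:
                attrs.append(f"ko={g.ko_id}")
            fh.write(
                "\t".join(
                    [
                        seqid,
                        "methylhic",
                        "CDS",
                        str(g.interval.start + 1),
                        str(g.interval.end),
                        ".",
                        g.interval.strand,
                        "0",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Methylation calls (simplified PacBio dialects)

_MOTIFS_CSV_COLUMNS = ["motifString", "centerPos", "fraction", "nDetected", "nGenome"]


def read_methylation(
    path: str | os.PathLike, dialect: str
) -> list[MethylationCall] | list[MotifSummaryRow]:
    """Read methylation data in one of two simplified PacBio dialects.

    ``mods_gff``
        GFF3-like rows of per-base m6A calls; start == end is the 1-based
        position of the methylated adenine, converted here to 0-based.
        An empty file (headers only or nothing) yields an empty list.
    ``motifs_csv``
        5-column CSV summary (motifString, centerPos, fraction, nDetected,
        nGenome); rows are preserved verbatim.  Extra columns are ignored.
    """
    if dialect == "mods_gff":
        calls: list[MethylationCall] = []
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 7:
                    raise FormatError(f"{path}:{ln}: expected >=7 tab-separated fields")
                _, _, ftype, start, end, score, strand = parts[:7]
                if ftype != "m6A":
                    raise FormatError(f"{path}:{ln}: unexpected feature type {ftype!r}")
                try:
                    start_i, end_i = int(start), int(end)
                except ValueError as exc:
                    raise FormatError(f"{path}:{ln}: non-integer coordinates") from exc
                if start_i != end_i:
                    raise FormatError(f"{path}:{ln}: per-base call must have start == end")
                motif_id = None
                if len(parts) >= 9 and parts[8]:
                    for kv in parts[8].split(";"):
                        if kv.startswith("motif="):
                            motif_id = kv[len("motif="):]
                calls.append(
                    MethylationCall(
                        position=start_i - 1,
                        strand=strand,
                        motif_id=motif_id,
                        score=float(score) if score not in (".", "") else None,
                    )
                )
        return calls
    if dialect == "motifs_csv":
        df = pd.read_csv(path)
        missing = [c for c in _MOTIFS_CSV_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: motifs_csv missing columns {missing}")
        return [
            MotifSummaryRow(
                motif_string=str(r.motifString),
                center_pos=int(r.centerPos),
                fraction=float(r.fraction),
                n_detected=int(r.nDetected),
                n_genome=int(r.nGenome),
            )
            for r in df.itertuples()
        ]
    raise FormatError(f"unknown methylation dialect {dialect!r}")


def write_mods_gff(
    path: str | os.PathLike, calls: list[MethylationCall], seqid: str = "chr"
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in calls:
            attrs = f"motif={c.motif_id}" if c.motif_id else "."
            score = f"{c.score:g}" if c.score is not None else "."
            fh.write(
                "\t".join(
                    [seqid, "methylhic", "m6A", str(c.position + 1), str(c.position + 1),
                     score, c.strand, ".", attrs]
                )
                + "\n"
            )


def write_motifs_csv(path: str | os.PathLike, rows: list[MotifSummaryRow]) -> None:
    pd.DataFrame(
        [
            {
                "motifString": r.motif_string,
                "centerPos": r.center_pos,
                "fraction": r.fraction,
                "nDetected": r.n_detected,
                "nGenome": r.n_genome,
            }
            for r in rows
        ],
        columns=_MOTIFS_CSV_COLUMNS,
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Hi-C contact pairs


def read_contacts(path: str | os.PathLike) -> list[tuple[int, int, int]]:
    """Read a 3-column TSV of (bin_i, bin_j, count).

    Pairs are canonicalized to i <= j and duplicate rows summed.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["bin_i", "bin_j", "count"])
    if df.empty:
        return []
    for col in df.columns:
        if not pd.api.types.is_integer_dtype(df[col]):
            raise FormatError(f"{path}: column {col} is not integer")
    if (df["count"] < 0).any():
        raise FormatError(f"{path}: negative contact counts")
    if (df[["bin_i", "bin_j"]] < 0).any().any():
        raise FormatError(f"{path}: negative bin indices")
    lo = df[["bin_i", "bin_j"]].min(axis=1)
    hi = df[["bin_i", "bin_j"]].max(axis=1)
    canon = pd.DataFrame({"bin_i": lo, "bin_j": hi, "count": df["count"]})
    grouped = canon.groupby(["bin_i", "bin_j"], as_index=False)["count"].sum()
    grouped = grouped.sort_values(["bin_i", "bin_j"])
    return [tuple(map(int, row)) for row in grouped.itertuples(index=False)]


def write_contacts(path: str | os.PathLike, pairs: list[tuple[int, int, int]]) -> None:
    with open(path, "w") as fh:
        for i, j, c in pairs:
            fh.write(f"{i}\t{j}\t{c}\n")
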