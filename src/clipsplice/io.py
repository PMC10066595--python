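"""Readers and writers for tags (BED6), reads (BED12), FASTA and TSV tables.

BED records are 0-based half-open.  The 5' end of a CLIP tag — the
reverse-transcriptase truncation-site proxy — is the interval start on
the + strand and ``end - 1`` on the - strand.  BED12 blocks define the
exonic segments of (possibly junction-spanning) RNA-seq reads; multiple
BED12 lines sharing a read name are the alignments of one multimapping
read.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import Region

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClipTag:
    """A deduplicated CLIP tag; ``five_prime`` marks the truncation site."""

    chrom: str
    strand: str
    five_prime: int
    length: int
    replicate_id: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("tag length must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid tag strand {self.strand!r}")

    @property
    def start(self) -> int:
        return self.five_prime if self.strand == "+" else self.five_prime - self.length + 1

    @property
    def end(self) -> int:
        return self.start + self.length

    @property
    def region(self) -> Region:
        return Region(self.chrom, self.start, self.end, self.strand)


@dataclass
class ReadRecord:
    """One alignment of an RNA-seq read as a chain of exonic blocks."""

    sample_id: str
    blocks: list[Region]
    n_alignments: int = 1
    name: str = ""

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("read without blocks")
        if self.n_alignments < 1:
            raise ValueError("n_alignments must be >= 1")
        for a, b in zip(self.blocks, self.blocks[1:]):
            if b.start < a.end:
                raise ValueError("read blocks must be sorted and disjoint")

    @property
    def n_junctions(self) -> int:
        return len(self.blocks) - 1


def _check_bed_interval(chrom, start, end, path, lineno):
    if start < 0 or start >= end:
        raise ValueError(
            f"{path}: line {lineno}: invalid BED interval "
            f"{chrom}:{start}-{end}"
        )


def read_tags(path, replicate_id: str = "") -> list[ClipTag]:
    """Read deduplicated CLIP tags from BED6.

    Duplicate identical records (same interval, name and strand) are
    assumed to be accidental re-entries of an already collapsed library
    and are dropped with a warning.  Records differing only in name are
    kept: a UMI-collapsed library can legitimately contain distinct tags
    with identical coordinates, and their 5' pileups are the truncation
    signal.
    """
    tags: list[ClipTag] = []
    seen: set[tuple] = set()
    n_dup = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(
                    f"{path}: line {lineno}: BED6 needs 6 columns"
                )
            chrom, start, end, name, _score, strand = f[:6]
            start, end = int(start), int(end)
            _check_bed_interval(chrom, start, end, path, lineno)
            if strand not in ("+", "-"):
                raise ValueError(f"{path}: line {lineno}: invalid strand")
            key = (chrom, start, end, name, strand)
            if key in seen:
                n_dup += 1
                continue
            seen.add(key)
            five = start if strand == "+" else end - 1
            tags.append(
                ClipTag(chrom, strand, five, end - start, replicate_id, name)
            )
    if n_dup:
        log.warning("%s: dropped %d duplicate tag records", path, n_dup)
    return tags


def write_tags(tags: list[ClipTag], path) -> None:
    with open(path, "w") as fh:
        for i, t in enumerate(tags):
            name = t.name or f"tag{i}"
            fh.write(
                f"{t.chrom}\t{t.start}\t{t.end}\t{name}\t0\t{t.strand}\n"
            )


def read_reads(path, sample_id: str = "") -> list[ReadRecord]:
    """Read RNA-seq alignments from a BED12 dialect.

    Lines sharing a name are the candidate alignments of one
    multimapping read; ``n_alignments`` is set to that multiplicity on
    every alignment of the read.
    """
    rows: list[tuple[str, list[Region]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(
                    f"{path}: line {lineno}: BED12 needs 12 columns"
                )
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5]
            _check_bed_interval(chrom, start, end, path, lineno)
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise ValueError(
                    f"{path}: line {lineno}: blockCount mismatch"
                )
            blocks = [
                Region(chrom, start + o, start + o + s, strand)
                for o, s in zip(offsets, sizes)
            ]
            rows.append((name, blocks))
    mult = Counter(name for name, _ in rows)
    return [
        ReadRecord(sample_id, blocks, n_alignments=mult[name], name=name)
        for name, blocks in rows
    ]


def write_reads(reads: list[ReadRecord], path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            b = r.blocks
            chrom = b[0].chrom
            start, end = b[0].start, b[-1].end
            strand = b[0].strand if b[0].strand in "+-" else "+"
            sizes = ",".join(str(x.width) for x in b)
            offs = ",".join(str(x.start - start) for x in b)
            name = r.name or f"read{i}"
            fh.write(
                f"{chrom}\t{start}\t{end}\t{name}\t{r.n_alignments}\t{strand}"
                f"\t{start}\t{end}\t0\t{len(b)}\t{sizes}\t{offs}\n"
            )


def read_counts(path) -> pd.DataFrame:
    """Read an exon- or gene-level count table (TSV, first columns index)."""
    df = pd.read_csv(path, sep="\t")
    index_cols = [c for c in ("gene_id", "exon_index") if c in df.columns]
    if index_cols:
        df = df.set_index(index_cols)
    return df


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_sample_sheet(path) -> pd.DataFrame:
    """Sample sheet TSV with columns sample, group, replicate."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "group": str})
    missing = {"sample", "group", "replicate"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: sample sheet missing columns {missing}")
    if df["sample"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    return df


def read_annotation_with_genome(gtf_path, fasta_path=None):
    """Read a GTF, taking chromosome lengths from a FASTA when given."""
    from .annotation import read_annotation

    lengths = None
    if fasta_path:
        lengths = {c: len(s) for c, s in load_genome(fasta_path).items()}
    return read_annotation(gtf_path, lengths)


def load_genome(path) -> dict[str, str]:
    """Load a FASTA genome into an uppercase in-memory dict."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_genome(genome: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="")
        for chrom, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


_DNA_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMP)[::-1]


def fetch_rna(
    genome: dict[str, str], chrom: str, start: int, end: int, strand: str
) -> str:
    """Fetch a genomic window as RNA in transcript orientation.

    Minus-strand windows are reverse-complemented; T is transcribed to U.
    """
    if chrom not in genome:
        raise KeyError(f"genome is missing chromosome {chrom!r}")
    seq = genome[chrom][start:end].upper()
    if strand == "-":
        seq = revcomp_dna(seq)
    return seq.replace("T", "U")
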