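"""Gene annotation, coordinate conventions, and constitutivity classes.

All internal coordinates are 0-based half-open on the forward genomic
strand.  GTF input (1-based inclusive) is converted at the parsing
boundary; BED input is used natively.  Exons with identical genomic
coordinates in different transcripts of a gene are collapsed into a
single exon entity with multi-transcript membership; partially
overlapping exon variants are kept as distinct exons.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

log = logging.getLogger(__name__)

STRANDS = ("+", "-")


@dataclass(frozen=True)
class Region:
    """A genomic interval, 0-based half-open, strand '.' when unstranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid region {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Region") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_nt(self, other: "Region") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class GeneModel:
    """A gene with exon-level transcript membership.

    ``exons`` are sorted, non-overlapping (start, end) pairs in genomic
    order; each transcript is the set of exon indices it contains.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    transcripts: list[frozenset[int]]

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"{self.gene_id}: invalid strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene without exons")
        for (s, e) in self.exons:
            if s < 0 or s >= e:
                raise ValueError(f"{self.gene_id}: invalid exon ({s},{e})")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if (s2, e2) <= (s1, e1):
                raise ValueError(f"{self.gene_id}: exons not sorted")
        if not self.transcripts:
            raise ValueError(f"{self.gene_id}: gene without transcripts")
        n = len(self.exons)
        for t in self.transcripts:
            if not t or any(i < 0 or i >= n for i in t):
                raise ValueError(f"{self.gene_id}: invalid transcript exon set")

    @property
    def span(self) -> Region:
        return Region(
            self.chrom, self.exons[0][0], max(e for _, e in self.exons),
            self.strand,
        )

    @property
    def length(self) -> int:
        return self.span.width

    def exon_length(self, i: int) -> int:
        s, e = self.exons[i]
        return e - s


@dataclass(frozen=True)
class ConstitutivityClass:
    """Exon constitutivity: fraction of a gene's transcripts containing it.

    Class 2 ("constitutive"): fraction > 0.75.  Class 1
    ("semi-constitutive"): 0.5 <= fraction <= 0.75.  Class 0
    ("alternative"): fraction < 0.5.
    """

    exon_ref: tuple[str, int]
    fraction: float
    cls: int


@dataclass
class GenomeAnnotation:
    chrom_lengths: dict[str, int]
    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id}")
            seen.add(g.gene_id)
            if g.chrom not in self.chrom_lengths:
                raise ValueError(f"{g.gene_id}: unknown chrom {g.chrom}")
            if g.span.end > self.chrom_lengths[g.chrom]:
                raise ValueError(f"{g.gene_id}: exceeds chromosome bounds")

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    @property
    def genes_by_id(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_attrs(s: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(s))


def read_annotation(
    path, chrom_lengths: dict[str, int] | None = None
) -> GenomeAnnotation:
    """Parse an Ensembl-dialect GTF into a :class:`GenomeAnnotation`.

    Only ``exon`` features are used; each needs ``gene_id`` and
    ``transcript_id`` attributes.  1-based inclusive GTF coordinates are
    converted to 0-based half-open.  When ``chrom_lengths`` is None the
    length of each chromosome is inferred as the maximal exon end seen.
    """
    # gene_id -> {"chrom", "strand", "exons": {(s,e) -> set of tx ids}}
    genes: dict[str, dict] = {}
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValueError(
                    f"{path}: malformed GTF line {lineno}: expected 9 "
                    f"tab-separated fields, got {len(fields)}"
                )
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = (
                fields[:9]
            )
            if feature != "exon":
                continue
            try:
                start0, end0 = int(start) - 1, int(end)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed GTF line {lineno}: non-integer "
                    f"coordinates"
                ) from exc
            if start0 < 0 or start0 >= end0:
                raise ValueError(
                    f"{path}: malformed GTF line {lineno}: invalid interval"
                )
            a = _parse_gtf_attrs(attrs)
            gene_id = a.get("gene_id")
            tx_id = a.get("transcript_id")
            if not gene_id:
                raise ValueError(
                    f"{path}: malformed GTF line {lineno}: missing gene_id"
                )
            if not tx_id:
                raise ValueError(
                    f"{path}: GTF line {lineno}: exon without transcript_id"
                )
            rec = genes.setdefault(
                gene_id, {"chrom": chrom, "strand": strand, "exons": {}}
            )
            rec["exons"].setdefault((start0, end0), set()).add(tx_id)

    if not genes:
        log.warning("%s: no exon features found; empty annotation", path)

    models: list[GeneModel] = []
    for gene_id, rec in genes.items():
        intervals = sorted(rec["exons"])
        tx_ids = sorted({t for txs in rec["exons"].values() for t in txs})
        tx_sets = []
        for t in tx_ids:
            tx_sets.append(
                frozenset(
                    i for i, iv in enumerate(intervals) if t in rec["exons"][iv]
                )
            )
        models.append(
            GeneModel(gene_id, rec["chrom"], rec["strand"], intervals, tx_sets)
        )

    if chrom_lengths is None:
        chrom_lengths = {}
        for g in models:
            chrom_lengths[g.chrom] = max(
                chrom_lengths.get(g.chrom, 0), g.span.end
            )
    return GenomeAnnotation(chrom_lengths, models)


def classify_constitutivity(gene: GeneModel) -> list[ConstitutivityClass]:
    """Per-exon transcript-membership fraction and constitutivity class."""
    n_tx = len(gene.transcripts)
    if n_tx == 0:
        raise ValueError(f"{gene.gene_id}: zero transcripts")
    out = []
    for i in range(len(gene.exons)):
        frac = sum(1 for t in gene.transcripts if i in t) / n_tx
        if frac > 0.75:
            cls = 2
        elif frac >= 0.5:
            cls = 1
        else:
            cls = 0
        out.append(ConstitutivityClass((gene.gene_id, i), frac, cls))
    return out


def merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of intervals as a sorted disjoint list."""
    merged: list[list[int]] = []
    for s, e in sorted(ivals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def intergenic_regions(ann: GenomeAnnotation) -> list[Region]:
    """Strand-agnostic complement of the union of gene spans per chromosome."""
    spans: dict[str, list[tuple[int, int]]] = {c: [] for c in ann.chrom_lengths}
    for g in ann.genes:
        spans[g.chrom].append((g.span.start, g.span.end))
    out: list[Region] = []
    for chrom in sorted(ann.chrom_lengths):
        length = ann.chrom_lengths[chrom]
        pos = 0
        for s, e in merge_intervals(spans[chrom]):
            if s > pos:
                out.append(Region(chrom, pos, s))
            pos = max(pos, e)
        if pos < length:
            out.append(Region(chrom, pos, length))
    return out
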