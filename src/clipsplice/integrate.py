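"""Direct/indirect target classification of deregulated exons.

A deregulated alternative exon is a *direct* target when binding
evidence sits in the 500-nt window of intron immediately downstream of
the exon (downstream in transcript orientation, clipped to the intron):
at least one high-confidence peak overlapping the window, or at least
``min_motif`` (default 3) degenerate-motif matches inside it — the
computable form of "densely clustered" binding motifs.  Exons without a
downstream intron (terminal exons) are indirect by default, with the
reason recorded.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .annotation import GeneModel, GenomeAnnotation, Region
from .io import fetch_rna
from .motif import DegenerateMotif, match_degenerate

DOWNSTREAM_WINDOW_NT = 500
MIN_MOTIF = 3


@dataclass
class RegulatedExon:
    exon_ref: tuple[str, int]
    direction: str  # increased_inclusion / decreased_inclusion in mutant
    window: Region | None
    n_peaks_in_window: int
    n_motif_matches_in_window: int
    direct: bool
    reason: str = ""


def downstream_window(
    exon: Region, gene: GeneModel, exon_index: int,
    width: int = DOWNSTREAM_WINDOW_NT,
) -> Region | None:
    """The downstream-intron window of an exon, strand-aware and clipped
    to the intron (and chromosome).  None for terminal exons."""
    chrom = gene.chrom
    if gene.strand == "+":
        nxt = [s for s, _ in gene.exons if s >= exon.end]
        if not nxt:
            return None  # terminal exon: no downstream intron
        end = min(exon.end + width, min(nxt))
        if end <= exon.end:
            return None
        return Region(chrom, exon.end, end, "+")
    else:
        prv = [e for _, e in gene.exons if e <= exon.start]
        if not prv:
            return None
        start = max(exon.start - width, max(prv), 0)
        if start >= exon.start:
            return None
        return Region(chrom, start, exon.start, "-")


def classify_direct(
    sig_exons: pd.DataFrame,
    peaks,
    motif: DegenerateMotif | str,
    genome: dict[str, str],
    ann: GenomeAnnotation,
    *,
    window_nt: int = DOWNSTREAM_WINDOW_NT,
    min_motif: int = MIN_MOTIF,
    truth_motif_sites: list[tuple[str, int]] | None = None,
) -> list[RegulatedExon]:
    """Label significant deregulated exons as direct or indirect targets.

    ``sig_exons`` is a differential-splicing table (indexed by
    (gene_id, exon_index), with a ``log2fc`` column) already filtered to
    significant rows.  Peaks count when overlapping the downstream
    window by >= 1 nt.  Motif matches are scanned in the window sequence
    (transcript orientation); when ``truth_motif_sites`` (chrom,
    genomic motif start) is given, planted-site coordinates are counted
    instead of rescanning — the truth-based classification mode.
    """
    if isinstance(motif, str):
        motif = DegenerateMotif(motif)
    genes = ann.genes_by_id
    out: list[RegulatedExon] = []
    for (gene_id, exon_index), row in sig_exons.iterrows():
        if gene_id not in genes:
            raise ValueError(f"unknown gene {gene_id}: assembly mismatch?")
        gene = genes[gene_id]
        if gene.chrom not in genome:
            raise ValueError(
                f"{gene.chrom} absent from genome: assembly mismatch"
            )
        s, e = gene.exons[exon_index]
        exon = Region(gene.chrom, s, e, gene.strand)
        direction = (
            "increased_inclusion" if row["log2fc"] > 0
            else "decreased_inclusion"
        )
        win = downstream_window(exon, gene, exon_index, width=window_nt)
        if win is None:
            out.append(
                RegulatedExon(
                    (gene_id, exon_index), direction, None, 0, 0, False,
                    reason="no downstream intron",
                )
            )
            continue
        n_peaks = sum(1 for p in peaks if p.region.overlaps(win))
        if truth_motif_sites is not None:
            n_motif = sum(
                1
                for chrom, pos in truth_motif_sites
                if chrom == win.chrom and win.start <= pos < win.end
            )
        else:
            seq = fetch_rna(genome, win.chrom, win.start, win.end, win.strand)
            n_motif = len(match_degenerate(motif, seq))
        direct = n_peaks >= 1 or n_motif >= min_motif
        out.append(
            RegulatedExon(
                (gene_id, exon_index), direction, win, n_peaks, n_motif,
                direct,
            )
        )
    return out


def summarize_regulation(regulated: list[RegulatedExon]) -> pd.DataFrame:
    """Counts per direction and class, plus the fraction of direct exons
    with increased inclusion in the mutant."""
    if not regulated:
        raise ValueError("no regulated exons to summarize")
    rows = []
    for cls in (True, False):
        for direction in ("increased_inclusion", "decreased_inclusion"):
            n = sum(
                1
                for r in regulated
                if r.direct is cls and r.direction == direction
            )
            rows.append(
                {
                    "class": "direct" if cls else "indirect",
                    "direction": direction,
                    "n": n,
                }
            )
    df = pd.DataFrame(rows)
    n_direct = sum(1 for r in regulated if r.direct)
    n_direct_up = sum(
        1
        for r in regulated
        if r.direct and r.direction == "increased_inclusion"
    )
    df.attrs["fraction_direct_increased"] = (
        n_direct_up / n_direct if n_direct else float("nan")
    )
    return df


def regulated_table(regulated: list[RegulatedExon]) -> pd.DataFrame:
    rows = []
    for r in regulated:
        rows.append(
            {
                "gene_id": r.exon_ref[0],
                "exon_index": r.exon_ref[1],
                "direction": r.direction,
                "window": (
                    f"{r.window.chrom}:{r.window.start}-{r.window.end}"
                    if r.window
                    else ""
                ),
                "n_peaks": r.n_peaks_in_window,
                "n_motifs": r.n_motif_matches_in_window,
                "direct": r.direct,
                "reason": r.reason,
            }
        )
    return pd.DataFrame(rows)
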