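"""End-to-end orchestration: simulate -> clip-call -> motif -> splice ->
dge -> integrate, with a run log and recovery report.

Every analysis threshold lives in :class:`RunConfig` with the study's
printed value as its default, so a bare run reproduces the reference
analysis conditions.  ``full_run`` is deterministic for a fixed seed;
every output directory carries the configuration hash in
``report.json``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clip as clipmod
from . import integrate as integmod
from . import motif as motifmod
from . import simulate as simmod
from . import splicing as splmod
from .annotation import GenomeAnnotation
from .io import (
    fetch_rna,
    read_reads,
    read_sample_sheet,
    read_tags,
    write_genome,
    write_reads,
    write_table,
    write_tags,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All stage parameters, defaulting to the reference thresholds."""

    seed: int = 0
    cluster_alpha: float = 0.05
    cits_fdr: float = 0.001
    ph_min: int = 10
    fg_halfwidth: int = 50
    bg_flank: tuple[int, int] = (450, 550)
    repeat_max_frac: float = 0.2
    k: int = 7
    peak_log2fc_min: float = 2.0
    repro_min: float = 2.0
    expr_quantile: float = 0.96
    min_overlap_nt: int = 7
    si_p: float = 0.01
    si_log2fc: float = 1.0
    dge_padj: float = 0.05
    dge_fc: float = 1.5
    window_nt: int = 500
    min_motif: int = 3
    integration_motif: str = "UWAA"
    sim: simmod.SimConfig = field(default_factory=simmod.SimConfig)

    def __post_init__(self) -> None:
        checks = [
            (0 < self.cluster_alpha < 1, "cluster_alpha"),
            (0 < self.cits_fdr < 1, "cits_fdr"),
            (self.ph_min >= 1, "ph_min"),
            (0 < self.expr_quantile < 1, "expr_quantile"),
            (self.min_overlap_nt >= 1, "min_overlap_nt"),
            (self.window_nt >= 1, "window_nt"),
            (self.min_motif >= 1, "min_motif"),
        ]
        for ok, name in checks:
            if not ok:
                raise ValueError(f"{name} out of valid range")
        if isinstance(self.sim, dict):
            self.sim = simmod.SimConfig(**self.sim)
        self.bg_flank = tuple(self.bg_flank)
        # the master seed drives the simulation too
        self.sim = dataclasses.replace(self.sim, seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bg_flank"] = list(self.bg_flank)
        d["sim"] = simmod._config_dict(self.sim)
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def simulate_stage(cfg: RunConfig, outdir: Path) -> simmod.Simulation:
    outdir.mkdir(parents=True, exist_ok=True)
    sim = simmod.build_genome(cfg.sim)
    write_genome(sim.genome, outdir / "genome.fa")
    _write_gtf(sim.ann, outdir / "annotation.gtf")
    with open(outdir / "repeats.bed", "w") as fh:
        for i, r in enumerate(sim.repeats):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\trepeat{i}\t0\t+\n")
    sim.truth.to_json(outdir / "manifest.json")
    tracks = simmod.simulate_clip(cfg.sim, sim)
    for name, tags in tracks.items():
        write_tags(tags, outdir / f"tags_{name}.bed")
    reads = simmod.simulate_rnaseq(cfg.sim, sim)
    for sample, rr in reads.items():
        write_reads(rr, outdir / f"reads_{sample}.bed")
    write_table(simmod.sample_sheet(cfg.sim), outdir / "samples.tsv",
                index=False)
    return sim


def _write_gtf(ann: GenomeAnnotation, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(ann.genes, key=lambda g: g.gene_id):
            for ti, tx in enumerate(g.transcripts):
                for i in sorted(tx):
                    s, e = g.exons[i]
                    attrs = (
                        f'gene_id "{g.gene_id}"; '
                        f'transcript_id "{g.gene_id}.t{ti}";'
                    )
                    fh.write(
                        f"{g.chrom}\tclipsplice\texon\t{s + 1}\t{e}\t.\t"
                        f"{g.strand}\t.\t{attrs}\n"
                    )


def clip_stage(
    cfg: RunConfig,
    tags_rep1,
    tags_rep2,
    input_tags,
    ann: GenomeAnnotation,
):
    """Cluster, CITS, and reproducible-peak calling.

    Unique tags from the replicates are combined for cluster and CITS
    calling; per-replicate clusters feed the reproducibility filter.
    """
    pooled = list(tags_rep1) + list(tags_rep2)
    clusters = clipmod.call_clusters(pooled, ann, alpha=cfg.cluster_alpha)
    cits = clipmod.call_cits(clusters, pooled, fdr=cfg.cits_fdr)
    c1 = clipmod.call_clusters(tags_rep1, ann, alpha=cfg.cluster_alpha)
    c2 = clipmod.call_clusters(tags_rep2, ann, alpha=cfg.cluster_alpha)
    peaks = clipmod.reproducible_peaks(
        c1, c2, input_tags,
        ip_library_size=len(pooled),
        input_library_size=len(input_tags),
        ann=ann,
        log2fc_min=cfg.peak_log2fc_min,
        repro_min=cfg.repro_min,
    )
    return clusters, cits, peaks


def motif_stage(cfg: RunConfig, clusters, cits, genome, repeats):
    fg, bg = motifmod.extract_fg_bg(
        clusters, genome, ph_min=cfg.ph_min, half=cfg.fg_halfwidth,
        flank=cfg.bg_flank,
    )
    fg = motifmod.repeat_filter(fg, repeats, max_frac=cfg.repeat_max_frac)
    bg = motifmod.repeat_filter(bg, repeats, max_frac=cfg.repeat_max_frac)
    kmers = motifmod.kmer_enrichment(fg, bg, k=cfg.k)
    anchors = [(c.chrom, c.position, c.strand) for c in cits]
    profile = motifmod.positional_enrichment(
        cfg.integration_motif, anchors, genome,
        half_window=cfg.fg_halfwidth, flank=cfg.bg_flank,
    )
    windows = []
    for chrom, pos, strand in anchors:
        lo, hi = pos - 30, pos + 31
        if lo >= 0 and hi <= len(genome[chrom]):
            windows.append(fetch_rna(genome, chrom, lo, hi, strand))
    pwm = None
    if windows and kmers:
        try:
            pwm = motifmod.seeded_pwm(
                [s.kmer for s in kmers[:10]], windows
            )
        except ValueError:
            log.warning("no seed matched any CITS window; PWM skipped")
    return kmers, profile, pwm


def splice_stage(cfg: RunConfig, reads_by_sample, ann, groups):
    counts, inter, libs, index = splmod.count_table(reads_by_sample, ann)
    exons = splmod.exon_table(ann)
    fpkm = splmod.compute_fpkm(counts, exons["length"], libs)
    inter_lengths = pd.Series(
        [r.width for r in index.intergenic], index=inter.index
    )
    inter_fpkm = splmod.compute_fpkm(inter, inter_lengths, libs)
    thresholds = pd.Series(
        {
            s: splmod.background_threshold(
                inter_fpkm[s].values, q=cfg.expr_quantile * 100
            )
            for s in fpkm.columns
        }
    )
    flags, retained = splmod.expression_flags(fpkm, thresholds, groups)
    si = splmod.splicing_index(counts, exons)
    wt, mut = _group_pair(groups)
    diff = splmod.differential_splicing(
        si[sorted(groups)], groups, wt, mut, p_max=cfg.si_p,
        lfc_min=cfg.si_log2fc,
    )
    diff = diff[retained.reindex(diff.index).fillna(False)]
    patterns = splmod.pattern_si(
        counts, exons, ann, groups, wt, mut, p_max=cfg.si_p,
        lfc_min=cfg.si_log2fc,
    )
    return {
        "counts": counts,
        "intergenic": inter,
        "libs": libs,
        "exons": exons,
        "fpkm": fpkm,
        "thresholds": thresholds,
        "flags": flags,
        "retained": retained,
        "si": si,
        "diff": diff,
        "patterns": patterns,
    }


def dge_stage(cfg: RunConfig, splice, groups):
    gene_counts, detected, classes_used = splmod.gene_counts_cascade(
        splice["counts"], splice["exons"], splice["flags"],
        splice["thresholds"], splice["libs"],
    )
    factors = splmod.size_factors(gene_counts)
    norm = gene_counts.div(factors, axis=1)
    _flags, gene_retained = splmod.expression_flags(
        # reuse the 3-of-4 retention rule on the cascade detection flags
        detected.astype(float), pd.Series(0.5, index=detected.columns),
        groups,
    )
    wt, mut = _group_pair(groups)
    dge = splmod.differential_expression(
        norm[sorted(groups)][gene_retained], groups, wt, mut,
        padj_max=cfg.dge_padj, fc_min=cfg.dge_fc,
    )
    return {
        "gene_counts": gene_counts,
        "detected": detected,
        "classes_used": classes_used,
        "size_factors": factors,
        "dge": dge,
    }


def integrate_stage(cfg: RunConfig, diff, peaks, genome, ann,
                    truth_motif_sites=None):
    sig = diff[diff["significant"]]
    regulated = integmod.classify_direct(
        sig, peaks, cfg.integration_motif, genome, ann,
        window_nt=cfg.window_nt, min_motif=cfg.min_motif,
        truth_motif_sites=truth_motif_sites,
    )
    return regulated


def _group_pair(groups: dict[str, str]) -> tuple[str, str]:
    names = sorted(set(groups.values()))
    if len(names) != 2:
        raise ValueError(f"expected exactly two groups, got {names}")
    # wild type sorts last alphabetically for wt/ko; prefer explicit names
    if "wt" in names:
        wt = "wt"
        mut = next(n for n in names if n != "wt")
    else:
        wt, mut = names
    return wt, mut


def full_run(cfg: RunConfig, outdir) -> dict:
    """Run every stage on a fresh simulation and write versioned outputs.

    Returns the report dict (also written to ``report.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    simdir = outdir / "sim"
    sim = simulate_stage(cfg, simdir)
    genome = sim.genome
    ann = sim.ann
    tags1 = read_tags(simdir / "tags_ip_rep1.bed", "rep1")
    tags2 = read_tags(simdir / "tags_ip_rep2.bed", "rep2")
    input_tags = read_tags(simdir / "tags_input.bed", "input")
    clusters, cits, peaks = clip_stage(cfg, tags1, tags2, input_tags, ann)
    _write_clusters(clusters, outdir / "clusters.tsv")
    _write_cits(cits, outdir / "cits.tsv")
    _write_peaks(peaks, outdir / "peaks.tsv")

    kmers, profile, pwm = motif_stage(
        cfg, clusters, cits, genome, sim.repeats
    )
    write_table(
        pd.DataFrame(
            [
                {"kmer": s.kmer, "fg_count": s.fg_count,
                 "fg_total": s.fg_total, "bg_freq": s.bg_freq, "z": s.z,
                 "p": s.p}
                for s in kmers
            ]
        ),
        outdir / "kmers.tsv",
        index=False,
    )
    write_table(
        pd.DataFrame(
            {"offset": profile.offsets, "enrichment": profile.enrichment}
        ),
        outdir / "positional.tsv",
        index=False,
    )
    if pwm is not None:
        motifmod.write_meme(pwm, outdir / "pwm.meme")

    sheet = read_sample_sheet(simdir / "samples.tsv")
    groups = dict(zip(sheet["sample"], sheet["group"]))
    reads_by_sample = {
        s: read_reads(simdir / f"reads_{s}.bed", s) for s in sheet["sample"]
    }
    splice = splice_stage(cfg, reads_by_sample, ann, groups)
    write_table(splice["si"], outdir / "si.tsv")
    write_table(splice["diff"], outdir / "si_differential.tsv")
    write_table(splice["patterns"], outdir / "patterns.tsv", index=False)

    dge = dge_stage(cfg, splice, groups)
    write_table(dge["gene_counts"], outdir / "gene_counts.tsv")
    write_table(dge["dge"], outdir / "dge.tsv")

    regulated = integrate_stage(cfg, splice["diff"], peaks, genome, ann)
    write_table(
        integmod.regulated_table(regulated), outdir / "regulated.tsv",
        index=False,
    )
    truth_sites = [(s["chrom"], s["start"]) for s in sim.truth.motif_sites]
    truth_peaks = _truth_peaks(sim)
    regulated_truth = integrate_stage(
        cfg, splice["diff"], truth_peaks, genome, ann,
        truth_motif_sites=truth_sites,
    )

    report = {
        "config_hash": cfg.config_hash,
        "seed": cfg.seed,
        "n_tags": {"rep1": len(tags1), "rep2": len(tags2),
                   "input": len(input_tags)},
        "n_clusters": len(clusters),
        "n_cits": len(cits),
        "n_peaks": len(peaks),
        "top_kmers": [s.kmer for s in kmers[:10]],
        "kmer": simmod.kmer_metrics(kmers, cfg.sim.planted_motif),
        "positional_argmax_offset": int(
            profile.offsets[int(np.argmax(profile.enrichment))]
        ),
        "pwm_consensus": pwm.consensus if pwm is not None else "",
        "n_exons_retained": int(splice["retained"].sum()),
        "n_si_significant": int(splice["diff"]["significant"].sum()),
        "cits_metrics": simmod.cits_metrics(cits, sim.truth),
        "si_metrics": simmod.si_metrics(splice["diff"], sim.truth),
        "dge_metrics": simmod.dge_metrics(dge["dge"], sim.truth),
        "integration_called": simmod.integration_metrics(
            regulated, sim.truth
        ),
        "integration_truth": simmod.integration_metrics(
            regulated_truth, sim.truth
        ),
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return report


def _truth_peaks(sim: simmod.Simulation):
    """Idealized peaks at the planted crosslink sites (truth mode)."""
    from .annotation import Region
    from .clip import HighConfidencePeak

    peaks = []
    for s in sim.truth.clip_sites:
        peaks.append(
            HighConfidencePeak(
                Region(s["chrom"], max(0, s["crosslink"] - 15),
                       s["crosslink"] + 15, s["strand"]),
                np.inf, np.inf, s.get("gene_id"),
            )
        )
    return peaks


def _write_clusters(clusters, path) -> None:
    write_table(
        pd.DataFrame(
            [
                {
                    "chrom": c.region.chrom, "start": c.region.start,
                    "end": c.region.end, "strand": c.region.strand,
                    "n_tags": c.n_tags, "peak_height": c.peak_height,
                    "peak_center": c.peak_center, "p_raw": c.p_raw,
                    "p_bonferroni": c.p_bonferroni,
                    "gene_id": c.gene_id or "",
                }
                for c in clusters
            ]
        ),
        path,
        index=False,
    )


def _write_cits(cits, path) -> None:
    write_table(
        pd.DataFrame(
            [
                {
                    "chrom": c.chrom, "position": c.position,
                    "strand": c.strand, "k_trunc": c.k_trunc,
                    "n_tags": c.n_tags, "p": c.p, "q": c.q,
                }
                for c in cits
            ]
        ),
        path,
        index=False,
    )


def _write_peaks(peaks, path) -> None:
    write_table(
        pd.DataFrame(
            [
                {
                    "chrom": p.region.chrom, "start": p.region.start,
                    "end": p.region.end, "strand": p.region.strand,
                    "log2fc_vs_input": p.log2fc_vs_input,
                    "reproducibility": p.reproducibility,
                    "gene_id": p.gene_id or "",
                }
                for p in peaks
            ]
        ),
        path,
        index=False,
    )
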