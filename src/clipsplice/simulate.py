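"""Seeded synthetic genomes, CLIP tag sets, and RNA-seq reads with a
truth manifest.

The generator emulates the observables the analysis consumes, not the
sequencing chemistry: multi-transcript gene models yielding
constitutive/semi-constitutive/alternative exons, an intergenic
background, crosslink-biased CLIP tag pileups at planted UUWAAAA motif
clusters plus a size-matched input track, and negative-binomial exon
counts with planted inclusion shifts between a wild-type and a mutant
group.  Direct-target cassette exons carry >= 3 planted motif
realizations in their 500-nt downstream intron and crosslink sites;
indirect-target cassette exons are deregulated but their downstream
windows are scrubbed of UWAA matches and receive no tag bursts.

Everything is deterministic given ``SimConfig.seed``: per-stream seeds
are derived as CRC32 hashes of ``(seed, stream-name)``, so adding
samples never reshuffles existing ones.  The negative binomial is
parameterized by mean and dispersion with variance = mu + mu^2 * disp.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .annotation import GeneModel, GenomeAnnotation, Region
from .io import ClipTag, ReadRecord, revcomp_dna
from .motif import matches_degenerate

DNA = "ACGT"


def stream_rng(seed: int, name: str) -> np.random.Generator:
    """Deterministic per-stream generator derived from the master seed."""
    return np.random.default_rng(
        [int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode()) & 0x7FFFFFFF]
    )


@dataclass
class SimConfig:
    seed: int = 0
    n_genes: int = 40
    exons_per_gene: tuple[int, int] = (5, 5)
    cassette_fraction: float = 0.75
    planted_motif: str = "UUWAAAA"
    n_planted_direct: int = 12
    n_planted_indirect: int = 8
    psi_wt: float = 0.2
    psi_null: float = 0.5
    delta_psi: float = 0.25
    nb_mean: float = 200.0       # mean fragments per exon
    nb_dispersion: float = 0.05
    n_clip_sites: int = 300
    clip_motif_fraction: float = 0.6
    motifs_per_direct_window: int = 3
    tags_per_cluster: float = 50.0
    p_trunc: float = 0.7
    crosslink_offset_in_motif: int = 2
    replicates: int = 4
    group_names: tuple[str, str] = ("wt", "ko")
    read_length: int = 75
    tag_length: int = 30
    bg_tag_density: float = 0.02   # background tags per nt of gene span
    noise_read_fraction: float = 0.02
    multimap_fraction: float = 0.02
    de_folds: tuple[float, ...] = (1.8, 3.0, 4.7)
    exon_length: int = 150
    intron_length: int = 900
    intergenic_gap: int = 2000
    n_repeat_regions: int = 10
    repeat_length: int = 150
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        for name in ("cassette_fraction", "psi_wt", "psi_null", "p_trunc",
                     "clip_motif_fraction", "noise_read_fraction",
                     "multimap_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.exons_per_gene
        if lo < 4 or hi < lo:
            raise ValueError("exons_per_gene range must satisfy 4 <= lo <= hi")
        shifted = self.psi_wt + self.delta_psi
        if self.delta_psi and not (0.05 <= shifted <= 0.95):
            raise ValueError(
                f"delta_psi must keep mutant psi within [0.05, 0.95]; "
                f"got {shifted}"
            )
        n_cas = round(self.cassette_fraction * self.n_genes)
        if self.n_planted_direct + self.n_planted_indirect > n_cas:
            raise ValueError("more planted exons than cassette genes")
        if not (0 <= self.crosslink_offset_in_motif
                < len(self.planted_motif)):
            raise ValueError("crosslink offset outside motif")


@dataclass
class TruthManifest:
    clip_sites: list[dict] = field(default_factory=list)
    direct_exons: list[dict] = field(default_factory=list)
    indirect_exons: list[dict] = field(default_factory=list)
    de_genes: list[dict] = field(default_factory=list)
    psi: dict = field(default_factory=dict)  # gene_id -> {wt, mut}
    config: dict = field(default_factory=dict)

    @property
    def motif_sites(self) -> list[dict]:
        return [s for s in self.clip_sites if s["has_motif"]]

    @property
    def crosslink_positions(self) -> list[tuple[str, int, str]]:
        return [(s["chrom"], s["crosslink"], s["strand"])
                for s in self.clip_sites]

    def planted_exons(self) -> list[tuple[str, int]]:
        return [
            (d["gene_id"], d["exon_index"])
            for d in self.direct_exons + self.indirect_exons
        ]

    def _payload(self) -> dict:
        return {
            "clip_sites": self.clip_sites,
            "direct_exons": self.direct_exons,
            "indirect_exons": self.indirect_exons,
            "de_genes": self.de_genes,
            "psi": self.psi,
            "config": self.config,
        }

    @property
    def checksum(self) -> str:
        blob = json.dumps(self._payload(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def to_json(self, path) -> None:
        payload = self._payload()
        payload["checksum"] = self.checksum
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path) as fh:
            payload = json.load(fh)
        stated = payload.pop("checksum", None)
        # JSON round-trip turns tuples into lists; normalize via dumps
        m = cls(**payload)
        if stated is not None and stated != m.checksum:
            raise ValueError(f"{path}: manifest checksum mismatch")
        return m


@dataclass
class Simulation:
    cfg: SimConfig
    genome: dict[str, str]
    ann: GenomeAnnotation
    repeats: list[Region]
    truth: TruthManifest


def _motif_realization(pattern: str, rng: np.random.Generator) -> str:
    """Draw a concrete DNA realization of a degenerate RNA pattern."""
    from .motif import IUPAC

    out = []
    for c in pattern:
        allowed = sorted(IUPAC[c])
        base = allowed[int(rng.integers(len(allowed)))]
        out.append("T" if base == "U" else base)
    return "".join(out)


def _write_sense(seq: list[str], start: int, dna: str, strand: str) -> None:
    """Write a sense-oriented DNA word into the forward-strand sequence.

    ``start`` is the genomic coordinate of the word's first sense base:
    on + the word occupies [start, start+L); on - it occupies
    (start-L, start] and is stored reverse-complemented.
    """
    if strand == "+":
        seq[start:start + len(dna)] = list(dna)
    else:
        rc = revcomp_dna(dna)
        seq[start - len(dna) + 1:start + 1] = list(rc)


def _scrub_uwaa(seq: list[str], start: int, end: int, strand: str) -> None:
    """Remove every UWAA match from a window (sense orientation)."""
    while True:
        window = "".join(seq[start:end])
        sense = window if strand == "+" else revcomp_dna(window)
        hits = [
            i
            for i in range(len(sense) - 3)
            if sense[i] == "T" and sense[i + 1] in "TA"
            and sense[i + 2] == "A" and sense[i + 3] == "A"
        ]
        if not hits:
            return
        for i in hits:
            if strand == "+":
                seq[start + i] = "C"
            else:
                # sense index i maps to genomic end-1-i; base is complement
                seq[end - 1 - i] = "G"


def build_genome(cfg: SimConfig):
    """Build the toy genome: FASTA sequence, annotation, repeat mask and
    truth manifest.  Returns a :class:`Simulation`."""
    rng = stream_rng(cfg.seed, "genome")
    lo, hi = cfg.exons_per_gene
    n_ex = rng.integers(lo, hi + 1, size=cfg.n_genes)
    n_cassette = round(cfg.cassette_fraction * cfg.n_genes)

    # paralog pairs (2i, 2i+1) share the pair's exon count so multimapping
    # reads can be mirrored between them
    for i in range(0, cfg.n_genes - 1, 2):
        n_ex[i + 1] = n_ex[i]

    genes: list[GeneModel] = []
    pos = cfg.intergenic_gap
    layouts = []
    for gi in range(cfg.n_genes):
        k = int(n_ex[gi])
        exons = []
        p = pos
        for e in range(k):
            exons.append((p, p + cfg.exon_length))
            p += cfg.exon_length
            if e < k - 1:
                p += cfg.intron_length
        strand = "+" if gi % 2 == 0 else "-"
        gene_id = f"g{gi + 1:03d}"
        cas = k // 2 if gi < n_cassette else None
        if cas is not None:
            txs = [
                frozenset(range(k)),
                frozenset(set(range(k)) - {cas}),
                frozenset(set(range(k)) - {cas, 1}),
                frozenset(set(range(k)) - {cas, k - 2}),
            ]
        else:
            txs = [
                frozenset(range(k)),
                frozenset(set(range(k)) - {1}),
                frozenset(set(range(k)) - {k - 2}),
            ]
        genes.append(GeneModel(gene_id, cfg.chrom, strand, exons, txs))
        layouts.append({"cassette": cas, "gene_index": gi})
        pos = p + cfg.intergenic_gap
    chrom_len = pos + cfg.intergenic_gap
    ann = GenomeAnnotation({cfg.chrom: chrom_len}, genes)

    seq = list("".join(rng.choice(list(DNA), size=chrom_len)))

    truth = TruthManifest(config=_config_dict(cfg))
    motif_len = len(cfg.planted_motif)
    xoff = cfg.crosslink_offset_in_motif

    def sense_window(gene: GeneModel, cas: int) -> tuple[int, int]:
        s, e = gene.exons[cas]
        if gene.strand == "+":
            return e, e + 500
        return s - 500, s

    def add_motif_site(gene: GeneModel, sense_start: int, context: str):
        """Plant one motif realization; sense_start is the genomic
        coordinate of the motif's first sense base."""
        dna = _motif_realization(cfg.planted_motif, rng)
        _write_sense(seq, sense_start, dna, gene.strand)
        if gene.strand == "+":
            region = (sense_start, sense_start + motif_len)
            crosslink = sense_start + xoff
        else:
            region = (sense_start - motif_len + 1, sense_start + 1)
            crosslink = sense_start - xoff
        truth.clip_sites.append(
            {
                "chrom": gene.chrom, "start": region[0], "end": region[1],
                "strand": gene.strand, "crosslink": int(crosslink),
                "has_motif": True, "gene_id": gene.gene_id,
                "context": context, "realization": dna,
            }
        )

    # planted direct / indirect cassette exons
    psi_mut = cfg.psi_wt + cfg.delta_psi
    cas_gis = list(range(n_cassette))
    direct_gis = cas_gis[: cfg.n_planted_direct]
    indirect_gis = cas_gis[
        cfg.n_planted_direct: cfg.n_planted_direct + cfg.n_planted_indirect
    ]
    forbidden: list[tuple[int, int]] = []  # windows no extra site may enter
    for gi in direct_gis + indirect_gis:
        gene = genes[gi]
        cas = layouts[gi]["cassette"]
        lo_w, hi_w = sense_window(gene, cas)
        forbidden.append((lo_w - 60, hi_w + 60))
        rec = {
            "gene_id": gene.gene_id, "exon_index": int(cas),
            "psi_wt": cfg.psi_wt, "psi_mut": psi_mut,
        }
        if gi in direct_gis:
            offsets = np.linspace(
                40, 500 - motif_len - 40, cfg.motifs_per_direct_window
            ).astype(int)
            for off in offsets:
                if gene.strand == "+":
                    add_motif_site(gene, lo_w + int(off), "direct_window")
                else:
                    add_motif_site(gene, hi_w - 1 - int(off), "direct_window")
            truth.direct_exons.append(rec)
        else:
            truth.indirect_exons.append(rec)

    # psi per cassette gene
    for gi in cas_gis:
        gene_id = genes[gi].gene_id
        if gi in direct_gis or gi in indirect_gis:
            truth.psi[gene_id] = {"wt": cfg.psi_wt, "mut": psi_mut}
        else:
            truth.psi[gene_id] = {"wt": cfg.psi_null, "mut": cfg.psi_null}

    # standalone clip sites (motif and motif-free), placed in introns away
    # from planted windows and from each other
    n_direct_sites = len(truth.clip_sites)
    n_extra = max(0, cfg.n_clip_sites - n_direct_sites)
    n_target_motif = round(cfg.clip_motif_fraction * cfg.n_clip_sites)
    n_extra_motif = min(n_extra, max(0, n_target_motif - n_direct_sites))
    placed: list[int] = [s["crosslink"] for s in truth.clip_sites]
    intron_spans = []
    for gi, gene in enumerate(genes):
        for (s1, e1), (s2, _) in zip(gene.exons, gene.exons[1:]):
            intron_spans.append((gi, e1 + 40, s2 - 40))
    attempts = 0
    while len(truth.clip_sites) < n_direct_sites + n_extra:
        attempts += 1
        if attempts > 200 * cfg.n_clip_sites:
            raise RuntimeError("could not place clip sites; genome too small")
        gi, lo_i, hi_i = intron_spans[int(rng.integers(len(intron_spans)))]
        p = int(rng.integers(lo_i, hi_i - motif_len))
        if any(f_lo <= p < f_hi for f_lo, f_hi in forbidden):
            continue
        if any(abs(p - q) < 150 for q in placed):
            continue
        gene = genes[gi]
        want_motif = (
            len(truth.clip_sites) - n_direct_sites < n_extra_motif
        )
        if want_motif:
            add_motif_site(gene, p, "standalone")
        else:
            truth.clip_sites.append(
                {
                    "chrom": gene.chrom, "start": p, "end": p + 1,
                    "strand": gene.strand, "crosslink": p,
                    "has_motif": False, "gene_id": gene.gene_id,
                    "context": "standalone", "realization": "",
                }
            )
        placed.append(truth.clip_sites[-1]["crosslink"])

    # scrub UWAA from indirect windows (after all planting)
    for gi in indirect_gis:
        gene = genes[gi]
        lo_w, hi_w = sense_window(gene, layouts[gi]["cassette"])
        _scrub_uwaa(seq, lo_w, hi_w, gene.strand)

    # repeat-mask regions in intergenic space; two of them overlapping the
    # foreground windows of the first motif-free standalone sites, to
    # exercise the 20% repeat filter
    repeats: list[Region] = []
    nonmotif = [s for s in truth.clip_sites
                if not s["has_motif"]][: min(2, cfg.n_repeat_regions)]
    for s in nonmotif:
        repeats.append(
            Region(cfg.chrom, s["crosslink"] - cfg.repeat_length // 2,
                   s["crosslink"] + cfg.repeat_length // 2)
        )
    while len(repeats) < cfg.n_repeat_regions:
        p = int(rng.integers(0, chrom_len - cfg.repeat_length))
        repeats.append(Region(cfg.chrom, p, p + cfg.repeat_length))

    # planted differentially expressed genes: non-cassette genes, up in
    # the mutant group
    non_cas = [g.gene_id for gi, g in enumerate(genes) if gi >= n_cassette]
    for gene_id, fold in zip(non_cas, cfg.de_folds):
        truth.de_genes.append({"gene_id": gene_id, "fold": float(fold)})

    genome = {cfg.chrom: "".join(seq)}
    return Simulation(cfg, genome, ann, repeats, truth)


def _config_dict(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def simulate_clip(
    cfg: SimConfig, sim: Simulation
) -> dict[str, list[ClipTag]]:
    """Simulate IP replicate and size-matched input tag tracks.

    Background tags fall uniformly over gene spans (pre-mRNA); at every
    planted site a Poisson(tags_per_cluster) burst of tags truncates
    exactly at the crosslink with probability ``p_trunc`` (otherwise
    uniformly within +/-10 nt).  The input track is uniform over the
    whole genome.
    """
    out: dict[str, list[ClipTag]] = {}
    chrom_len = len(sim.genome[cfg.chrom])
    L = cfg.tag_length
    for rep in ("rep1", "rep2"):
        rng = stream_rng(cfg.seed, f"clip:{rep}")
        tags: list[ClipTag] = []
        for gene in sim.ann.genes:
            span = gene.span
            n_bg = rng.poisson(cfg.bg_tag_density * span.width)
            for p in rng.integers(span.start, span.end, size=n_bg):
                tags.append(_make_tag(cfg, chrom_len, int(p), gene.strand,
                                      rep))
        for site in sim.truth.clip_sites:
            m = rng.poisson(cfg.tags_per_cluster)
            for _ in range(m):
                if rng.random() < cfg.p_trunc:
                    p = site["crosslink"]
                else:
                    off = int(rng.integers(-10, 11))
                    sign = 1 if site["strand"] == "+" else -1
                    p = site["crosslink"] + sign * off
                tags.append(
                    _make_tag(cfg, chrom_len, int(p), site["strand"], rep)
                )
        out[f"ip_{rep}"] = tags
    rng = stream_rng(cfg.seed, "clip:input")
    n_in = rng.poisson(cfg.bg_tag_density * chrom_len)
    input_tags = []
    for p in rng.integers(L, chrom_len - L, size=n_in):
        strand = "+" if rng.random() < 0.5 else "-"
        input_tags.append(_make_tag(cfg, chrom_len, int(p), strand, "input"))
    out["input"] = input_tags
    return out


def _make_tag(cfg, chrom_len, five, strand, rep) -> ClipTag:
    L = cfg.tag_length
    five = min(max(five, L), chrom_len - L - 1)
    return ClipTag(cfg.chrom, strand, five, L, rep)


def sample_ids(cfg: SimConfig) -> list[str]:
    return [
        f"{grp}_{r + 1}"
        for grp in cfg.group_names
        for r in range(cfg.replicates)
    ]


def sample_sheet(cfg: SimConfig) -> pd.DataFrame:
    rows = [
        {"sample": f"{grp}_{r + 1}", "group": grp, "replicate": r + 1}
        for grp in cfg.group_names
        for r in range(cfg.replicates)
    ]
    return pd.DataFrame(rows)


def negative_binomial(
    rng: np.random.Generator, mean, dispersion: float, size=None
):
    """NB draws with variance = mean + mean^2 * dispersion."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def simulate_rnaseq(
    cfg: SimConfig, sim: Simulation
) -> dict[str, list[ReadRecord]]:
    """Simulate per-sample RNA-seq reads as exonic block chains.

    Per gene and sample the fragment count is NB(nb_mean * n_exons,
    nb_dispersion) — scaled by the planted fold for differentially
    expressed genes in the mutant group — and each fragment picks the
    cassette-inclusion isoform with the gene's group-specific psi.
    Reads are placed uniformly along the chosen transcript and emitted
    as genomic blocks (junction reads span >= 7 nt on each side only
    when geometry allows; shorter overhangs are left to the counting
    rule).  A ``multimap_fraction`` of reads gains a second alignment at
    the mirrored position in the paralog partner gene, and a
    ``noise_read_fraction`` of extra reads falls uniformly over the
    genome to populate the intergenic background.
    """
    wt_name, mut_name = cfg.group_names
    chrom_len = len(sim.genome[cfg.chrom])
    de_fold = {d["gene_id"]: d["fold"] for d in sim.truth.de_genes}
    genes = sim.ann.genes
    n_cassette = round(cfg.cassette_fraction * cfg.n_genes)

    reads_by_sample: dict[str, list[ReadRecord]] = {}
    for sample in sample_ids(cfg):
        grp = sample.rsplit("_", 1)[0]
        rng = stream_rng(cfg.seed, f"rnaseq:{sample}")
        reads: list[ReadRecord] = []
        ridx = 0
        total_frags = 0
        for gi, gene in enumerate(genes):
            k = len(gene.exons)
            mu = cfg.nb_mean * k
            if grp == mut_name and gene.gene_id in de_fold:
                mu *= de_fold[gene.gene_id]
            n_frags = int(negative_binomial(rng, mu, cfg.nb_dispersion))
            total_frags += n_frags
            if n_frags == 0:
                continue
            if gi < n_cassette:
                psi = sim.truth.psi[gene.gene_id][
                    "mut" if grp == mut_name else "wt"
                ]
                n_incl = int(rng.binomial(n_frags, psi))
                tx_counts = [(frozenset(range(k)), n_incl),
                             (frozenset(set(range(k)) - {k // 2}),
                              n_frags - n_incl)]
            else:
                tx_counts = [(frozenset(range(k)), n_frags)]
            partner = None
            if (gi ^ 1) < cfg.n_genes:
                partner = genes[gi ^ 1]
            shift = (
                partner.span.start - gene.span.start
                if partner is not None else 0
            )
            for tx, cnt in tx_counts:
                if cnt == 0:
                    continue
                exon_ivs = [gene.exons[i] for i in sorted(tx)]
                lens = np.array([e - s for s, e in exon_ivs])
                cum = np.concatenate([[0], np.cumsum(lens)])
                T = int(cum[-1])
                if T < cfg.read_length:
                    continue
                starts = rng.integers(0, T - cfg.read_length + 1, size=cnt)
                multi = rng.random(cnt) < cfg.multimap_fraction
                for st, is_multi in zip(starts, multi):
                    blocks = _tx_to_blocks(
                        cfg.chrom, gene.strand, exon_ivs, cum, int(st),
                        cfg.read_length,
                    )
                    name = f"{sample}:r{ridx}"
                    ridx += 1
                    if is_multi and partner is not None:
                        b2 = [
                            Region(cfg.chrom, b.start + shift,
                                   b.end + shift, partner.strand)
                            for b in blocks
                        ]
                        reads.append(ReadRecord(sample, blocks, 2, name))
                        reads.append(ReadRecord(sample, b2, 2, name))
                    else:
                        reads.append(ReadRecord(sample, blocks, 1, name))
        n_noise = rng.poisson(cfg.noise_read_fraction * total_frags)
        for p in rng.integers(0, chrom_len - cfg.read_length, size=n_noise):
            reads.append(
                ReadRecord(
                    sample,
                    [Region(cfg.chrom, int(p), int(p) + cfg.read_length,
                            "+")],
                    1,
                    f"{sample}:r{ridx}",
                )
            )
            ridx += 1
        reads_by_sample[sample] = reads
    return reads_by_sample


def _tx_to_blocks(chrom, strand, exon_ivs, cum, start, length):
    """Map a transcript-coordinate interval to genomic blocks."""
    end = start + length
    blocks = []
    for (s, e), c0, c1 in zip(exon_ivs, cum[:-1], cum[1:]):
        a, b = max(start, c0), min(end, c1)
        if a < b:
            blocks.append(Region(chrom, s + (a - c0), s + (b - c0), strand))
    return blocks


def simulate_gene_count_matrix(
    n_genes: int,
    replicates: int,
    *,
    mean: float = 500.0,
    dispersion: float = 0.01,
    planted_folds: dict[int, float] | None = None,
    group_names: tuple[str, str] = ("wt", "ko"),
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """A gene-level NB count matrix for expression-analysis calibration.

    ``planted_folds`` maps gene row index to the mutant/wild-type fold.
    Returns the count matrix and the sample->group mapping.
    """
    rng = stream_rng(seed, "gene-counts")
    planted_folds = planted_folds or {}
    base = rng.uniform(0.25, 4.0, size=n_genes) * mean
    cols, groups = [], {}
    data = {}
    for grp in group_names:
        for r in range(replicates):
            sample = f"{grp}_{r + 1}"
            mu = base.copy()
            if grp == group_names[1]:
                for gi, fold in planted_folds.items():
                    mu[gi] *= fold
            data[sample] = negative_binomial(rng, mu, dispersion)
            cols.append(sample)
            groups[sample] = grp
    df = pd.DataFrame(data, index=[f"g{i + 1:04d}" for i in range(n_genes)])
    return df, groups


# ---------------------------------------------------------------------------
# recovery metrics against the truth manifest

def cits_metrics(cits_calls, truth: TruthManifest, tol: int = 1) -> dict:
    """Sensitivity and false-discovery proportion of CITS calls against
    planted crosslink positions (a call within ``tol`` nt matches)."""
    sites = [(s["chrom"], s["crosslink"]) for s in truth.clip_sites]
    recovered = set()
    n_false = 0
    for c in cits_calls:
        hit = None
        for i, (chrom, pos) in enumerate(sites):
            if chrom == c.chrom and abs(pos - c.position) <= tol:
                hit = i
                break
        if hit is None:
            n_false += 1
        else:
            recovered.add(hit)
    n_calls = len(cits_calls)
    return {
        "sensitivity": len(recovered) / len(sites) if sites else float("nan"),
        "fdp": n_false / n_calls if n_calls else 0.0,
        "n_calls": n_calls,
    }


def si_metrics(diff: pd.DataFrame, truth: TruthManifest) -> dict:
    """Recovery of planted differential exons from a differential-
    splicing table indexed by (gene_id, exon_index)."""
    planted = set(truth.planted_exons())
    sig = diff[diff["significant"]]
    sig_set = set(sig.index)
    tp = sig_set & planted
    fp = sig_set - planted
    up = sum(1 for ref in tp if diff.loc[ref, "log2fc"] > 0)
    return {
        "sensitivity": len(tp) / len(planted) if planted else float("nan"),
        "false_positives": len(fp),
        "n_null": len(diff) - len(planted),
        "direction_agreement": up / len(tp) if tp else float("nan"),
    }


def dge_metrics(dge: pd.DataFrame, truth: TruthManifest) -> dict:
    planted = {d["gene_id"]: d["fold"] for d in truth.de_genes}
    sig = set(dge.index[dge["significant"]])
    tp = sig & set(planted)
    return {
        "sensitivity": len(tp) / len(planted) if planted else float("nan"),
        "false_positives": len(sig - set(planted)),
        "max_fold_called": float(
            max((planted[g] for g in tp), default=float("nan"))
        ),
    }


def integration_metrics(regulated, truth: TruthManifest) -> dict:
    """Direct/indirect label accuracy over planted exons."""
    label = {}
    for d in truth.direct_exons:
        label[(d["gene_id"], d["exon_index"])] = True
    for d in truth.indirect_exons:
        label[(d["gene_id"], d["exon_index"])] = False
    n_eval = n_correct = 0
    for r in regulated:
        if r.exon_ref in label:
            n_eval += 1
            n_correct += r.direct == label[r.exon_ref]
    return {
        "accuracy": n_correct / n_eval if n_eval else float("nan"),
        "n_evaluated": n_eval,
    }


def kmer_metrics(kmer_stats, pattern: str) -> dict:
    """Whether the top Z-ranked k-mer realizes the planted pattern."""
    top = kmer_stats[0].kmer if kmer_stats else ""
    return {
        "top_kmer": top,
        "top_is_motif": float(bool(top) and matches_degenerate(pattern, top)),
    }


def truth_metrics(kind: str, calls, truth, **kw) -> dict:
    """Dispatch to the per-call-type recovery metric."""
    table = {
        "cits": cits_metrics,
        "si": si_metrics,
        "dge": dge_metrics,
        "integration": integration_metrics,
    }
    if kind not in table:
        raise KeyError(f"unknown call type {kind!r}")
    return table[kind](calls, truth, **kw)
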