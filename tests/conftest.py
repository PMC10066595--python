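import pytest

from clipsplice.annotation import GeneModel, GenomeAnnotation
from clipsplice.pipeline import RunConfig, full_run


@pytest.fixture(scope="session")
def default_cfg():
    """The default study conditions with a fixed seed."""
    return RunConfig(seed=7)


@pytest.fixture(scope="session")
def default_run(default_cfg, tmp_path_factory):
    """One end-to-end run of the full pipeline on the default simulation,
    shared across tests."""
    outdir = tmp_path_factory.mktemp("default_run")
    report = full_run(default_cfg, outdir)
    return {"report": report, "outdir": outdir, "cfg": default_cfg}


def make_gene(
    gene_id="g1",
    chrom="chr1",
    strand="+",
    exons=((100, 200), (1000, 1100), (2000, 2100)),
    transcripts=({0, 1, 2}, {0, 2}),
):
    return GeneModel(
        gene_id, chrom, strand, [tuple(e) for e in exons],
        [frozenset(t) for t in transcripts],
    )


def make_annotation(genes, chrom_lengths=None):
    if chrom_lengths is None:
        chrom_lengths = {}
        for g in genes:
            chrom_lengths[g.chrom] = max(
                chrom_lengths.get(g.chrom, 0), g.span.end + 1000
            )
    return GenomeAnnotation(chrom_lengths, list(genes))
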