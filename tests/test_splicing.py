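"""Exon counting, multimapper allocation, expression calls, splicing
index, pattern analysis, and differential expression."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from clipsplice.annotation import Region
from clipsplice.io import ReadRecord
from clipsplice.splicing import (
    _ExonIndex,
    allocate_multimappers,
    assign_reads_to_exons,
    background_threshold,
    compute_fpkm,
    count_sample,
    differential_expression,
    differential_splicing,
    enumerate_patterns,
    exon_table,
    expression_flags,
    gene_counts_cascade,
    pattern_si,
    size_factors,
    splicing_index,
)

from conftest import make_annotation, make_gene


def read(blocks, sample="s", n_alignments=1, name="r"):
    return ReadRecord(
        sample, [Region("chr1", s, e, "+") for s, e in blocks],
        n_alignments, name,
    )


@pytest.fixture()
def ann():
    # exons (100,200), (1000,1100), (2000,2100); tx {0,1,2} and {0,2}
    return make_annotation([make_gene()], chrom_lengths={"chr1": 5000})


class TestAssignReads:
    def test_junction_read_counts_once_toward_each_exon(self, ann):
        r = read([(180, 200), (1000, 1020)])  # 20 nt on each side
        counts, inter, n = assign_reads_to_exons([r], ann)
        assert counts == {("g1", 0): 1, ("g1", 1): 1}
        assert inter == {} and n == 1

    def test_six_nt_overhang_not_counted(self, ann):
        r = read([(166, 200), (1000, 1006)])  # 34 nt exon0, 6 nt exon1
        counts, _, _ = assign_reads_to_exons([r], ann)
        assert counts == {("g1", 0): 1}

    def test_seven_nt_overhang_is_counted(self, ann):
        r = read([(167, 200), (1000, 1007)])
        counts, _, _ = assign_reads_to_exons([r], ann)
        assert counts == {("g1", 0): 1, ("g1", 1): 1}

    def test_contained_read_counts_one_exon(self, ann):
        counts, _, _ = assign_reads_to_exons([read([(120, 170)])], ann)
        assert counts == {("g1", 0): 1}

    def test_read_outside_genes_feeds_intergenic_pool(self, ann):
        counts, inter, _ = assign_reads_to_exons([read([(3000, 3050)])], ann)
        assert counts == {}
        assert sum(inter.values()) == 1

    def test_intronic_read_counts_nowhere(self, ann):
        counts, inter, _ = assign_reads_to_exons([read([(500, 550)])], ann)
        assert counts == {} and inter == {}

    def test_multimapper_rejected(self, ann):
        with pytest.raises(ValueError, match="unique"):
            assign_reads_to_exons([read([(120, 170)], n_alignments=2)], ann)

    def test_count_conservation(self, ann):
        """Exonic assignments + intergenic pool account for every read
        (junction reads enter once per qualifying exon by design)."""
        rng = np.random.default_rng(0)
        reads = [
            read([(int(p), int(p) + 50)], name=f"r{i}")
            for i, p in enumerate(rng.integers(0, 4900, size=200))
        ]
        counts, inter, n = assign_reads_to_exons(reads, ann)
        idx = _ExonIndex(ann)
        n_exonic_reads = sum(
            1
            for r in reads
            if any(v >= 7 for v in idx.exon_overlaps(r).values())
        )
        assert sum(counts.values()) >= n_exonic_reads  # junction double-entry
        n_genic_only = sum(
            1
            for r in reads
            if not any(v >= 7 for v in idx.exon_overlaps(r).values())
            and idx.in_gene(r)
        )
        assert sum(inter.values()) == n - n_exonic_reads - n_genic_only


class TestAllocateMultimappers:
    def test_weights_proportional_to_unique_counts(self):
        alloc = allocate_multimappers(
            [[("g1", 0), ("g2", 0)]], {("g1", 0): 30, ("g2", 0): 10}
        )
        assert alloc == {("g1", 0): 0.75, ("g2", 0): 0.25}

    def test_zero_unique_counts_split_equally(self):
        alloc = allocate_multimappers([[("a", 0), ("b", 0)]], {})
        assert alloc == {("a", 0): 0.5, ("b", 0): 0.5}

    def test_total_weight_conserved(self):
        rng = np.random.default_rng(1)
        exons = [(f"g{i}", 0) for i in range(10)]
        cands = [
            list(
                {exons[j] for j in rng.integers(0, 10, size=3)}
            )
            for _ in range(100)
        ]
        uniq = {e: int(rng.integers(0, 50)) for e in exons}
        alloc = allocate_multimappers(cands, uniq)
        assert sum(alloc.values()) == pytest.approx(100.0, abs=1e-9)

    def test_count_sample_discards_ten_plus_alignments(self, ann):
        aligns = [
            read([(120, 170)], n_alignments=10, name="m") for _ in range(10)
        ]
        total, uniq, _, lib = count_sample(aligns, ann)
        assert total == {} and lib == 0


class TestFpkm:
    def test_formula(self):
        fpkm = compute_fpkm(
            pd.DataFrame({"s": [100, 0, 50]}),
            pd.Series([1000, 500, 500]),
            pd.Series({"s": 10_000_000}),
        )
        assert list(fpkm["s"]) == [10.0, 0.0, 10.0]

    def test_25m_library(self):
        fpkm = compute_fpkm(
            pd.DataFrame({"s": [50]}), pd.Series([500]),
            pd.Series({"s": 25_000_000}),
        )
        assert fpkm.iloc[0, 0] == pytest.approx(4.0)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError, match="length"):
            compute_fpkm(
                pd.DataFrame({"s": [1]}), pd.Series([0]), pd.Series({"s": 1})
            )


class TestBackgroundThreshold:
    def test_96th_percentile_linear_interpolation(self):
        assert background_threshold(np.arange(1, 101)) == pytest.approx(
            96.04
        )

    def test_all_zeros(self):
        assert background_threshold(np.zeros(30)) == 0.0

    def test_single_value(self, caplog):
        with caplog.at_level("WARNING"):
            assert background_threshold([3.5]) == 3.5
        assert "unstable" in caplog.text

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            background_threshold([])


class TestExpressionFlags:
    def groups(self, n, grp="a"):
        return {f"{grp}{i}": grp for i in range(n)}

    def test_three_of_four_retained(self):
        fpkm = pd.DataFrame(
            [[1.0, 1.0, 1.0, 0.0]], columns=["a0", "a1", "a2", "a3"]
        )
        thr = pd.Series(0.5, index=fpkm.columns)
        _, retained = expression_flags(fpkm, thr, self.groups(4))
        assert retained.iloc[0]

    def test_two_of_four_not_retained(self):
        fpkm = pd.DataFrame(
            [[1.0, 1.0, 0.0, 0.0]], columns=["a0", "a1", "a2", "a3"]
        )
        thr = pd.Series(0.5, index=fpkm.columns)
        _, retained = expression_flags(fpkm, thr, self.groups(4))
        assert not retained.iloc[0]

    def test_two_of_three_retained(self):
        fpkm = pd.DataFrame([[1.0, 1.0, 0.0]], columns=["a0", "a1", "a2"])
        thr = pd.Series(0.5, index=fpkm.columns)
        _, retained = expression_flags(fpkm, thr, self.groups(3))
        assert retained.iloc[0]

    def test_fpkm_equal_to_threshold_is_not_expressed(self):
        fpkm = pd.DataFrame([[0.5]], columns=["a0"])
        thr = pd.Series(0.5, index=fpkm.columns)
        flags, _ = expression_flags(fpkm, thr, {"a0": "a"})
        assert not flags.iloc[0, 0]

    def test_retention_required_in_every_group(self):
        fpkm = pd.DataFrame(
            [[1, 1, 1, 1, 0, 0, 0, 0]],
            columns=[f"w{i}" for i in range(4)] + [f"k{i}" for i in range(4)],
        )
        groups = {f"w{i}": "wt" for i in range(4)}
        groups |= {f"k{i}": "ko" for i in range(4)}
        thr = pd.Series(0.5, index=fpkm.columns)
        _, retained = expression_flags(fpkm, thr, groups)
        assert not retained.iloc[0]


def cascade_inputs(counts_by_cls, flags_by_cls, lengths=100):
    """One gene, one sample; exons grouped by class."""
    rows, counts, flags = [], [], []
    i = 0
    for cls, cnts in counts_by_cls.items():
        for j, c in enumerate(cnts):
            rows.append(
                {
                    "gene_id": "g", "exon_index": i, "length": lengths,
                    "cls": cls,
                }
            )
            counts.append(c)
            flags.append(flags_by_cls[cls][j])
            i += 1
    exons = pd.DataFrame(rows).set_index(["gene_id", "exon_index"])
    cdf = pd.DataFrame({"s": counts}, index=exons.index)
    fdf = pd.DataFrame({"s": flags}, index=exons.index)
    return cdf, exons, fdf


class TestGeneCascade:
    libs = pd.Series({"s": 1_000_000})

    def run(self, counts_by_cls, flags_by_cls, thr):
        cdf, exons, fdf = cascade_inputs(counts_by_cls, flags_by_cls)
        return gene_counts_cascade(
            cdf, exons, fdf, pd.Series({"s": thr}), self.libs
        )

    def test_expressed_class2_only(self):
        gc, det, used = self.run(
            {2: [10, 20, 30], 1: [100]},
            {2: [True, True, True], 1: [True]},
            thr=1.0,
        )
        assert gc.loc["g", "s"] == 60
        assert det.loc["g", "s"]
        assert used.loc["g", "s"] == "2"

    def test_cascade_adds_class1_when_class2_insufficient(self):
        gc, det, used = self.run(
            {2: [1, 1], 1: [500]},
            {2: [False, False], 1: [True]},
            thr=50.0,
        )
        # class2 counts stay in the sum when the cascade extends
        assert gc.loc["g", "s"] == 502
        assert det.loc["g", "s"]
        assert used.loc["g", "s"] == "2+1"

    def test_nothing_expressed_flags_not_detected(self):
        gc, det, used = self.run(
            {2: [1], 1: [2], 0: [3]},
            {2: [False], 1: [False], 0: [False]},
            thr=1e9,
        )
        assert gc.loc["g", "s"] == 6
        assert not det.loc["g", "s"]
        assert used.loc["g", "s"] == "all(not detected)"


class TestSplicingIndex:
    def si_frame(self, exon_counts, cls, lengths):
        idx = pd.MultiIndex.from_tuples(
            [("g", i) for i in range(len(cls))],
            names=["gene_id", "exon_index"],
        )
        exons = pd.DataFrame(
            {"length": lengths, "cls": cls}, index=idx
        )
        counts = pd.DataFrame({"s": exon_counts}, index=idx)
        return splicing_index(counts, exons)

    def test_equal_densities_give_si_one(self):
        si = self.si_frame([50, 250, 250], [0, 2, 2], [100, 500, 500])
        assert si.loc[("g", 0), "s"] == pytest.approx(1.0)

    def test_double_density_gives_si_two(self):
        si = self.si_frame([100, 500], [0, 2], [100, 1000])
        assert si.loc[("g", 0), "s"] == pytest.approx(2.0)

    def test_zero_constitutive_counts_give_missing(self):
        si = self.si_frame([100, 0], [0, 2], [100, 1000])
        assert np.isnan(si.loc[("g", 0), "s"])

    def test_matches_per_base_oracle_on_toy_simulation(self):
        """Pipeline SI equals an independent per-base brute-force
        recomputation to 1e-12 relative on a small simulated dataset."""
        from clipsplice.simulate import SimConfig, build_genome, simulate_rnaseq

        cfg = SimConfig(
            seed=3, n_genes=5, n_planted_direct=2, n_planted_indirect=1,
            n_clip_sites=10, nb_mean=40.0, noise_read_fraction=0.0,
            multimap_fraction=0.0, replicates=1,
        )
        sim = build_genome(cfg)
        reads = simulate_rnaseq(cfg, sim)
        sample = next(iter(reads))
        counts, _, _ = assign_reads_to_exons(reads[sample], sim.ann)
        exons = exon_table(sim.ann)
        cdf = pd.DataFrame(0.0, index=exons.index, columns=[sample])
        for k, v in counts.items():
            cdf.loc[k, sample] = v
        si = splicing_index(cdf, exons)

        # oracle: naive per-read, per-exon overlap loop, then densities
        oracle_counts = {k: 0 for k in exons.index}
        for r in reads[sample]:
            for (gene_id, i), (s, e) in zip(
                exons.index,
                zip(exons["start"], exons["end"]),
            ):
                if exons.loc[(gene_id, i), "chrom"] != r.blocks[0].chrom:
                    continue
                nt = sum(
                    max(0, min(b.end, e) - max(b.start, s))
                    for b in r.blocks
                )
                if nt >= 7:
                    oracle_counts[(gene_id, i)] += 1
        for gene in sim.ann.genes:
            sub = exons.loc[gene.gene_id]
            const = sub[sub["cls"] == 2]
            cc = sum(oracle_counts[(gene.gene_id, i)] for i in const.index)
            cl = const["length"].sum()
            for i in sub.index:
                dens = (
                    oracle_counts[(gene.gene_id, i)]
                    / sub.loc[i, "length"]
                )
                expected = dens / (cc / cl) if cc > 0 else np.nan
                got = si.loc[(gene.gene_id, i), sample]
                if np.isnan(expected):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(expected, rel=1e-12)


class TestDifferentialSplicing:
    def frame(self, wt, ko):
        cols = [f"wt_{i}" for i in range(len(wt))] + [
            f"ko_{i}" for i in range(len(ko))
        ]
        groups = {c: c.split("_")[0] for c in cols}
        df = pd.DataFrame(
            [list(wt) + list(ko)], columns=cols,
            index=pd.MultiIndex.from_tuples(
                [("g", 0)], names=["gene_id", "exon_index"]
            ),
        )
        return df, groups

    def test_identical_groups_not_significant(self):
        si, groups = self.frame([1.0, 1.1, 0.9], [1.0, 1.1, 0.9])
        out = differential_splicing(si, groups, "wt", "ko")
        assert out["log2fc"].iloc[0] == pytest.approx(0.0)
        assert not out["significant"].iloc[0]

    def test_doubling_with_tight_replicates_is_significant(self):
        """Oracle: the pooled-variance t statistic computed from first
        principles gives p << 0.01 for a clean doubling."""
        wt, ko = [0.9, 1.0, 1.1, 1.0], [1.9, 2.0, 2.1, 2.0]
        si, groups = self.frame(wt, ko)
        out = differential_splicing(si, groups, "wt", "ko")
        assert out["log2fc"].iloc[0] == pytest.approx(1.0)
        sp2 = (3 * np.var(wt, ddof=1) + 3 * np.var(ko, ddof=1)) / 6
        t = (np.mean(ko) - np.mean(wt)) / math.sqrt(sp2 * 0.5)
        p_oracle = 2 * sps.t.sf(abs(t), df=6)
        assert out["p"].iloc[0] == pytest.approx(p_oracle, rel=1e-9)
        assert out["significant"].iloc[0]

    def test_zero_variance_equal_means_p_one(self):
        si, groups = self.frame([1.0, 1.0], [1.0, 1.0])
        out = differential_splicing(si, groups, "wt", "ko")
        assert out["p"].iloc[0] == 1.0

    def test_zero_variance_unequal_means_p_zero(self):
        si, groups = self.frame([1.0, 1.0], [2.0, 2.0])
        out = differential_splicing(si, groups, "wt", "ko")
        assert out["p"].iloc[0] == 0.0

    def test_all_missing_group_skipped_with_reason(self):
        si, groups = self.frame(
            [np.nan, np.nan, np.nan], [1.0, 1.0, 1.0]
        )
        out = differential_splicing(si, groups, "wt", "ko")
        assert out["skipped"].iloc[0]
        assert out["skipped_reason"].iloc[0]

    def test_type_one_error_rate_near_nominal(self):
        """Null SI ratios: the realized p <= 0.01 rate stays within
        [0.005, 0.02] (t on ratio statistics is approximate)."""
        rng = np.random.default_rng(6)
        n = 4000
        cols = [f"wt_{i}" for i in range(4)] + [f"ko_{i}" for i in range(4)]
        groups = {c: c.split("_")[0] for c in cols}
        si = pd.DataFrame(
            rng.normal(1.0, 0.1, size=(n, 8)).clip(min=0.01),
            columns=cols,
            index=pd.MultiIndex.from_tuples(
                [("g", i) for i in range(n)], names=["gene_id", "exon_index"]
            ),
        )
        out = differential_splicing(si, groups, "wt", "ko")
        rate = (out["p"] <= 0.01).mean()
        assert 0.005 <= rate <= 0.02


class TestPatterns:
    def test_cassette_detected(self):
        gene = make_gene()  # exon1 skipped by one transcript, flanked
        pats = enumerate_patterns(gene)
        assert [(p.kind, p.exons) for p in pats] == [("cassette", (1,))]

    def test_exon_in_all_transcripts_emits_nothing(self):
        gene = make_gene(transcripts=({0, 1, 2}, {0, 1, 2}))
        assert enumerate_patterns(gene) == []

    def test_mutually_exclusive_pair(self):
        gene = make_gene(
            exons=((0, 100), (200, 300), (400, 500), (600, 700)),
            transcripts=({0, 1, 3}, {0, 2, 3}),
        )
        pats = enumerate_patterns(gene)
        kinds = {p.kind for p in pats}
        assert "mutually_exclusive" in kinds
        (mxe,) = [p for p in pats if p.kind == "mutually_exclusive"]
        assert mxe.exons == (1, 2)

    def test_alt5_and_alt3_by_shared_boundary(self):
        plus = make_gene(
            exons=((0, 100), (0, 150), (300, 400)),
            transcripts=({0, 2}, {1, 2}),
        )
        kinds = {p.kind for p in enumerate_patterns(plus)}
        assert kinds == {"alt5"}
        minus = make_gene(
            strand="-",
            exons=((0, 100), (0, 150), (300, 400)),
            transcripts=({0, 2}, {1, 2}),
        )
        assert {p.kind for p in enumerate_patterns(minus)} == {"alt3"}

    def test_cassette_pattern_si_equals_exon_si(self):
        """With junction/exon reads on a constructed cassette gene, the
        pattern record reproduces the exon-level differential SI."""
        ann = make_annotation([make_gene()], chrom_lengths={"chr1": 5000})
        exons = exon_table(ann)
        cols = [f"wt_{i}" for i in range(2)] + [f"ko_{i}" for i in range(2)]
        groups = {c: c.split("_")[0] for c in cols}
        rng = np.random.default_rng(7)
        counts = pd.DataFrame(
            rng.integers(50, 150, size=(3, 4)).astype(float),
            index=exons.index, columns=cols,
        )
        si = splicing_index(counts, exons)
        diff = differential_splicing(si, groups, "wt", "ko")
        pats = pattern_si(counts, exons, ann, groups, "wt", "ko")
        (row,) = pats[pats["pattern_kind"] == "cassette"].itertuples()
        assert row.exon_index == 1
        assert row.log2fc == pytest.approx(diff.loc[("g1", 1), "log2fc"])
        assert row.p == pytest.approx(diff.loc[("g1", 1), "p"])

    def test_mutually_exclusive_swap_gives_anticorrelated_records(self):
        gene = make_gene(
            exons=((0, 100), (200, 300), (400, 500), (600, 700)),
            transcripts=({0, 1, 3}, {0, 2, 3}),
        )
        ann = make_annotation([gene], chrom_lengths={"chr1": 5000})
        exons = exon_table(ann)
        cols = ["wt_0", "wt_1", "ko_0", "ko_1"]
        groups = {c: c.split("_")[0] for c in cols}
        # usage swaps between groups for exons 1 and 2
        counts = pd.DataFrame(
            {
                "wt_0": [100, 80, 20, 100],
                "wt_1": [100, 82, 18, 100],
                "ko_0": [100, 20, 80, 100],
                "ko_1": [100, 18, 82, 100],
            },
            index=exons.index,
            dtype=float,
        )
        pats = pattern_si(counts, exons, ann, groups, "wt", "ko")
        mxe = pats[pats["pattern_kind"] == "mutually_exclusive"]
        lfc = dict(zip(mxe["exon_index"], mxe["log2fc"]))
        assert lfc[1] < 0 < lfc[2]


class TestSizeFactors:
    def test_doubled_sample_gives_sqrt2_factors(self):
        counts = pd.DataFrame(
            {"s1": [10, 100, 40], "s2": [20, 200, 80]}, dtype=float
        )
        f = size_factors(counts)
        assert f["s1"] == pytest.approx(1 / math.sqrt(2))
        assert f["s2"] == pytest.approx(math.sqrt(2))

    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"a": [5, 10], "b": [5, 10]}, dtype=float)
        assert np.allclose(size_factors(counts), 1.0)

    def test_single_gene(self):
        counts = pd.DataFrame({"a": [4.0], "b": [16.0]})
        f = size_factors(counts)
        assert f["a"] == pytest.approx(0.5)
        assert f["b"] == pytest.approx(2.0)

    def test_no_all_nonzero_gene_is_an_error(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError):
            size_factors(counts)


class TestDifferentialExpression:
    def frame(self, rows):
        cols = ["wt_0", "wt_1", "wt_2", "ko_0", "ko_1", "ko_2"]
        groups = {c: c.split("_")[0] for c in cols}
        df = pd.DataFrame(rows, columns=cols, dtype=float)
        df.index = [f"g{i}" for i in range(len(df))]
        return df, groups

    def test_bh_adjustment_matches_hand_stepup(self):
        """BH of [0.001, 0.01, 0.02, 0.5] is [0.004, 0.02, 0.0267, 0.5]."""
        from clipsplice.clip import bh_adjust

        adj = bh_adjust(np.array([0.001, 0.01, 0.02, 0.5]))
        assert np.allclose(adj, [0.004, 0.02, 0.02 * 4 / 3, 0.5])

    def test_bh_monotone_and_at_least_raw(self):
        from clipsplice.clip import bh_adjust

        rng = np.random.default_rng(8)
        p = rng.uniform(size=200)
        q = bh_adjust(p)
        assert np.all(q >= p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_fold_change_filter_blocks_small_effects(self):
        rows = [[100, 101, 99, 140, 141, 139]]  # fc = 1.4, p tiny
        df, groups = self.frame(rows)
        out = differential_expression(df, groups, "wt", "ko")
        assert out["fc"].iloc[0] == pytest.approx(1.4, abs=0.01)
        assert out["padj"].iloc[0] < 0.05
        assert not out["significant"].iloc[0]

    def test_signed_fold_change_for_downregulation(self):
        rows = [[100, 100, 100, 50, 50, 50]]
        df, groups = self.frame(rows)
        out = differential_expression(df, groups, "wt", "ko")
        assert out["fc"].iloc[0] == pytest.approx(-2.0)

    def test_fewer_than_two_replicates_rejected(self):
        df = pd.DataFrame({"wt_0": [1.0], "ko_0": [1.0], "ko_1": [2.0]})
        groups = {"wt_0": "wt", "ko_0": "ko", "ko_1": "ko"}
        with pytest.raises(ValueError):
            differential_expression(df, groups, "wt", "ko")

    def test_null_simulation_yields_no_calls(self):
        from clipsplice.simulate import simulate_gene_count_matrix

        counts, groups = simulate_gene_count_matrix(
            1000, 4, seed=9
        )
        out = differential_expression(
            counts / size_factors(counts), groups, "wt", "ko"
        )
        assert out["significant"].sum() == 0
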