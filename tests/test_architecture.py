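"""Gene-organisation statistics."""

import warnings

import pytest

import glacialis as gl
from glacialis.architecture import (
    assembly_stats,
    classify_dark_sets,
    cluster_genes,
    find_nested_genes,
    gene_stats,
    intergenic_regions,
    intergenic_repeat_partition,
    single_exon_census,
    strand_change_histogram,
    transcript_support,
)
from glacialis.core_io import GeneModel, Interval, SeqRecord, TabularHit


def gene(gid, start, end, strand="+", scaffold="s1", exons=None):
    return GeneModel(gid, scaffold, strand, tuple(exons or [(start, end)]))


def hit(qid, length, pident, evalue=1e-30, bitscore=200.0, qstart=1):
    return TabularHit(qid, "subj", pident, length, 0, 0, qstart,
                      qstart + length - 1, 1, length, evalue, bitscore)


class TestIntergenicRegions:
    def test_simple_gap_length(self):
        regions = intergenic_regions([gene("a", 1, 100), gene("b", 201, 300)])
        assert [r.length for r in regions] == [100]

    def test_overlapping_genes_zero(self):
        regions = intergenic_regions([gene("a", 1, 100), gene("b", 50, 150)])
        assert [r.length for r in regions] == [0]

    def test_single_gene_no_regions(self):
        assert intergenic_regions([gene("a", 1, 100)]) == []


class TestClusters:
    def test_gap_at_threshold_clusters(self):
        clusters, n = cluster_genes([gene("a", 1, 100), gene("b", 5100, 5200)])
        assert len(clusters) == 1 and n == 2
        assert clusters[0].unidirectional

    def test_gap_over_threshold_no_cluster(self):
        clusters, n = cluster_genes([gene("a", 1, 100), gene("b", 5102, 5200)])
        assert clusters == [] and n == 0

    def test_mixed_strands_not_unidirectional(self):
        genes = [
            gene("a", 1, 100, "+"),
            gene("b", 201, 300, "-"),
            gene("c", 401, 500, "+"),
        ]
        clusters, n = cluster_genes(genes)
        assert len(clusters) == 1 and n == 3
        assert not clusters[0].unidirectional

    def test_cluster_sizes_sum_to_clustered_genes(self, default_sim):
        _cfg, sim = default_sim
        clusters, n = cluster_genes(sim.genes)
        assert sum(c.size for c in clusters) == n


class TestStrandWindows:
    def test_uniform_strand_single_window(self):
        genes = [gene(f"g{i}", i * 1000 + 1, i * 1000 + 100, "+") for i in range(10)]
        assert dict(strand_change_histogram(genes)) == {0: 1}

    def test_alternating_strands(self):
        genes = [
            gene(f"g{i}", i * 1000 + 1, i * 1000 + 100, "+-"[i % 2])
            for i in range(12)
        ]
        assert dict(strand_change_histogram(genes)) == {9: 3}

    def test_single_flip_mid_scaffold(self):
        strands = ["+"] * 6 + ["-"] * 5
        genes = [
            gene(f"g{i}", i * 1000 + 1, i * 1000 + 100, strands[i])
            for i in range(11)
        ]
        assert dict(strand_change_histogram(genes)) == {1: 2}

    def test_window_count_identity(self, default_sim):
        _cfg, sim = default_sim
        hist = strand_change_histogram(sim.genes)
        per_scaffold = {}
        for g in sim.genes:
            per_scaffold[g.scaffold_id] = per_scaffold.get(g.scaffold_id, 0) + 1
        expected = sum(max(0, n - 9) for n in per_scaffold.values())
        assert sum(hist.values()) == expected


class TestCensuses:
    def test_single_exon_fraction(self):
        genes = [
            gene("a", 1, 100),
            gene("b", 201, 400, exons=[(201, 250), (351, 400)]),
            gene("c", 501, 700, exons=[(501, 550), (651, 700)]),
            gene("d", 801, 1000, exons=[(801, 850), (951, 1000)]),
        ]
        assert single_exon_census(genes) == (1, 0.25)

    def test_all_multi_exon(self):
        genes = [gene("a", 1, 400, exons=[(1, 50), (351, 400)])]
        assert single_exon_census(genes) == (0, 0.0)

    def test_nested_in_intron(self):
        host = gene("host", 1, 2100, exons=[(1, 100), (2001, 2100)])
        inner = gene("in", 500, 900, "-")
        rep = find_nested_genes([host, inner])
        assert rep.hosts == {"host": [("in", 1)]}

    def test_overlap_with_exon_not_nested(self):
        host = gene("host", 1, 2100, exons=[(1, 100), (2001, 2100)])
        inner = gene("in", 50, 200)
        assert find_nested_genes([host, inner]).hosts == {}

    def test_planted_fifteen_nested_in_three_introns(self, default_sim):
        _cfg, sim = default_sim
        rep = find_nested_genes(sim.genes)
        assert rep.n_nested == 15
        (host_id,) = rep.hosts
        assert len(rep.hosts[host_id]) == 15
        assert rep.introns_occupied(host_id) == 3


class TestRepeatPartition:
    def region(self, length, start=1000):
        genes = [gene("a", 1, start), gene("b", start + length + 1, start + length + 100)]
        return intergenic_regions(genes)

    def test_fully_covered(self):
        regions = self.region(1000)
        cov = intergenic_repeat_partition(regions, [Interval("s1", 0, 5000)])
        assert cov["le"] == pytest.approx(1.0)

    def test_quarter_covered(self):
        regions = self.region(1000)
        cov = intergenic_repeat_partition(regions, [Interval("s1", 1000, 1250)])
        assert cov["le"] == pytest.approx(0.25)

    def test_no_repeats(self):
        regions = self.region(1000) + self.region(8000)
        cov = intergenic_repeat_partition(regions, [])
        assert cov == {"le": 0.0, "gt": 0.0}


class TestAssemblyStats:
    def test_n50_worked_case(self):
        scaffolds = [SeqRecord(f"s{i}", "A" * n) for i, n in enumerate([40, 30, 20, 10])]
        st = assembly_stats(scaffolds)
        assert st.n50_bp == 30
        assert st.max_scaffold_bp == 40 and st.total_bp == 100

    def test_single_scaffold(self):
        st = assembly_stats([SeqRecord("s", "ACGT" * 10)])
        assert st.n50_bp == 40

    def test_all_n_scaffold_gc_undefined(self):
        st = assembly_stats([SeqRecord("s", "N" * 100)])
        assert st.gc_percent is None and st.n_scaffolds == 1

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            assembly_stats([])


class TestGeneStats:
    SCAFFOLD = [SeqRecord("s1", "ACGT" * 500)]

    def test_mean_exons_and_intron_percent(self):
        genes = [
            gene("a", 1, 100),
            gene("b", 201, 500, exons=[(201, 250), (301, 350), (451, 500)]),
        ]
        st = gene_stats(genes, self.SCAFFOLD)
        assert st.mean_exons_per_gene == 2.0
        assert st.pct_genes_with_introns == 50.0

    def test_intron_length_from_exon_gap(self):
        genes = [gene("a", 1, 30, exons=[(1, 10), (21, 30)])]
        st = gene_stats(genes, self.SCAFFOLD)
        assert st.total_intron_length_bp == 10
        assert st.mean_intron_length_bp == 10.0

    def test_out_of_bounds_gene_named(self):
        genes = [gene("runaway", 1, 99999)]
        with pytest.raises(ValueError, match="runaway"):
            gene_stats(genes, self.SCAFFOLD)

    def test_matches_planted_truth(self, default_sim):
        _cfg, sim = default_sim
        st = gene_stats(sim.genes, sim.scaffolds)
        truth = sim.truth.genes
        n = len(truth)
        assert st.n_genes == n
        assert st.mean_exons_per_gene == pytest.approx(
            sum(i["n_exons"] for i in truth.values()) / n
        )
        assert st.total_exon_length_bp == sum(i["exon_bp"] for i in truth.values())
        assert st.total_intron_length_bp == sum(i["intron_bp"] for i in truth.values())
        assert st.pct_single_exon == pytest.approx(
            100.0 * sum(i["n_exons"] == 1 for i in truth.values()) / n
        )


class TestTranscriptSupport:
    GENES = [gene("a", 1, 1000)]  # spliced length 1000

    def test_supported(self):
        flags, pct = transcript_support(self.GENES, [hit("a", 600, 95.0)])
        assert flags["a"] and pct == 100.0

    def test_low_coverage_unsupported(self):
        flags, _ = transcript_support(self.GENES, [hit("a", 400, 95.0)])
        assert not flags["a"]

    def test_identity_boundary_strict(self):
        flags, _ = transcript_support(self.GENES, [hit("a", 900, 90.0)])
        assert not flags["a"]

    def test_unknown_query_warns_and_skips(self):
        with pytest.warns(UserWarning, match="ghost"):
            flags, _ = transcript_support(self.GENES, [hit("ghost", 900, 99.0)])
        assert not flags["a"]


class TestDarkSets:
    def test_mixed_set_not_dark(self):
        rep = classify_dark_sets({"set1": ["p1", "p2"]}, {"p1": True, "p2": False})
        assert rep.dark == {"set1": False}

    def test_all_uninformative_dark(self):
        rep = classify_dark_sets({"set1": ["p1", "p2"]}, {"p1": False, "p2": False})
        assert rep.dark == {"set1": True}
        assert rep.dark_set_fraction == 1.0

    def test_uncharacterized_only_hit_is_dark(self):
        # an "uncharacterized" hit is recorded as non-informative upstream
        rep = classify_dark_sets({"set1": ["p1"]}, {"p1": False})
        assert rep.dark["set1"]

    def test_missing_annotation_warns(self):
        with pytest.warns(UserWarning, match="p9"):
            rep = classify_dark_sets({"s": ["p9"]}, {})
        assert rep.dark["s"]
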