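"""Reference ranges, gVCF ingestion and consensus collapsing."""

import itertools

import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from phglite.graph import (
    MISSING,
    ConsensusParams,
    GvcfRecord,
    RawHaplotype,
    build_graph_from_panel,
    build_reference_ranges,
    collapse_range,
    haplotypes_per_range,
    ingest_taxon_calls,
    ranges_per_chromosome,
)


# ---------------------------------------------------------------------------
# reference ranges
# ---------------------------------------------------------------------------

class TestBuildReferenceRanges:
    @pytest.mark.parametrize(
        "genes, expected",
        [
            # extended flanks overlap -> single merged range
            ([(1000, 2000), (2400, 3000)], [(500, 3500)]),
            # gap 1000 > merge_gap 500 -> stay separate
            ([(1000, 2000), (4000, 5000)], [(500, 2500), (3500, 5500)]),
            # flank clamped at chromosome start
            ([(200, 800)], [(0, 1300)]),
        ],
    )
    def test_flank_and_merge(self, genes, expected):
        ranges = build_reference_ranges({"chr1": genes}, {"chr1": 100_000})
        assert [(r.start, r.end) for r in ranges] == expected
        assert all(r.informative for r in ranges)

    def test_gap_exactly_merge_gap_merges(self):
        # extended ends 2500, next starts 3000: gap 500 <= 500
        ranges = build_reference_ranges(
            {"chr1": [(1000, 2000), (3500, 4000)]}, {"chr1": 100_000}
        )
        assert [(r.start, r.end) for r in ranges] == [(500, 4500)]

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            build_reference_ranges({"chr1": [(100, 100)]}, {"chr1": 1000})
        with pytest.raises(ValueError):
            build_reference_ranges({"chrX": [(0, 10)]}, {"chr1": 1000})
        with pytest.raises(ValueError):
            build_reference_ranges({"chr1": [(0, 2000)]}, {"chr1": 1000})

    def test_merge_idempotent(self):
        rng = np.random.default_rng(5)
        genes = sorted(
            (int(s), int(s) + int(rng.integers(100, 2000)))
            for s in rng.choice(80_000, size=15, replace=False)
        )
        genes = [(s, e) for s, e in genes if e <= 100_000]
        ranges = build_reference_ranges({"chr1": genes}, {"chr1": 100_000})
        again = build_reference_ranges(
            {"chr1": [(r.start, r.end) for r in ranges]},
            {"chr1": 100_000},
            flank_bp=0,
        )
        assert [(r.start, r.end) for r in again] == [
            (r.start, r.end) for r in ranges
        ]

    def test_output_sorted_disjoint_dense_ids(self):
        ranges = build_reference_ranges(
            {"chr1": [(5000, 6000), (1000, 2000)], "chr2": [(100, 700)]},
            {"chr1": 100_000, "chr2": 50_000},
        )
        assert [r.range_id for r in ranges] == list(range(len(ranges)))
        for a, b in itertools.pairwise(r for r in ranges if r.chrom == "chr1"):
            assert a.end < b.start


# ---------------------------------------------------------------------------
# ingestion
# ---------------------------------------------------------------------------

class TestIngestTaxonCalls:
    def setup_method(self):
        self.ranges = build_reference_ranges(
            {"chr1": [(1000, 2000)]}, {"chr1": 100_000}
        )  # single range [500, 2500)

    def test_snp_in_ref_block(self):
        records = [
            GvcfRecord("chr1", 500, "A", None, end=1500),
            GvcfRecord("chr1", 1500, "A", "G", gt=(1, 1)),
            GvcfRecord("chr1", 1501, "C", None, end=2500),
        ]
        raws, skipped = ingest_taxon_calls("t1", records, self.ranges)
        raw = raws[0]
        assert skipped == 0
        assert raw.calls == {1500: 1}
        assert raw.allele_at(1500) == 1
        assert raw.allele_at(700) == 0          # inside ref block
        assert raw.allele_at(2499) == 0

    def test_record_outside_any_range_skipped(self):
        records = [GvcfRecord("chr1", 9000, "A", "G", gt=(1, 1))]
        raws, skipped = ingest_taxon_calls("t1", records, self.ranges)
        assert skipped == 1
        assert raws[0].calls == {}

    def test_heterozygous_call_stored_missing(self):
        records = [GvcfRecord("chr1", 1500, "A", "G", gt=(0, 1))]
        raws, _ = ingest_taxon_calls("t1", records, self.ranges)
        assert raws[0].calls[1500] == MISSING

    def test_uncovered_position_missing(self):
        raws, _ = ingest_taxon_calls("t1", [], self.ranges)
        assert raws[0].allele_at(1500) == MISSING

    def test_malformed_allele_rejected(self):
        with pytest.raises(ValueError):
            ingest_taxon_calls(
                "t1", [GvcfRecord("chr1", 1500, "A", "@", gt=(1, 1))], self.ranges
            )


# ---------------------------------------------------------------------------
# consensus collapsing
# ---------------------------------------------------------------------------

def _raw(taxon, calls, covered=((0, 10_000),)):
    return RawHaplotype(taxon, 0, dict(calls), [tuple(c) for c in covered])


class TestCollapseRange:
    def test_two_identical_one_divergent(self):
        # h3 differs at 2 sites on 10 kb: d = 0.0002 >= mxDiv -> two clusters
        h1 = _raw("t1", {100: 0, 200: 0})
        h2 = _raw("t2", {100: 0, 200: 0})
        h3 = _raw("t3", {100: 1, 200: 1})
        out = collapse_range([h1, h2, h3], 10_000, ConsensusParams(0.0001, 1))
        assert [set(h.taxa) for h in out] == [{"t1", "t2"}, {"t3"}]
        assert out[0].hap_id == 0 and out[1].hap_id == 1

    def test_single_difference_below_threshold_merges(self):
        # 1 difference but window 20 kb: d = 0.00005 < 0.0001 -> merge
        h1 = _raw("t1", {100: 0})
        h2 = _raw("t2", {100: 1})
        out = collapse_range([h1, h2], 20_000, ConsensusParams(0.0001, 1))
        assert len(out) == 1 and out[0].taxa == {"t1", "t2"}

    def test_mxdiv_zero_merges_only_identical(self):
        h1 = _raw("t1", {100: 1})
        h2 = _raw("t2", {100: 1})
        h3 = _raw("t3", {100: 0})
        out = collapse_range([h1, h2, h3], 10_000, ConsensusParams(0.0, 1))
        assert sorted(sorted(h.taxa) for h in out) == [["t1", "t2"], ["t3"]]

    def test_divergence_equal_to_mxdiv_does_not_merge(self):
        # exactly 1 variant per 10 kb is not below the threshold
        h1 = _raw("t1", {100: 0})
        h2 = _raw("t2", {100: 1})
        out = collapse_range([h1, h2], 10_000, ConsensusParams(0.0001, 1))
        assert len(out) == 2

    def test_consensus_majority_and_tie_to_ref(self):
        raws = [
            _raw("t1", {100: 1, 200: 1}),
            _raw("t2", {100: 1, 200: 0}),
            _raw("t3", {100: 0, 200: MISSING}),
        ]
        out = collapse_range(raws, 100, ConsensusParams(1.0, 1))  # force one cluster
        assert len(out) == 1
        assert out[0].calls[100] == 1        # majority alt
        assert out[0].calls[200] == 0        # 1 alt vs 1 ref: tie -> ref

    def test_all_missing_site_stays_missing(self):
        raws = [_raw("t1", {100: MISSING}), _raw("t2", {100: MISSING})]
        out = collapse_range(raws, 100, ConsensusParams(1.0, 1))
        assert out[0].calls[100] == MISSING

    def test_min_taxa_drops_small_clusters(self):
        h1 = _raw("t1", {100: 0})
        h2 = _raw("t2", {100: 0})
        h3 = _raw("t3", {100: 1, 200: 1, 300: 1})
        out = collapse_range([h1, h2, h3], 1000, ConsensusParams(0.0001, 2))
        assert len(out) == 1 and out[0].taxa == {"t1", "t2"}

    def test_errors(self):
        with pytest.raises(ValueError):
            collapse_range([], 100)
        with pytest.raises(ValueError):
            collapse_range([_raw("t1", {})], 0)

    def test_taxa_conserved_at_min_taxa_one(self):
        rng = np.random.default_rng(3)
        raws = [
            _raw(f"t{i}", {p: int(rng.integers(0, 2)) for p in range(0, 500, 50)})
            for i in range(8)
        ]
        out = collapse_range(raws, 10_000, ConsensusParams(0.0005, 1))
        assert sum(len(h.taxa) for h in out) == 8
        assert set().union(*(h.taxa for h in out)) == {f"t{i}" for i in range(8)}

    def test_cluster_count_monotone_in_mxdiv(self):
        rng = np.random.default_rng(9)
        raws = [
            _raw(f"t{i}", {p: int(rng.integers(0, 2)) for p in range(0, 1000, 100)})
            for i in range(6)
        ]
        counts = [
            len(collapse_range(raws, 10_000, ConsensusParams(mx, 1)))
            for mx in (0.0, 0.0001, 0.0003, 0.001, 0.01)
        ]
        assert counts == sorted(counts, reverse=True)

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_scipy_average_linkage_oracle(self, trial):
        """Cluster assignment equals an independent average-linkage cut
        (scipy UPGMA) on random 5-haplotype ranges."""
        rng = np.random.default_rng(100 + trial)
        n, length = 5, 10_000
        raws = [
            _raw(f"t{i}", {p: int(rng.integers(0, 2)) for p in range(0, 600, 100)})
            for i in range(n)
        ]
        mxdiv = float(rng.choice([0.0001, 0.0002, 0.0004, 0.001]))
        got = collapse_range(raws, length, ConsensusParams(mxdiv, 1))
        got_parts = sorted(tuple(sorted(h.taxa)) for h in got)

        sites = sorted({p for r in raws for p in r.calls})
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = sum(
                    raws[i].calls[p] != raws[j].calls[p] for p in sites
                ) / length
                D[i, j] = D[j, i] = d
        Z = linkage(squareform(D), method="average")
        labels = fcluster(Z, t=mxdiv * (1 - 1e-9), criterion="distance")
        oracle = {}
        for i, lab in enumerate(labels):
            oracle.setdefault(lab, []).append(f"t{i}")
        oracle_parts = sorted(tuple(sorted(v)) for v in oracle.values())
        assert got_parts == oracle_parts


# ---------------------------------------------------------------------------
# graph assembly
# ---------------------------------------------------------------------------

class TestGraphSummary:
    def test_published_scale_means(self):
        assert round(haplotypes_per_range(712_733, 106_484), 1) == 6.7
        assert int(ranges_per_chromosome(106_484, 21)) == 5070

    def test_single_range_single_hap(self):
        assert haplotypes_per_range(1, 1) == 1.0

    def test_graph_from_panel(self, scenario):
        g = scenario.graph
        s = g.summary()
        assert s["n_haplotypes"] / s["n_ranges"] == s["haplotypes_per_range"]
        # every range has at least one consensus haplotype
        assert all(len(g.haplotypes[r.range_id]) >= 1 for r in g.ranges)
        # taxa conservation: each range accounts for every founder once
        n_founders = scenario.config.n_founders
        for r in g.ranges:
            assert sum(len(h.taxa) for h in g.haplotypes[r.range_id]) == n_founders

    def test_zero_haplotype_range_rejected(self):
        from phglite.graph import build_graph, ReferenceRange

        with pytest.raises(ValueError):
            build_graph([ReferenceRange("chr1", 0, 100, 0)], {0: []})

    def test_mxdiv_zero_preserves_distinct_haplotypes(self):
        """Collapsing at zero divergence keeps every distinct raw haplotype."""
        rng = np.random.default_rng(17)
        raws = [
            _raw(f"t{i}", {p: int(rng.integers(0, 2)) for p in range(0, 300, 100)})
            for i in range(6)
        ]
        out = collapse_range(raws, 10_000, ConsensusParams(0.0, 1))
        distinct = {tuple(sorted(r.calls.items())) for r in raws}
        assert len(out) == len(distinct)
        for h in out:
            for t in h.taxa:
                raw = next(r for r in raws if r.taxon == t)
                assert raw.calls == h.calls


def test_save_load_roundtrip(tmp_path, scenario):
    from phglite.graph import load_graph, save_graph

    save_graph(scenario.graph, str(tmp_path / "g"))
    g2 = load_graph(str(tmp_path / "g"))
    assert g2.summary() == scenario.graph.summary()
    r0 = scenario.graph.ranges[0].range_id
    assert [h.taxa for h in g2.haplotypes[r0]] == [
        h.taxa for h in scenario.graph.haplotypes[r0]
    ]
    assert g2.haplotypes[r0][0].sequence == scenario.graph.haplotypes[r0][0].sequence
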