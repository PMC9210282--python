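import numpy as np
import pytest

from phglite import pipeline
from phglite.graph import ConsensusHaplotype, HaplotypeGraph, ReferenceRange
from phglite.mapping import RangeReadEvidence
from phglite.simulate import SimConfig


@pytest.fixture(scope="session")
def scenario():
    """One fully built synthetic study shared across tests."""
    return pipeline.build_scenario(SimConfig(seed=11))


def make_toy_graph(rng, n_ranges, max_states, chrom="chr1", taxa_pool=4):
    """Random single-chromosome graph: each range gets 1..max_states
    haplotypes with random non-empty taxa subsets (no sequences/sites)."""
    ranges = [
        ReferenceRange(chrom, i * 1000, (i + 1) * 1000, i) for i in range(n_ranges)
    ]
    names = [f"t{j}" for j in range(taxa_pool)]
    haplotypes = {}
    for r in ranges:
        n = int(rng.integers(1, max_states + 1))
        haps = []
        for hid in range(n):
            size = int(rng.integers(1, taxa_pool + 1))
            taxa = frozenset(rng.choice(names, size=size, replace=False))
            haps.append(ConsensusHaplotype(hid, r.range_id, taxa, {}))
        haplotypes[r.range_id] = haps
    sites = {r.range_id: [] for r in ranges}
    return HaplotypeGraph(ranges, haplotypes, sites, [chrom])


def make_toy_evidence(rng, graph, max_reads=8):
    """Random read evidence for a toy graph (some ranges left empty)."""
    evidence = {}
    for r in graph.ranges:
        n = int(rng.integers(0, max_reads + 1))
        if n == 0:
            continue
        haps = graph.haplotypes[r.range_id]
        counts = {}
        for _ in range(n):
            hid = int(rng.integers(0, len(haps)))
            counts[hid] = counts.get(hid, 0) + 1
        evidence[r.range_id] = RangeReadEvidence(r.range_id, n, counts)
    return evidence


@pytest.fixture
def toy_graph_factory():
    return make_toy_graph


@pytest.fixture
def toy_evidence_factory():
    return make_toy_evidence
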