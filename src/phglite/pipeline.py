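"""End-to-end orchestration: simulate -> build graph -> map -> impute -> score.

These helpers wire the individual modules into the benchmark loops used to
characterise imputation accuracy versus coverage, sequencing protocol,
parental representation and introgression content.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import evaluate, graph as graphmod, impute, mapping, simulate
from .evaluate import SiteKey
from .graph import ConsensusParams, HaplotypeGraph, ReferenceRange
from .impute import HmmParams
from .mapping import KmerIndex
from .simulate import RilSample, SimConfig


@dataclass
class Scenario:
    """A fully built synthetic study: genome, panel, graph and k-mer index."""

    config: SimConfig
    genome: dict[str, str]
    genes: dict[str, list[tuple[int, int]]]
    ranges: list[ReferenceRange]
    founders: dict[str, dict[tuple[str, int], str]]
    graph: HaplotypeGraph
    index: KmerIndex

    def site_keys(self) -> list[SiteKey]:
        return [
            (s.chrom, s.pos, s.ref, s.alt) for s in self.graph.site_catalog()
        ]


def build_scenario(
    config: SimConfig,
    exclude_taxa: Sequence[str] = (),
    params: ConsensusParams = ConsensusParams(),
    k: int = 21,
) -> Scenario:
    """Simulate a reference + founder panel and build the haplotype graph.

    ``exclude_taxa`` drops founders from the database (the simulated truth
    still knows them) — used for donor-removal and single-parent contrasts.
    """
    genome, genes = simulate.simulate_reference(config)
    founders = simulate.simulate_founders(genome, genes, config)
    ranges = graphmod.build_reference_ranges(
        genes, {c: len(s) for c, s in genome.items()}
    )
    panel = {
        name: simulate.founder_gvcf_records(genome, v, config.chrom_names())
        for name, v in founders.items()
        if name not in exclude_taxa
    }
    g = graphmod.build_graph_from_panel(ranges, panel, params, reference=genome)
    index = mapping.index_haplotypes(g, k=k)
    return Scenario(config, genome, genes, ranges, founders, g, index)


def impute_sample(
    scenario: Scenario,
    reads1: Sequence[tuple[str, str]],
    reads2: Sequence[tuple[str, str]] | None = None,
    params: HmmParams = HmmParams(),
) -> dict[SiteKey, int]:
    """Map reads, decode per-chromosome paths and return imputed genotypes."""
    evidence, _ = mapping.map_reads(
        [s for _, s in reads1],
        scenario.index,
        [s for _, s in reads2] if reads2 is not None else None,
    )
    paths = impute.decode_all(scenario.graph, evidence, params)
    return impute.path_genotypes(paths, scenario.graph)


def database_site_maf(graph: HaplotypeGraph) -> dict[SiteKey, float]:
    """Per-site minor allele frequency in the haplotype database, with
    haplotypes weighted by their member-taxa counts."""
    out: dict[SiteKey, float] = {}
    for r in graph.ranges:
        haps = graph.haplotypes[r.range_id]
        for s in graph.sites[r.range_id]:
            n = alt = 0
            for h in haps:
                code = h.calls.get(s.pos, graphmod.MISSING)
                if code != graphmod.MISSING:
                    n += len(h.taxa)
                    if code == 1:
                        alt += len(h.taxa)
            p = alt / n if n else 0.0
            out[(s.chrom, s.pos, s.ref, s.alt)] = min(p, 1.0 - p)
    return out


def score_ril(
    scenario: Scenario,
    ril: RilSample,
    protocol: str = "capture",
    coverage: float | None = None,
    n_reads: int | None = None,
    seed_offset: int = 0,
    hmm: HmmParams = HmmParams(),
    digest_sites: Mapping[str, Sequence[int]] | None = None,
    restrict: set[SiteKey] | None = None,
) -> evaluate.AccuracyReport:
    """Simulate reads for one RIL, impute it, score against its truth."""
    sample_genome = simulate.realize_sample(scenario.genome, ril.variants)
    reads1, reads2 = simulate.simulate_reads(
        sample_genome,
        protocol,
        scenario.config,
        ranges=scenario.ranges,
        digest_sites=digest_sites,
        coverage=coverage,
        n_reads=n_reads,
        seed_offset=seed_offset,
    )
    imputed = impute_sample(scenario, reads1, reads2, hmm)
    keys = scenario.site_keys()
    if restrict is not None:
        keys = [k for k in keys if k in restrict]
    truth = simulate.truth_genotypes(ril, keys)
    return evaluate.concordance(imputed, truth, ril.name)


def ril_benchmark(
    config: SimConfig,
    coverage: float = 0.1,
    protocol: str = "capture",
    parents: tuple[str, str] = ("founder1", "founder2"),
    exclude_taxa: Sequence[str] = (),
    hmm: HmmParams = HmmParams(),
) -> list[evaluate.AccuracyReport]:
    """Accuracy of imputing a simulated RIL family at one coverage level."""
    scenario = build_scenario(config, exclude_taxa=exclude_taxa)
    digest = (
        simulate.digest_genome(
            scenario.genome,
            config.motif_a,
            config.motif_b,
            config.digest_max_dist,
        )
        if protocol == "gbs"
        else None
    )
    rils = simulate.simulate_rils(
        parents[0], parents[1], scenario.founders, scenario.genome, config
    )
    return [
        score_ril(
            scenario,
            ril,
            protocol=protocol,
            coverage=coverage,
            seed_offset=i + 1,
            hmm=hmm,
            digest_sites=digest,
        )
        for i, ril in enumerate(rils)
    ]


def mean_accuracy(reports: Sequence[evaluate.AccuracyReport]) -> float:
    return float(np.mean([r.accuracy for r in reports]))


def introgression_contrast(
    config: SimConfig, coverage: float = 0.5
) -> tuple[float, float]:
    """Imputation accuracy over the introgressed interval for a carrier,
    with and without the donor haplotype in the graph.

    The carrier sample is the donor accession itself; accuracy is measured
    on the interval sites catalogued by both graphs so the two pipelines
    are compared on identical ground.
    """
    donor = config.founder_names()[config.introgression_donor]
    with_donor = build_scenario(config)
    without_donor = build_scenario(config, exclude_taxa=(donor,))
    chrom = config.chrom_names()[config.introgression_chrom]
    lo, hi = config.introgression_interval

    def interval_keys(s: Scenario) -> set[SiteKey]:
        return {
            k for k in s.site_keys() if k[0] == chrom and lo <= k[1] < hi
        }

    shared = interval_keys(with_donor) & interval_keys(without_donor)
    carrier_genome = simulate.realize_sample(
        with_donor.genome, with_donor.founders[donor]
    )
    truth = {
        k: (1 if with_donor.founders[donor].get((k[0], k[1])) == k[3] else 0)
        for k in shared
    }
    accs = []
    for scen in (with_donor, without_donor):
        reads1, reads2 = simulate.simulate_reads(
            carrier_genome,
            "capture",
            config,
            ranges=scen.ranges,
            coverage=coverage,
            seed_offset=99,
        )
        imputed = impute_sample(scen, reads1, reads2)
        accs.append(evaluate.concordance(imputed, truth, "carrier").accuracy)
    return accs[0], accs[1]
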