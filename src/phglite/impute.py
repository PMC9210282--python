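"""HMM path decoding and genotype emission.

Each chromosome is an HMM whose hidden states at step t are the consensus
haplotypes of the t-th reference range.  Emission: each read assigned to the
range is consistent with the true haplotype with probability 1 - eps, so

    log P(evidence | h) = hits(h) * log(1 - eps) + (n - hits(h)) * log(eps)

and a range with no (or fewer than minReads) reads emits log 1 = 0 for every
state, so the path still traverses it (minReads = 0 semantics: every range,
hence every catalogued site, is imputed).  Transition: haplotype pairs in
consecutive ranges sharing at least one member taxon carry unnormalised
weight 1 - switch_p, disjoint pairs switch_p / n_states_next; rows are
renormalised.  Paths are single (inbred panels), genotypes emitted
homozygous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .graph import MISSING, ConsensusHaplotype, HaplotypeGraph
from .mapping import RangeReadEvidence


@dataclass(frozen=True)
class HmmParams:
    """Decoding parameters.

    eps: probability a read is inconsistent with the true haplotype.
    switch_p: per-boundary probability of a taxon discontinuity.
    minReads: minimum reads per range for evidence to be used (0 means every
    range is imputed regardless of coverage).
    """

    eps: float = 0.01
    switch_p: float = 0.001
    minReads: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.eps < 0.5:
            raise ValueError("eps must be in (0, 0.5)")
        if not 0 < self.switch_p < 1:
            raise ValueError("switch_p must be in (0, 1)")
        if self.minReads < 0:
            raise ValueError("minReads must be >= 0")


@dataclass
class HaplotypePath:
    """Decoded haplotype path for one chromosome."""

    chrom: str
    states: dict[int, int]              # range_id -> chosen hap_id
    scores: dict[int, float] = field(default_factory=dict)
    log_prob: float = 0.0


def emission_loglik(
    evidence: RangeReadEvidence | None,
    hap_id: int,
    params: HmmParams,
    range_haps: Sequence[ConsensusHaplotype] | None = None,
) -> float:
    """Log-likelihood of a range's read evidence under one haplotype."""
    if range_haps is not None and all(h.hap_id != hap_id for h in range_haps):
        raise ValueError(f"hap_id {hap_id} absent from range")
    if evidence is None or evidence.n_reads == 0 or evidence.n_reads < params.minReads:
        return 0.0
    hits = evidence.hit_counts.get(hap_id, 0)
    return hits * math.log1p(-params.eps) + (evidence.n_reads - hits) * math.log(
        params.eps
    )


def _transition_row(
    h_from: ConsensusHaplotype,
    next_haps: Sequence[ConsensusHaplotype],
    params: HmmParams,
) -> np.ndarray:
    n = len(next_haps)
    w = np.array(
        [
            (1.0 - params.switch_p)
            if h_from.taxa & h.taxa
            else params.switch_p / n
            for h in next_haps
        ]
    )
    return np.log(w / w.sum())


def transition_logprob(
    h_from: ConsensusHaplotype,
    h_to: ConsensusHaplotype,
    next_haps: Sequence[ConsensusHaplotype],
    params: HmmParams,
) -> float:
    """Normalised log transition probability between consecutive ranges."""
    row = _transition_row(h_from, next_haps, params)
    for i, h in enumerate(next_haps):
        if h.hap_id == h_to.hap_id:
            return float(row[i])
    raise ValueError("h_to not among next range's haplotypes")


def _chrom_layers(
    graph: HaplotypeGraph, chrom: str
) -> list[tuple[int, list[ConsensusHaplotype]]]:
    layers = [
        (r.range_id, graph.haplotypes[r.range_id]) for r in graph.ranges_on(chrom)
    ]
    if not layers:
        raise ValueError(f"no reference ranges on chromosome {chrom!r}")
    return layers


def _emission_vec(
    haps: Sequence[ConsensusHaplotype],
    evidence: Mapping[int, RangeReadEvidence],
    rid: int,
    params: HmmParams,
) -> np.ndarray:
    ev = evidence.get(rid)
    return np.array([emission_loglik(ev, h.hap_id, params) for h in haps])


def viterbi_path(
    graph: HaplotypeGraph,
    evidence: Mapping[int, RangeReadEvidence],
    params: HmmParams,
    chrom: str,
) -> HaplotypePath:
    """Maximum-a-posteriori haplotype path along one chromosome.

    Uniform initial distribution; ties broken toward the lowest hap_id
    (states are scanned in hap_id order and argmax keeps the first maximum).
    All arithmetic in log domain.
    """
    layers = _chrom_layers(graph, chrom)
    rid0, haps0 = layers[0]
    delta = _emission_vec(haps0, evidence, rid0, params) - math.log(len(haps0))
    back: list[np.ndarray] = []
    for (rid_prev, haps_prev), (rid, haps) in zip(layers, layers[1:]):
        trans = np.stack([_transition_row(h, haps, params) for h in haps_prev])
        scores = delta[:, None] + trans          # prev x next
        back.append(np.argmax(scores, axis=0))   # first max -> lowest prev id
        delta = np.max(scores, axis=0) + _emission_vec(haps, evidence, rid, params)
    last = int(np.argmax(delta))
    total = float(delta[last])
    idx = [last]
    for bp in reversed(back):
        idx.append(int(bp[idx[-1]]))
    idx.reverse()
    states = {rid: haps[i].hap_id for (rid, haps), i in zip(layers, idx)}
    scores = {
        rid: float(
            emission_loglik(evidence.get(rid), haps[i].hap_id, params)
        )
        for (rid, haps), i in zip(layers, idx)
    }
    return HaplotypePath(chrom, states, scores, total)


def forward_loglik(
    graph: HaplotypeGraph,
    evidence: Mapping[int, RangeReadEvidence],
    params: HmmParams,
    chrom: str,
) -> float:
    """Log of the total probability summed over all haplotype paths."""
    from scipy.special import logsumexp

    layers = _chrom_layers(graph, chrom)
    rid0, haps0 = layers[0]
    alpha = _emission_vec(haps0, evidence, rid0, params) - math.log(len(haps0))
    for (rid_prev, haps_prev), (rid, haps) in zip(layers, layers[1:]):
        trans = np.stack([_transition_row(h, haps, params) for h in haps_prev])
        alpha = logsumexp(alpha[:, None] + trans, axis=0) + _emission_vec(
            haps, evidence, rid, params
        )
    return float(logsumexp(alpha))


def decode_all(
    graph: HaplotypeGraph,
    evidence: Mapping[int, RangeReadEvidence],
    params: HmmParams = HmmParams(),
) -> dict[str, HaplotypePath]:
    """Viterbi-decode every chromosome independently."""
    return {c: viterbi_path(graph, evidence, params, c) for c in graph.chroms}


# ---------------------------------------------------------------------------
# genotype emission
# ---------------------------------------------------------------------------

def path_genotypes(
    paths: Mapping[str, HaplotypePath], graph: HaplotypeGraph
) -> dict[tuple[str, int, str, str], int]:
    """Imputed allele code at every catalogued site (MISSING where the
    chosen consensus is missing)."""
    out: dict[tuple[str, int, str, str], int] = {}
    for r in graph.ranges:
        hap_id = paths[r.chrom].states[r.range_id]
        hap = next(h for h in graph.haplotypes[r.range_id] if h.hap_id == hap_id)
        for s in graph.sites[r.range_id]:
            out[(s.chrom, s.pos, s.ref, s.alt)] = hap.calls.get(s.pos, MISSING)
    return out


def emit_genotypes(
    paths: Mapping[str, HaplotypePath],
    graph: HaplotypeGraph,
    taxon_name: str,
) -> list[str]:
    """Render the imputed genotypes as sorted VCF 4.2 lines (one sample,
    homozygous calls, 1-based positions)."""
    lines = ["##fileformat=VCFv4.2", "##source=phglite"]
    chrom_max: dict[str, int] = {}
    for r in graph.ranges:
        chrom_max[r.chrom] = max(chrom_max.get(r.chrom, 0), r.end)
    for c in graph.chroms:
        lines.append(f"##contig=<ID={c},length={chrom_max[c]}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + taxon_name
    )
    geno = path_genotypes(paths, graph)
    order = {c: i for i, c in enumerate(graph.chroms)}
    for (chrom, pos, ref, alt), code in sorted(
        geno.items(), key=lambda kv: (order[kv[0][0]], kv[0][1])
    ):
        if code == MISSING:
            gt = "./."
        else:
            gt = f"{code}/{code}"
        lines.append(f"{chrom}\t{pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gt}")
    return lines


def write_vcf(path: str, lines: Sequence[str]) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
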