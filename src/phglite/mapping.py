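"""K-mer pseudo-mapping of reads to consensus haplotypes.

Low-coverage reads are assigned to reference ranges by canonical k-mer
lookup against the consensus haplotype sequences.  A read whose k-mers hit
more than one range is discarded (uniquely-mapped-reads semantics); within
its range a read is "consistent" with every haplotype achieving the maximal
k-mer hit count.  Paired reads must agree on the range or the pair is
dropped.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from .graph import HaplotypeGraph

log = logging.getLogger(__name__)

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class KmerIndex:
    """Canonical k-mer -> {(range_id, hap_id)} over haplotype sequences."""

    k: int
    lookup: dict[str, frozenset[tuple[int, int]]]

    def __len__(self) -> int:
        return len(self.lookup)


@dataclass
class RangeReadEvidence:
    """Per-range read support: total reads and per-haplotype hit counts."""

    range_id: int
    n_reads: int = 0
    hit_counts: dict[int, int] = field(default_factory=dict)


@dataclass
class MappingStats:
    assigned: int = 0
    too_short: int = 0
    no_hits: int = 0
    multi_range: int = 0
    pair_disagree: int = 0

    @property
    def discarded(self) -> int:
        return self.too_short + self.no_hits + self.multi_range + self.pair_disagree


def index_haplotypes(graph: HaplotypeGraph, k: int = 21) -> KmerIndex:
    """Index every consensus haplotype sequence by canonical k-mer.

    Haplotypes shorter than ``k`` contribute nothing (warned).  Requires
    realised sequences.
    """
    if k % 2 == 0 or not 11 <= k <= 31:
        raise ValueError("k must be odd and in [11, 31]")
    lookup: dict[str, set[tuple[int, int]]] = {}
    for r in graph.ranges:
        for h in graph.haplotypes[r.range_id]:
            if h.sequence is None:
                raise ValueError(
                    f"haplotype {r.range_id}/{h.hap_id} has no realised sequence"
                )
            if len(h.sequence) < k:
                log.warning(
                    "haplotype %d/%d shorter than k=%d", r.range_id, h.hap_id, k
                )
                continue
            seq = h.sequence
            key = (r.range_id, h.hap_id)
            for i in range(len(seq) - k + 1):
                lookup.setdefault(canonical(seq[i : i + k]), set()).add(key)
    return KmerIndex(k, {km: frozenset(v) for km, v in lookup.items()})


def _read_hits(seq: str, index: KmerIndex) -> dict[tuple[int, int], int]:
    hits: dict[tuple[int, int], int] = {}
    k = index.k
    for i in range(len(seq) - k + 1):
        occ = index.lookup.get(canonical(seq[i : i + k]))
        if occ:
            for key in occ:
                hits[key] = hits.get(key, 0) + 1
    return hits


def _assign(seq: str, index: KmerIndex, stats: MappingStats):
    """Return (range_id, consistent hap set) or None if discarded."""
    if len(seq) < index.k:
        stats.too_short += 1
        return None
    hits = _read_hits(seq.upper(), index)
    if not hits:
        stats.no_hits += 1
        return None
    ranges = {rid for rid, _ in hits}
    if len(ranges) > 1:
        stats.multi_range += 1
        return None
    rid = next(iter(ranges))
    best = max(hits.values())
    consistent = frozenset(hid for (_, hid), c in hits.items() if c == best)
    return rid, consistent


def map_reads(
    reads: Iterable[str],
    index: KmerIndex,
    reads2: Iterable[str] | None = None,
) -> tuple[dict[int, RangeReadEvidence], MappingStats]:
    """Aggregate per-range read evidence from single or paired reads.

    For pairs, both mates must individually map uniquely to the same range;
    a disagreeing or partially unmapped pair is discarded whole.  Each
    surviving mate contributes one read of evidence with its own consistent
    haplotype set.  Aggregation is order-invariant.
    """
    stats = MappingStats()
    evidence: dict[int, RangeReadEvidence] = {}

    def add(rid: int, consistent: frozenset[int]) -> None:
        ev = evidence.setdefault(rid, RangeReadEvidence(rid))
        ev.n_reads += 1
        for hid in consistent:
            ev.hit_counts[hid] = ev.hit_counts.get(hid, 0) + 1
        stats.assigned += 1

    if reads2 is None:
        for seq in reads:
            res = _assign(seq, index, stats)
            if res is not None:
                add(*res)
    else:
        for seq1, seq2 in zip(reads, reads2):
            sub = MappingStats()
            r1 = _assign(seq1, index, sub)
            r2 = _assign(seq2, index, sub)
            if r1 is None or r2 is None:
                # propagate individual-discard reasons for both mates
                stats.too_short += sub.too_short
                stats.no_hits += sub.no_hits
                stats.multi_range += sub.multi_range
                if r1 is not None or r2 is not None:
                    stats.pair_disagree += 1
                continue
            if r1[0] != r2[0]:
                stats.pair_disagree += 2
                continue
            add(*r1)
            add(*r2)
    return evidence, stats


# ---------------------------------------------------------------------------
# FASTQ I/O
# ---------------------------------------------------------------------------

def read_fastq(path: str) -> Iterator[str]:
    """Yield read sequences from a FASTQ file (gzipped or plain)."""
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "rt") as fh:
        for i, line in enumerate(fh):
            if i % 4 == 1:
                yield line.strip()


def write_fastq(path: str, reads: Sequence[tuple[str, str]]) -> None:
    """Write (name, seq) pairs as FASTQ with uniform quality."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_evidence_tsv(path: str, evidence: dict[int, RangeReadEvidence]) -> None:
    with open(path, "w") as fh:
        fh.write("range_id\tn_reads\thap_id\thit_count\n")
        for rid in sorted(evidence):
            ev = evidence[rid]
            for hid in sorted(ev.hit_counts):
                fh.write(f"{rid}\t{ev.n_reads}\t{hid}\t{ev.hit_counts[hid]}\n")


def read_evidence_tsv(path: str) -> dict[int, RangeReadEvidence]:
    evidence: dict[int, RangeReadEvidence] = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            rid_s, n_s, hid_s, c_s = line.split("\t")
            ev = evidence.setdefault(int(rid_s), RangeReadEvidence(int(rid_s)))
            ev.n_reads = int(n_s)
            ev.hit_counts[int(hid_s)] = int(c_s)
    return evidence
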