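"""Haplotype-graph construction.

A practical haplotype graph stores, for every gene-anchored *reference
range*, the set of consensus haplotypes observed in a founder panel.  The
graph is built in three steps:

1. :func:`build_reference_ranges` turns gene models into flanked, merged,
   non-overlapping "informative" intervals.
2. :func:`ingest_taxon_calls` loads one accession's gVCF-style calls
   (variant records plus reference blocks) into per-range raw haplotypes.
3. :func:`collapse_range` clusters raw haplotypes whose pairwise divergence
   stays below ``mxDiv`` (differences per bp of range length) into consensus
   haplotypes; :func:`build_graph` assembles the result.

Coordinates are 0-based half-open internally; VCF I/O is 1-based.
"""

from __future__ import annotations

import bisect
import logging
import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)

#: allele code for a missing call
MISSING = -1
#: allele code for the reference allele
REF = 0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class ReferenceRange:
    """A gene-anchored genomic interval, one column of the graph."""

    chrom: str
    start: int
    end: int
    range_id: int
    informative: bool = True

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"range end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class Site:
    """A catalogued bi-allelic variant site."""

    chrom: str
    pos: int          # 0-based
    ref: str
    alt: str


@dataclass
class RawHaplotype:
    """One accession's calls over one reference range.

    ``calls`` holds the taxon's own genotyped variant positions (allele
    code, :data:`MISSING` for heterozygous source calls); ``covered`` holds
    the merged intervals backed by data (variant records and gVCF reference
    blocks).  Positions inside ``covered`` but absent from ``calls`` are
    implicitly reference; positions outside are missing.
    """

    taxon: str
    range_id: int
    calls: dict[int, int] = field(default_factory=dict)
    covered: list[tuple[int, int]] = field(default_factory=list)
    alleles: dict[int, tuple[str, str]] = field(default_factory=dict)

    def allele_at(self, pos: int) -> int:
        if pos in self.calls:
            return self.calls[pos]
        for s, e in self.covered:
            if s <= pos < e:
                return REF
        return MISSING


@dataclass(frozen=True)
class ConsensusParams:
    """Clustering parameters for consensus collapsing.

    mxDiv is the maximum within-cluster divergence in differences per bp of
    range length; the wheat default 0.0001 merges haplotypes with fewer than
    one difference per 10 kb.  minTaxa = 1 retains singleton haplotypes.
    """

    mxDiv: float = 0.0001
    minTaxa: int = 1

    def __post_init__(self) -> None:
        if self.mxDiv < 0:
            raise ValueError("mxDiv must be >= 0")
        if self.minTaxa < 1:
            raise ValueError("minTaxa must be >= 1")


@dataclass
class ConsensusHaplotype:
    """Merged representative of a cluster of raw haplotypes."""

    hap_id: int
    range_id: int
    taxa: frozenset[str]
    calls: dict[int, int]
    sequence: str | None = None


@dataclass
class HaplotypeGraph:
    """Ordered reference ranges with their consensus haplotypes.

    ``sites`` is the per-range catalogue of variable positions (union over
    consensus haplotypes); ``chroms`` preserves chromosome order.
    """

    ranges: list[ReferenceRange]
    haplotypes: dict[int, list[ConsensusHaplotype]]
    sites: dict[int, list[Site]]
    chroms: list[str]

    def ranges_on(self, chrom: str) -> list[ReferenceRange]:
        return [r for r in self.ranges if r.chrom == chrom]

    def range_by_id(self, range_id: int) -> ReferenceRange:
        r = self.ranges[range_id] if range_id < len(self.ranges) else None
        if r is None or r.range_id != range_id:
            r = next(x for x in self.ranges if x.range_id == range_id)
        return r

    @property
    def n_ranges(self) -> int:
        return len(self.ranges)

    @property
    def n_haplotypes(self) -> int:
        return sum(len(h) for h in self.haplotypes.values())

    def site_catalog(self) -> list[Site]:
        out: list[Site] = []
        for r in self.ranges:
            out.extend(self.sites[r.range_id])
        return out

    def summary(self) -> dict[str, float]:
        return {
            "n_chromosomes": len(self.chroms),
            "n_ranges": self.n_ranges,
            "n_haplotypes": self.n_haplotypes,
            "n_sites": sum(len(s) for s in self.sites.values()),
            "haplotypes_per_range": haplotypes_per_range(
                self.n_haplotypes, self.n_ranges
            ),
            "ranges_per_chromosome": ranges_per_chromosome(
                self.n_ranges, len(self.chroms)
            ),
        }


def haplotypes_per_range(n_haplotypes: int, n_ranges: int) -> float:
    """Mean consensus haplotypes per informative reference range."""
    if n_ranges <= 0:
        raise ValueError("n_ranges must be positive")
    return n_haplotypes / n_ranges


def ranges_per_chromosome(n_ranges: int, n_chroms: int) -> float:
    """Mean reference ranges per chromosome."""
    if n_chroms <= 0:
        raise ValueError("n_chroms must be positive")
    return n_ranges / n_chroms


# ---------------------------------------------------------------------------
# step 1: reference ranges
# ---------------------------------------------------------------------------

def build_reference_ranges(
    gene_models: Mapping[str, Sequence[tuple[int, int]]],
    chrom_lengths: Mapping[str, int],
    flank_bp: int = 500,
    merge_gap_bp: int = 500,
) -> list[ReferenceRange]:
    """Build informative reference ranges from gene models.

    Each gene interval is extended ``flank_bp`` in both directions, clamped
    to the chromosome, and extended intervals that overlap or whose gap is
    at most ``merge_gap_bp`` are merged.  Output is sorted by (chrom, start)
    with dense ``range_id``; chromosome order follows ``chrom_lengths``.
    """
    for chrom, genes in gene_models.items():
        if chrom not in chrom_lengths:
            raise ValueError(f"unknown chromosome {chrom!r}")
        for s, e in genes:
            if e <= s:
                raise ValueError(f"invalid gene interval {chrom}:{s}-{e}")
            if s < 0 or e > chrom_lengths[chrom]:
                raise ValueError(
                    f"gene {chrom}:{s}-{e} outside chromosome bounds"
                )

    ranges: list[ReferenceRange] = []
    rid = 0
    for chrom in chrom_lengths:
        genes = sorted(gene_models.get(chrom, ()))
        if not genes:
            continue
        clen = chrom_lengths[chrom]
        extended = [
            (max(0, s - flank_bp), min(clen, e + flank_bp)) for s, e in genes
        ]
        merged = [list(extended[0])]
        for s, e in extended[1:]:
            if s - merged[-1][1] <= merge_gap_bp:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            ranges.append(ReferenceRange(chrom, s, e, rid, informative=True))
            rid += 1
    return ranges


class _RangeLocator:
    """Bisect-based point-in-range lookup over sorted disjoint ranges."""

    def __init__(self, ranges: Sequence[ReferenceRange]):
        self._by_chrom: dict[str, tuple[list[int], list[ReferenceRange]]] = {}
        for r in ranges:
            starts, rs = self._by_chrom.setdefault(r.chrom, ([], []))
            starts.append(r.start)
            rs.append(r)

    def find(self, chrom: str, pos: int) -> ReferenceRange | None:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        starts, rs = entry
        i = bisect.bisect_right(starts, pos) - 1
        if i >= 0 and rs[i].contains(pos):
            return rs[i]
        return None


# ---------------------------------------------------------------------------
# step 2: gVCF ingestion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GvcfRecord:
    """A minimal gVCF-style record (0-based position).

    A reference block has ``alt is None`` and ``end > pos + len(ref)``
    semantics via the END key; a variant record has a concrete alt allele
    and a genotype ``gt`` (pair of allele indices).
    """

    chrom: str
    pos: int
    ref: str
    alt: str | None
    gt: tuple[int, int] = (0, 0)
    end: int | None = None       # half-open end of a reference block

    @property
    def span(self) -> tuple[int, int]:
        if self.end is not None:
            return self.pos, self.end
        return self.pos, self.pos + len(self.ref)


_VALID_BASES = frozenset("ACGTN")


def ingest_taxon_calls(
    taxon: str,
    records: Iterable[GvcfRecord],
    ranges: Sequence[ReferenceRange],
) -> tuple[dict[int, RawHaplotype], int]:
    """Load one taxon's gVCF records into per-range raw haplotypes.

    Returns ``(raw_by_range_id, n_skipped)`` where skipped counts records
    falling outside every informative range.  Heterozygous variant calls are
    stored as :data:`MISSING`.  One RawHaplotype is produced per informative
    range (empty if no record touches it).
    """
    locator = _RangeLocator([r for r in ranges if r.informative])
    raws = {
        r.range_id: RawHaplotype(taxon=taxon, range_id=r.range_id)
        for r in ranges
        if r.informative
    }
    skipped = 0
    for rec in records:
        if rec.alt is not None:
            if not (set(rec.ref) <= _VALID_BASES and set(rec.alt) <= _VALID_BASES):
                raise ValueError(f"malformed allele in record {rec}")
            rng = locator.find(rec.chrom, rec.pos)
            if rng is None:
                skipped += 1
                continue
            raw = raws[rng.range_id]
            a, b = rec.gt
            if a != b:
                raw.calls[rec.pos] = MISSING
            else:
                raw.calls[rec.pos] = a
            raw.alleles[rec.pos] = (rec.ref, rec.alt)
            raw.covered.append((rec.pos, rec.pos + len(rec.ref)))
        else:
            s, e = rec.span
            hit = False
            # a block may straddle several ranges; clip to each
            for rng in _ranges_overlapping(ranges, rec.chrom, s, e):
                raws[rng.range_id].covered.append(
                    (max(s, rng.start), min(e, rng.end))
                )
                hit = True
            if not hit:
                skipped += 1
    for raw in raws.values():
        raw.covered = _merge_intervals(raw.covered)
    if skipped:
        log.info("%s: %d records outside informative ranges", taxon, skipped)
    return raws, skipped


def _ranges_overlapping(
    ranges: Sequence[ReferenceRange], chrom: str, start: int, end: int
) -> list[ReferenceRange]:
    return [
        r
        for r in ranges
        if r.informative and r.chrom == chrom and r.start < end and start < r.end
    ]


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


# ---------------------------------------------------------------------------
# step 3: consensus collapsing
# ---------------------------------------------------------------------------

def pairwise_divergence(
    h1: RawHaplotype, h2: RawHaplotype, sites: Sequence[int], range_length_bp: int
) -> float:
    """Differences per bp of range length at sites non-missing in both."""
    diff = 0
    for pos in sites:
        a, b = h1.allele_at(pos), h2.allele_at(pos)
        if a != MISSING and b != MISSING and a != b:
            diff += 1
    return diff / range_length_bp


def collapse_range(
    raws: Sequence[RawHaplotype],
    range_length_bp: int,
    params: ConsensusParams = ConsensusParams(),
) -> list[ConsensusHaplotype]:
    """Average-linkage agglomerative collapsing of raw haplotypes.

    Cluster pairs merge while their average pairwise divergence is below
    ``mxDiv`` (identical haplotypes always merge).  Clusters smaller than
    ``minTaxa`` are dropped.  The consensus allele at each site is the
    majority among non-missing members, ties resolved to the reference
    allele; an all-missing site stays missing.  Returned haplotypes carry
    dense ``hap_id`` ordered by descending taxa count, then lexicographic
    taxa.
    """
    if not raws:
        raise ValueError("collapse_range requires at least one raw haplotype")
    if range_length_bp <= 0:
        raise ValueError("range_length_bp must be positive")

    sites = sorted({p for r in raws for p in r.calls})
    n = len(raws)
    dist = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            d = pairwise_divergence(raws[i], raws[j], sites, range_length_bp)
            dist[i][j] = dist[j][i] = d

    clusters: list[list[int]] = [[i] for i in range(n)]
    while len(clusters) > 1:
        best = None
        best_d = float("inf")
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = _avg_linkage(clusters[a], clusters[b], dist)
                if d < best_d:
                    best_d = d
                    best = (a, b)
        # strict "< mxDiv" with a relative guard so a cross-pair average that
        # is exactly mxDiv in exact arithmetic never merges by float rounding
        if best is None or not (best_d < params.mxDiv * (1 - 1e-9) or best_d == 0.0):
            break
        a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]

    out: list[ConsensusHaplotype] = []
    range_id = raws[0].range_id
    for members in clusters:
        taxa = frozenset(raws[i].taxon for i in members)
        if len(taxa) < params.minTaxa:
            continue
        calls: dict[int, int] = {}
        for pos in sites:
            votes = Counter(
                raws[i].allele_at(pos)
                for i in members
                if raws[i].allele_at(pos) != MISSING
            )
            if not votes:
                calls[pos] = MISSING
                continue
            top = max(votes.values())
            winners = sorted(a for a, c in votes.items() if c == top)
            # majority; ties -> reference allele if tied, else lowest code
            calls[pos] = REF if (len(winners) > 1 and REF in winners) else winners[0]
        out.append(ConsensusHaplotype(-1, range_id, taxa, calls))

    out.sort(key=lambda h: (-len(h.taxa), tuple(sorted(h.taxa))))
    for hid, h in enumerate(out):
        h.hap_id = hid
    return out


def _avg_linkage(a: list[int], b: list[int], dist: list[list[float]]) -> float:
    return sum(dist[i][j] for i in a for j in b) / (len(a) * len(b))


# ---------------------------------------------------------------------------
# graph assembly
# ---------------------------------------------------------------------------

def build_graph(
    ranges: Sequence[ReferenceRange],
    consensus: Mapping[int, Sequence[ConsensusHaplotype]],
    site_alleles: Mapping[int, Mapping[int, tuple[str, str]]] | None = None,
    reference: Mapping[str, str] | None = None,
) -> HaplotypeGraph:
    """Assemble ranges and per-range consensus haplotypes into a graph.

    ``site_alleles`` maps range_id -> pos -> (ref, alt) for the catalogued
    sites; when ``reference`` sequences are supplied each haplotype's
    ``sequence`` is realised by editing the reference slice with its alt
    calls (required before k-mer indexing).
    """
    informative = [r for r in ranges if r.informative]
    haplotypes: dict[int, list[ConsensusHaplotype]] = {}
    sites: dict[int, list[Site]] = {}
    for r in informative:
        haps = list(consensus.get(r.range_id, ()))
        if not haps:
            raise ValueError(f"range {r.range_id} has no consensus haplotype")
        haplotypes[r.range_id] = haps
        positions = sorted({p for h in haps for p in h.calls})
        alleles = dict(site_alleles.get(r.range_id, {})) if site_alleles else {}
        sites[r.range_id] = [
            Site(r.chrom, p, *alleles.get(p, ("N", "N"))) for p in positions
        ]
    chroms: list[str] = []
    for r in informative:
        if r.chrom not in chroms:
            chroms.append(r.chrom)
    graph = HaplotypeGraph(list(informative), haplotypes, sites, chroms)
    if reference is not None:
        realize_sequences(graph, reference)
    return graph


def realize_sequences(graph: HaplotypeGraph, reference: Mapping[str, str]) -> None:
    """Fill each consensus haplotype's nucleotide sequence.

    The reference slice over the range is edited with the haplotype's alt
    alleles (right to left so indels do not shift later edits); missing or
    reference calls leave the reference base.
    """
    for r in graph.ranges:
        refseq = reference[r.chrom][r.start : r.end]
        alleles = {s.pos: (s.ref, s.alt) for s in graph.sites[r.range_id]}
        for h in graph.haplotypes[r.range_id]:
            seq = refseq
            for pos in sorted(h.calls, reverse=True):
                if h.calls[pos] == 1 and pos in alleles:
                    ref_a, alt_a = alleles[pos]
                    off = pos - r.start
                    seq = seq[:off] + alt_a + seq[off + len(ref_a):]
            h.sequence = seq


# ---------------------------------------------------------------------------
# panel-level convenience + persistence
# ---------------------------------------------------------------------------

def build_graph_from_panel(
    ranges: Sequence[ReferenceRange],
    panel: Mapping[str, Iterable[GvcfRecord]],
    params: ConsensusParams = ConsensusParams(),
    reference: Mapping[str, str] | None = None,
) -> HaplotypeGraph:
    """Ingest a whole founder panel and collapse every informative range."""
    raws_by_range: dict[int, list[RawHaplotype]] = {
        r.range_id: [] for r in ranges if r.informative
    }
    alleles_by_range: dict[int, dict[int, tuple[str, str]]] = {
        r.range_id: {} for r in ranges if r.informative
    }
    for taxon, records in panel.items():
        raws, _ = ingest_taxon_calls(taxon, records, ranges)
        for rid, raw in raws.items():
            raws_by_range[rid].append(raw)
            alleles_by_range[rid].update(raw.alleles)
    by_id = {r.range_id: r for r in ranges}
    consensus = {
        rid: collapse_range(raws, by_id[rid].length, params)
        for rid, raws in raws_by_range.items()
    }
    return build_graph(ranges, consensus, alleles_by_range, reference)


def save_graph(graph: HaplotypeGraph, outdir: str) -> None:
    """Persist a graph as plain text: ranges.bed, sites.tsv, haplotypes.tsv,
    optional sequences.fa, and a summary.txt."""
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "ranges.bed"), "w") as fh:
        for r in graph.ranges:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\trange_{r.range_id}\n")
    with open(os.path.join(outdir, "sites.tsv"), "w") as fh:
        fh.write("range_id\tchrom\tpos\tref\talt\n")
        for r in graph.ranges:
            for s in graph.sites[r.range_id]:
                fh.write(f"{r.range_id}\t{s.chrom}\t{s.pos}\t{s.ref}\t{s.alt}\n")
    any_seq = False
    with open(os.path.join(outdir, "haplotypes.tsv"), "w") as fh:
        fh.write("range_id\thap_id\ttaxa\tcalls\n")
        for r in graph.ranges:
            for h in graph.haplotypes[r.range_id]:
                calls = ",".join(f"{p}:{c}" for p, c in sorted(h.calls.items()))
                fh.write(
                    f"{r.range_id}\t{h.hap_id}\t{','.join(sorted(h.taxa))}\t{calls}\n"
                )
                any_seq = any_seq or h.sequence is not None
    if any_seq:
        with open(os.path.join(outdir, "sequences.fa"), "w") as fh:
            for r in graph.ranges:
                for h in graph.haplotypes[r.range_id]:
                    if h.sequence:
                        fh.write(f">r{r.range_id}_h{h.hap_id}\n{h.sequence}\n")
    with open(os.path.join(outdir, "summary.txt"), "w") as fh:
        for k, v in graph.summary().items():
            fh.write(f"{k}\t{v}\n")


def load_graph(indir: str) -> HaplotypeGraph:
    """Load a graph persisted by :func:`save_graph`."""
    ranges: list[ReferenceRange] = []
    with open(os.path.join(indir, "ranges.bed")) as fh:
        for line in fh:
            chrom, s, e, name = line.rstrip("\n").split("\t")
            ranges.append(ReferenceRange(chrom, int(s), int(e), int(name.split("_")[1])))
    sites: dict[int, list[Site]] = {r.range_id: [] for r in ranges}
    with open(os.path.join(indir, "sites.tsv")) as fh:
        next(fh)
        for line in fh:
            rid, chrom, pos, ref, alt = line.rstrip("\n").split("\t")
            sites[int(rid)].append(Site(chrom, int(pos), ref, alt))
    haplotypes: dict[int, list[ConsensusHaplotype]] = {r.range_id: [] for r in ranges}
    with open(os.path.join(indir, "haplotypes.tsv")) as fh:
        next(fh)
        for line in fh:
            rid_s, hid_s, taxa_s, calls_s = line.rstrip("\n").split("\t")
            calls = {}
            if calls_s:
                for kv in calls_s.split(","):
                    p, c = kv.split(":")
                    calls[int(p)] = int(c)
            haplotypes[int(rid_s)].append(
                ConsensusHaplotype(
                    int(hid_s), int(rid_s), frozenset(taxa_s.split(",")), calls
                )
            )
    seq_path = os.path.join(indir, "sequences.fa")
    if os.path.exists(seq_path):
        seqs: dict[str, str] = {}
        name = None
        with open(seq_path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith(">"):
                    name = line[1:]
                    seqs[name] = ""
                else:
                    seqs[name] += line
        for rid, haps in haplotypes.items():
            for h in haps:
                h.sequence = seqs.get(f"r{rid}_h{h.hap_id}")
    chroms: list[str] = []
    for r in ranges:
        if r.chrom not in chroms:
            chroms.append(r.chrom)
    return HaplotypeGraph(ranges, haplotypes, sites, chroms)
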