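"""Synthetic genome, founder panel, RIL population and read simulator.

Emulates the inputs of a gene-anchored haplotype-graph study on a desk-scale
polyploid-like genome: chromosomes carry gene islands in a repeat-rich
background, a founder panel includes one deeply divergent introgression
donor, biparental RILs are mosaics of two founders, and reads can be drawn
under capture-like (gene-space), GBS-like (restriction-site-anchored) or
skim-like (whole-genome) protocols at coverages from 0.01x up.

Divergence is modelled as independent per-bp mutation sprinkling rather
than a coalescent; this produces realistic haplotype structure for graph
collapsing and HMM decoding but not a realistic LD decay curve.  All
variants are bi-allelic SNPs with a deterministic ref -> alt transition so
that every founder shares the same alt allele at a position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .evaluate import MISSING, CoverageSpec, reads_for_coverage
from .graph import GvcfRecord, ReferenceRange
from .mapping import revcomp

BASES = np.array(list("ACGT"))
#: deterministic transition partner for alt alleles
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

#: subgenome label cycle for chromosomes (wheat-like A/B/D groups)
GROUP_CYCLE = ("A", "B", "D")


@dataclass
class SimConfig:
    """Study conditions for the synthetic population.

    Default scale: 2 chromosomes x 200 kb with 20 genes of ~2 kb each in an
    80%-repetitive background (wheat-like), a 6-founder panel diverging at
    2 mutations/kb inside genes (10x less in the intergenic background),
    one donor founder carrying a 10x-diverged introgression on chromosome 1,
    and 20 RILs with Poisson(1.5) crossovers per chromosome and 6 selfing
    generations.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_len: int = 200_000
    n_genes_per_chrom: int = 20
    gene_len_mean: int = 2_000
    gene_len_sd: int = 300
    repeat_fraction: float = 0.8
    repeat_motif_len: int = 200
    n_repeat_motifs: int = 5
    n_founders: int = 6
    founder_gene_rate: float = 0.002
    founder_intergenic_rate: float = 0.0002
    group_divergence: dict[str, float] = field(
        default_factory=lambda: {"A": 1.0, "B": 1.0, "D": 0.4}
    )
    introgression_donor: int = 5            # founder index carrying it
    introgression_chrom: int = 0
    introgression_interval: tuple[int, int] = (75_000, 125_000)
    introgression_multiplier: float = 10.0
    n_rils: int = 20
    crossover_mean: float = 1.5
    selfing_generations: int = 6
    read_len: int = 150
    fragment_len: int = 300
    gbs_read_len: int = 100
    error_rate: float = 0.002
    coverage: float = 0.1
    motif_a: str = "CTGCAG"                 # PstI
    motif_b: str = "CCGG"                   # MspI
    digest_max_dist: int = 250
    #: motifs kept out of the repeat library: methylation-sensitive enzymes
    #: (PstI) do not cut the methylated repeat fraction, which is what makes
    #: GBS a complexity-reduction protocol enriched toward low-copy sequence
    repeat_exclude_motifs: tuple[str, ...] = ("CTGCAG",)

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    def genome_groups(self) -> dict[str, str]:
        return {
            name: GROUP_CYCLE[i % len(GROUP_CYCLE)]
            for i, name in enumerate(self.chrom_names())
        }

    def founder_names(self) -> list[str]:
        return [f"founder{i + 1}" for i in range(self.n_founders)]


Variants = dict[tuple[str, int], str]       # (chrom, pos) -> alt base


# ---------------------------------------------------------------------------
# reference genome
# ---------------------------------------------------------------------------

def simulate_reference(
    config: SimConfig,
) -> tuple[dict[str, str], dict[str, list[tuple[int, int]]]]:
    """Simulate chromosomes (gene islands in repeat background) + gene BED.

    Genes are placed in evenly spaced slots with random jitter so they never
    overlap; the intergenic background is tiled with motifs from a small
    repeat library at ``repeat_fraction``, unique sequence otherwise.
    Deterministic per config.seed.
    """
    rng = np.random.default_rng([config.seed, 101])
    excluded = set(config.repeat_exclude_motifs) | {
        revcomp(m) for m in config.repeat_exclude_motifs
    }
    motifs = []
    while len(motifs) < config.n_repeat_motifs:
        m = "".join(rng.choice(BASES, size=config.repeat_motif_len))
        if not any(x in m for x in excluded):
            motifs.append(m)
    genome: dict[str, str] = {}
    genes: dict[str, list[tuple[int, int]]] = {}
    for chrom in config.chrom_names():
        tiles = []
        filled = 0
        while filled < config.chrom_len:
            if config.repeat_fraction > 0 and rng.random() < config.repeat_fraction:
                tile = motifs[rng.integers(len(motifs))]
            else:
                tile = "".join(rng.choice(BASES, size=config.repeat_motif_len))
            tiles.append(tile)
            filled += len(tile)
        seq = "".join(tiles)[: config.chrom_len]
        slot = config.chrom_len // config.n_genes_per_chrom
        chrom_genes = []
        for g in range(config.n_genes_per_chrom):
            glen = int(
                np.clip(
                    rng.normal(config.gene_len_mean, config.gene_len_sd),
                    200,
                    slot - 1200,  # keep >500 bp of background per side
                )
            )
            lo = g * slot + 600
            hi = (g + 1) * slot - 600 - glen
            start = int(rng.integers(lo, max(hi, lo + 1)))
            gene_seq = "".join(rng.choice(BASES, size=glen))
            seq = seq[:start] + gene_seq + seq[start + glen :]
            chrom_genes.append((start, start + glen))
        genome[chrom] = seq
        genes[chrom] = chrom_genes
    return genome, genes


# ---------------------------------------------------------------------------
# founder panel
# ---------------------------------------------------------------------------

def _sprinkle(
    rng: np.random.Generator, intervals: Sequence[tuple[int, int]], rate: float
) -> list[int]:
    out: list[int] = []
    for s, e in intervals:
        n = rng.poisson(rate * (e - s))
        if n:
            out.extend(int(p) for p in rng.integers(s, e, size=n))
    return sorted(set(out))


def simulate_founders(
    genome: Mapping[str, str],
    genes: Mapping[str, Sequence[tuple[int, int]]],
    config: SimConfig,
) -> dict[str, Variants]:
    """Sprinkle per-founder mutations; the donor founder gets an elevated
    divergence haplotype over the introgression interval.

    Genic intervals mutate at founder_gene_rate x the chromosome's
    group-divergence multiplier; the intergenic background at
    founder_intergenic_rate.  Alt alleles are the transition partner of the
    reference base, so all founders share the alt at a shared position.
    """
    if config.founder_gene_rate == 0 and config.introgression_multiplier > 1:
        raise ValueError("zero divergence contradicts introgression settings")
    rng = np.random.default_rng([config.seed, 202])
    groups = config.genome_groups()
    chrom_names = config.chrom_names()
    founders: dict[str, Variants] = {}
    for fi, name in enumerate(config.founder_names()):
        variants: Variants = {}
        for chrom in chrom_names:
            mult = config.group_divergence.get(groups[chrom], 1.0)
            gene_ivs = list(genes[chrom])
            inter_ivs = _complement(gene_ivs, len(genome[chrom]))
            pos_list = _sprinkle(rng, gene_ivs, config.founder_gene_rate * mult)
            pos_list += _sprinkle(
                rng, inter_ivs, config.founder_intergenic_rate * mult
            )
            if (
                fi == config.introgression_donor
                and chrom == chrom_names[config.introgression_chrom]
            ):
                lo, hi = config.introgression_interval
                extra_rate = (
                    config.founder_gene_rate
                    * mult
                    * (config.introgression_multiplier - 1.0)
                )
                pos_list += _sprinkle(
                    rng,
                    [(max(s, lo), min(e, hi)) for s, e in gene_ivs if s < hi and e > lo],
                    extra_rate,
                )
            for pos in sorted(set(pos_list)):
                ref = genome[chrom][pos]
                if ref in _TRANSITION:
                    variants[(chrom, pos)] = _TRANSITION[ref]
        founders[name] = variants
    return founders


def _complement(
    intervals: Sequence[tuple[int, int]], length: int
) -> list[tuple[int, int]]:
    out = []
    prev = 0
    for s, e in sorted(intervals):
        if s > prev:
            out.append((prev, s))
        prev = max(prev, e)
    if prev < length:
        out.append((prev, length))
    return out


def founder_gvcf_records(
    genome: Mapping[str, str], variants: Variants, chroms: Sequence[str]
) -> list[GvcfRecord]:
    """Render a founder's variants as gVCF-style records with reference
    blocks covering the rest of every chromosome (full-coverage assumption)."""
    records: list[GvcfRecord] = []
    by_chrom: dict[str, list[int]] = {c: [] for c in chroms}
    for (chrom, pos), _ in variants.items():
        by_chrom[chrom].append(pos)
    for chrom in chroms:
        prev = 0
        for pos in sorted(by_chrom[chrom]):
            if pos > prev:
                records.append(
                    GvcfRecord(chrom, prev, genome[chrom][prev], None, end=pos)
                )
            ref = genome[chrom][pos]
            records.append(
                GvcfRecord(chrom, pos, ref, variants[(chrom, pos)], gt=(1, 1))
            )
            prev = pos + 1
        clen = len(genome[chrom])
        if prev < clen:
            records.append(
                GvcfRecord(chrom, prev, genome[chrom][prev], None, end=clen)
            )
    return records


def realize_sample(genome: Mapping[str, str], variants: Variants) -> dict[str, str]:
    """Apply SNP variants to the reference to get a sample's genome."""
    out = {}
    for chrom, seq in genome.items():
        chars = list(seq)
        for (c, pos), alt in variants.items():
            if c == chrom:
                chars[pos] = alt
        out[chrom] = "".join(chars)
    return out


# ---------------------------------------------------------------------------
# RIL population
# ---------------------------------------------------------------------------

@dataclass
class RilSample:
    """One recombinant inbred line: mosaic variants, parental painting and
    residual-heterozygous positions (masked to missing downstream)."""

    name: str
    variants: Variants
    painting: dict[str, list[tuple[int, int, str]]]   # (start, end, parent)
    het_positions: set[tuple[str, int]]


def simulate_rils(
    parent_a: str,
    parent_b: str,
    founders: Mapping[str, Variants],
    genome: Mapping[str, str],
    config: SimConfig,
    seed_offset: int = 0,
) -> list[RilSample]:
    """Biparental RILs: Poisson crossovers, uniform breakpoints, alleles
    copied from the active parent, residual heterozygosity 2^-generations.

    Residual-het positions are drawn per line among the sites segregating
    between the parents; they are reported in ``het_positions`` and their
    genotype is treated as missing (inbred-panel het policy).
    """
    if founders[parent_a] == founders[parent_b]:
        import logging

        logging.getLogger(__name__).warning(
            "identical parents %s, %s: no segregating sites", parent_a, parent_b
        )
    rng = np.random.default_rng([config.seed, 303, seed_offset])
    seg = sorted(
        k
        for k in set(founders[parent_a]) | set(founders[parent_b])
        if founders[parent_a].get(k) != founders[parent_b].get(k)
    )
    het_frac = 0.5 ** config.selfing_generations
    rils = []
    for i in range(config.n_rils):
        variants: Variants = {}
        painting: dict[str, list[tuple[int, int, str]]] = {}
        for chrom, seq in genome.items():
            n_co = rng.poisson(config.crossover_mean)
            breaks = sorted(int(b) for b in rng.integers(1, len(seq), size=n_co))
            bounds = [0] + breaks + [len(seq)]
            current = parent_a if rng.random() < 0.5 else parent_b
            segs = []
            for s, e in zip(bounds, bounds[1:]):
                segs.append((s, e, current))
                for (c, pos), alt in founders[current].items():
                    if c == chrom and s <= pos < e:
                        variants[(c, pos)] = alt
                current = parent_b if current == parent_a else parent_a
            painting[chrom] = segs
        het = {
            seg[j]
            for j in range(len(seg))
            if rng.random() < het_frac
        }
        rils.append(RilSample(f"ril{i + 1}", variants, painting, het))
    return rils


def truth_genotypes(
    ril: RilSample, site_keys: Sequence[tuple[str, int, str, str]]
) -> dict[tuple[str, int, str, str], int]:
    """Truth allele codes for a RIL at the given catalogued sites
    (residual-het positions become missing)."""
    out = {}
    for chrom, pos, ref, alt in site_keys:
        if (chrom, pos) in ril.het_positions:
            out[(chrom, pos, ref, alt)] = MISSING
        elif ril.variants.get((chrom, pos)) == alt:
            out[(chrom, pos, ref, alt)] = 1
        else:
            out[(chrom, pos, ref, alt)] = 0
    return out


# ---------------------------------------------------------------------------
# in-silico restriction digest (GBS)
# ---------------------------------------------------------------------------

def digest_genome(
    genome: Mapping[str, str],
    motif_a: str = "CTGCAG",
    motif_b: str = "CCGG",
    max_dist: int = 250,
) -> dict[str, list[int]]:
    """PstI/MspI-style in-silico digest.

    Finds all occurrences of motif_a (both strands) and keeps those with a
    motif_b occurrence (both strands) within max_dist bp; returns sorted
    per-chromosome site positions.
    """
    if not motif_a or not motif_b:
        raise ValueError("motifs must be non-empty")
    out: dict[str, list[int]] = {}
    for chrom, seq in genome.items():
        a_pos = sorted(set(_find_motif(seq, motif_a)) | set(_find_motif(seq, revcomp(motif_a))))
        b_pos = sorted(set(_find_motif(seq, motif_b)) | set(_find_motif(seq, revcomp(motif_b))))
        retained = []
        import bisect

        for p in a_pos:
            i = bisect.bisect_left(b_pos, p - max_dist)
            if i < len(b_pos) and b_pos[i] <= p + max_dist:
                retained.append(p)
        out[chrom] = retained
    return out


def _find_motif(seq: str, motif: str) -> list[int]:
    out = []
    start = 0
    while True:
        i = seq.find(motif, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _apply_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = np.array(list(seq))
    err = rng.random(len(arr)) < error_rate
    if err.any():
        for i in np.nonzero(err)[0]:
            choices = [b for b in "ACGT" if b != arr[i]]
            arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def capture_target_bp(ranges: Sequence[ReferenceRange]) -> int:
    return sum(r.length for r in ranges)


def simulate_reads(
    sample_genome: Mapping[str, str],
    protocol: str,
    config: SimConfig,
    ranges: Sequence[ReferenceRange] | None = None,
    digest_sites: Mapping[str, Sequence[int]] | None = None,
    coverage: float | None = None,
    n_reads: int | None = None,
    seed_offset: int = 0,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]] | None]:
    """Simulate reads from a sample's genome under one protocol.

    capture: paired 2 x read_len fragments whose starts are uniform within
    the informative reference ranges (target = summed range length).
    gbs: single-end gbs_read_len reads anchored at digest sites (target =
    n_sites x gbs_read_len).  skim: paired fragments uniform genome-wide
    (target = genome length).  Read count follows reads_for_coverage unless
    ``n_reads`` (reads or pairs) is given.  Deterministic per seed.
    """
    rng = np.random.default_rng([config.seed, 404, seed_offset])
    cov = coverage if coverage is not None else config.coverage
    if protocol == "capture":
        if not ranges:
            raise ValueError("capture protocol requires reference ranges")
        target = capture_target_bp(ranges)
        paired = True
        rlen = config.read_len
    elif protocol == "gbs":
        if digest_sites is None:
            raise ValueError("gbs protocol requires digest sites")
        n_sites = sum(len(v) for v in digest_sites.values())
        target = n_sites * config.gbs_read_len
        paired = False
        rlen = config.gbs_read_len
    elif protocol == "skim":
        target = sum(len(s) for s in sample_genome.values())
        paired = True
        rlen = config.read_len
    else:
        raise ValueError(f"unknown protocol {protocol!r}")

    if n_reads is None:
        n_reads = reads_for_coverage(
            CoverageSpec(target, cov, rlen, paired=paired)
        )
    if n_reads == 0:
        import logging

        logging.getLogger(__name__).warning("coverage yields zero reads")
        return [], ([] if paired else None)

    reads1: list[tuple[str, str]] = []
    reads2: list[tuple[str, str]] | None = [] if paired else None

    if protocol == "capture":
        weights = np.array([r.length for r in ranges], dtype=float)
        weights /= weights.sum()
        picks = rng.choice(len(ranges), size=n_reads, p=weights)
        for i, ri in enumerate(picks):
            r = ranges[ri]
            seq = sample_genome[r.chrom]
            start = int(rng.integers(r.start, r.end))
            _add_pair(reads1, reads2, seq, start, rlen, config, rng, f"cap{i}")
    elif protocol == "gbs":
        flat = [
            (chrom, p) for chrom, ps in digest_sites.items() for p in ps
        ]
        if not flat:
            return [], None
        picks = rng.integers(len(flat), size=n_reads)
        for i, fi in enumerate(picks):
            chrom, p = flat[fi]
            seq = sample_genome[chrom]
            if rng.random() < 0.5:
                frag = seq[p : p + rlen]
            else:
                frag = revcomp(seq[max(0, p - rlen + len(config.motif_a)) : p + len(config.motif_a)])
            if len(frag) >= config.gbs_read_len // 2:
                reads1.append((f"gbs{i}", _apply_errors(frag, config.error_rate, rng)))
    else:  # skim
        chroms = list(sample_genome)
        lens = np.array([len(sample_genome[c]) for c in chroms], dtype=float)
        probs = lens / lens.sum()
        picks = rng.choice(len(chroms), size=n_reads, p=probs)
        for i, ci in enumerate(picks):
            seq = sample_genome[chroms[ci]]
            start = int(rng.integers(0, max(len(seq) - config.fragment_len, 1)))
            _add_pair(reads1, reads2, seq, start, rlen, config, rng, f"skim{i}")
    return reads1, reads2


def _add_pair(
    reads1: list,
    reads2: list | None,
    seq: str,
    start: int,
    rlen: int,
    config: SimConfig,
    rng: np.random.Generator,
    name: str,
) -> None:
    frag_end = min(start + config.fragment_len, len(seq))
    r1 = seq[start : start + rlen]
    reads1.append((name + "/1", _apply_errors(r1, config.error_rate, rng)))
    if reads2 is not None:
        r2 = revcomp(seq[max(frag_end - rlen, start) : frag_end])
        reads2.append((name + "/2", _apply_errors(r2, config.error_rate, rng)))


# ---------------------------------------------------------------------------
# text output
# ---------------------------------------------------------------------------

def write_fasta(path: str, genome: Mapping[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gene_bed(path: str, genes: Mapping[str, Sequence[tuple[int, int]]]) -> None:
    with open(path, "w") as fh:
        for chrom, ivs in genes.items():
            for i, (s, e) in enumerate(ivs):
                fh.write(f"{chrom}\t{s}\t{e}\tgene_{chrom}_{i}\n")


def write_gvcf(
    path: str,
    genome: Mapping[str, str],
    variants: Variants,
    sample: str,
) -> None:
    """Write a founder's calls as a gVCF-style single-sample VCF (reference
    blocks carry an END info key)."""
    chroms = list(genome)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c},length={len(genome[c])}>\n")
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="Block end">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for rec in founder_gvcf_records(genome, variants, chroms):
            if rec.alt is None:
                fh.write(
                    f"{rec.chrom}\t{rec.pos + 1}\t.\t{rec.ref}\t<NON_REF>\t.\t.\t"
                    f"END={rec.end}\tGT\t0/0\n"
                )
            else:
                fh.write(
                    f"{rec.chrom}\t{rec.pos + 1}\t.\t{rec.ref}\t{rec.alt}\t.\t.\t"
                    f".\tGT\t1/1\n"
                )


def read_gvcf(path: str) -> list[GvcfRecord]:
    """Parse a gVCF-style VCF (END key honoured) into GvcfRecords."""
    import pysam

    records: list[GvcfRecord] = []
    with pysam.VariantFile(path) as vf:
        sample = list(vf.header.samples)[0]
        for rec in vf:
            alt = rec.alts[0] if rec.alts else None
            if alt in (None, "<NON_REF>"):
                # pysam exposes the END info key as rec.stop (0-based exclusive)
                records.append(
                    GvcfRecord(rec.chrom, rec.pos - 1, rec.ref, None, end=int(rec.stop))
                )
            else:
                gt = rec.samples[sample].get("GT") or (0, 0)
                gt = tuple(0 if g is None else int(g) for g in gt)
                if len(gt) == 1:
                    gt = (gt[0], gt[0])
                records.append(
                    GvcfRecord(rec.chrom, rec.pos - 1, rec.ref, alt, gt=gt)
                )
    return records
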