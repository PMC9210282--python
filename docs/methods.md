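# Methods

`phglite` is a desk-scale implementation of a practical haplotype graph
(PHG): a database of founder haplotypes organised by gene-anchored genomic
intervals, used to impute genome-wide genotypes from very low-coverage
sequencing by finding the best haplotype path through the graph. This note
records the models, the parameters that matter, the synthetic study design,
and the numerical choices.

## The graph model

**Reference ranges.** The genome is partitioned into *informative* reference
ranges derived from gene models: each gene interval is extended 500 bp in
both directions (`flank_bp`), clamped to the chromosome, and extended
intervals that overlap or lie within 500 bp of each other (`merge_gap_bp`)
are merged. Intergenic sequence between ranges is not stored: in a highly
repetitive genome, read placement there is unreliable, so reads landing
outside ranges are ignored downstream. Coordinates are 0-based half-open
internally; VCF I/O is 1-based, BED 0-based.

**Raw haplotypes.** Each accession's gVCF-style calls (variant records plus
reference blocks with an END key) are projected onto the ranges: a position
covered by a homozygous variant record takes that allele, positions inside
reference blocks are reference, and uncovered positions are missing.
Heterozygous source calls are stored as missing — the intended panels are
inbred lines, where residual heterozygous calls are most likely artifacts.

**Consensus collapsing.** Within a range, raw haplotypes are clustered by
average-linkage agglomeration on pairwise divergence

d(h1, h2) = (# sites where both are non-missing and differ) / range length (bp),

merging while the cross-pair average divergence is strictly below `mxDiv`
(identical haplotypes always merge, so `mxDiv = 0` deduplicates exactly).
The default `mxDiv = 1e-4` merges haplotypes with fewer than one difference
per 10 kb. The divergence denominator is the full range length, not the
number of genotyped sites, matching that "per 10 kb" reading. Clusters
smaller than `minTaxa` (default 1, which keeps singletons and therefore
rare haplotypes) are dropped. The consensus allele at a site is the
majority over non-missing members; ties resolve to the reference allele,
and an all-missing site stays missing. Haplotype ids are dense per range,
ordered by descending member count then lexicographic taxa — all ordering
choices exist purely to make output deterministic.

Numerical guard: a cross-pair average that equals `mxDiv` in exact
arithmetic can land one ulp below it in floating point, so divergences
within 1e-9 (relative) of `mxDiv` are treated as equal and do not merge.

## Read mapping

The original pipeline aligns reads to consensus haplotype sequences with an
external aligner, keeping uniquely mapped reads. Here a self-contained
canonical k-mer pseudo-mapper (default k = 21) plays that role: consensus
sequences are realised by editing the reference slice with each haplotype's
alleles and indexed on both strands; a read is assigned to a range only if
its k-mer hits touch exactly one range (uniqueness), and within the range
it is *consistent* with every haplotype achieving the maximal hit count
(multi-mapping ties are kept, mirroring how an aligner reports equally good
placements). Mates of a pair must map to the same range or the pair is
discarded. This contract is a stated substitute for the external aligner,
not a reconstruction of it.

## HMM path decoding

Each chromosome is decoded independently. Hidden states at step *t* are
the consensus haplotypes of the *t*-th range; the initial distribution is
uniform.

- **Emission**: every read assigned to a range is consistent with the true
  haplotype with probability 1 − ε, so
  log P(evidence | h) = hits(h)·log(1 − ε) + (n − hits(h))·log ε,
  with ε (`eps`, default 0.01) the read-mismatch probability. A range with
  no reads (or fewer than `minReads`, default 0) emits log 1 for every
  state, so the path traverses it and every catalogued site is imputed
  regardless of coverage — the minReads = 0 semantics.
- **Transition**: consecutive haplotypes sharing at least one member taxon
  get unnormalised weight 1 − s, disjoint pairs s / (number of next states),
  rows renormalised; s (`switch_p`, default 0.001) is the per-boundary
  probability of a taxon discontinuity. This favours taxon-continuous
  paths, which is what lets sparse evidence impute whole parental blocks.

ε and `switch_p` are package defaults exposed in `HmmParams`; the source
framework does not publish its emission/transition forms, so these are this
package's own design, checked against brute-force path enumeration rather
than against an external implementation. Viterbi decoding breaks ties
toward the lowest haplotype id. All arithmetic is in log space; a
400-range × 50-reads-per-range chromosome decodes without underflow.
Paths are haploid and emitted genotypes homozygous (inbred panels);
diploid path pairs are out of scope.

## Diversity and LD statistics

Windows are defined by SNP count (default 2000 SNPs stepping 1000) while π
is reported per bp of the window's genomic span (last − first position + 1)
— the span denominator is this package's explicit reconciliation of
SNP-count windows with per-bp diversity. Per-site sample size uses
non-missing calls only. Tajima's D follows the 1989 constants, computed on
complete-call sites so the segregating-site count and mean pairwise
difference describe the same sample; it is undefined (NaN) for S = 0 or
n < 4. r² is the squared Pearson correlation of allele codes over
pairwise-complete samples (PLINK-compatible). LD decay bins all
intra-chromosomal pairs by distance (default 100 kb bins to 1 Mb on the
synthetic scale); the initial LD level is the first bin's mean r² and the
half-decay distance is the midpoint of the first bin at or below half that
level. Marker thinning removes the later site of any pair with r² ≥ 0.6
inside a 50-SNP window sliding by 10 SNPs, removals being final.

## Evaluation protocol

Read-count arithmetic: reads (or pairs) = coverage × target / (read length
× 2 if paired), rounded half-up; a 170 Mb capture target at 0.01× / 0.1× /
0.5× with 2 × 150 bp reads gives 5,667 / 56,667 / 283,333 pairs. The GBS
target is (retained restriction sites) × (read length). Down-sampling is a
uniform, seed-deterministic sample without replacement, pairs kept
together, input order preserved.

Concordance matches sites on (chrom, pos, ref, alt) — allele identity is
required so ref/alt swaps never count as overlap — and excludes calls
missing in either set from both numerator and denominator. Accuracy can be
stratified by database minor-allele frequency (frequencies computed from
the graph, haplotypes weighted by member-taxa counts; bins (0–0.1] …
(0.4–0.5] plus a ">0.1" union) and by genome group; empty strata report
NaN, never 0. The high-quality-site filter keeps sites with MAF ≥ 0.015
and missing fraction strictly below 10%, with the missing fraction computed
as an integer-count ratio so the boundary is exact.

## Synthetic study design

The simulator provides every input at desk scale. Defaults, chosen once as
the study conditions:

| parameter | default | rationale |
| --- | --- | --- |
| chromosomes × length | 2 × 200 kb | smallest scale with multi-range, multi-chromosome structure |
| genes per chromosome | 20 × ~2 kb (sd 300) | ~10% genic fraction, gene-island architecture |
| repeat fraction | 0.8 | wheat-like genomes are ~85% repetitive; drives both mapping ambiguity and GBS site enrichment |
| founders | 6 | enough for shared/private haplotype structure |
| genic divergence | 0.002 /bp (intergenic 0.0002) | well-separated haplotypes at a scale where mxDiv keeps founders distinct |
| subgenome divergence | A = B = 1.0, D = 0.4 | bottlenecked-subgenome contrast direction |
| introgression | founder6, chr1:75–125 kb, 10× divergence | one deeply divergent donor segment |
| RILs | 20 lines, Poisson(1.5) crossovers/chromosome, 6 selfings | biparental family; residual heterozygosity 2⁻⁶ masked to missing |
| reads | 2 × 150 bp capture (GBS 1 × 100 bp), error 0.002 | short-read geometry at the protocols' stated lengths |

Mutations are sprinkled independently per founder at a fixed per-bp rate
(deterministic ref→alt transitions so founders share the alt at a shared
position) rather than drawn from a coalescent. This produces the haplotype
structure the graph needs but **not** realistic LD decay or a realistic
site-frequency spectrum: nearly every database variant is a singleton, so
per-site mean MAF is flat across subgenomes and the A/B-versus-D contrast
expresses itself through variant density and π instead of mean MAF. Passing
tests therefore demonstrate the machinery (collapsing, mapping, decoding,
scoring) under controlled conditions, not performance on real wheat data.

Read protocols: *capture* draws paired fragments uniformly within reference
ranges (target = summed range length); *gbs* draws single 100 bp reads
anchored at in-silico PstI sites retained by a nearby MspI site within
250 bp (target = sites × read length); *skim* draws paired fragments
uniformly genome-wide. The repeat motif library is depleted of the PstI
recognition motif: methylation-sensitive enzymes do not cut the methylated
repeat fraction, which is precisely the complexity-reduction mechanism that
makes GBS informative — with it, ~70% of retained digest sites fall inside
reference ranges, versus ~30% for uniform placement. Without this feature
the capture ≥ gbs ≥ skim accuracy ordering is not a property of the
protocols at all, only of sampling noise.

## Problem sizes in the shipped checks

The end-to-end benchmark imputes a 20-RIL family on 2 chromosomes, at
0.01× / 0.1× / 0.5× capture coverage, averaged over 3 seeds (5 seeds for
the coverage-monotonicity check); protocol ordering uses the full family
over 2 seeds at an equal sequenced-base budget; decoding is verified
against exhaustive path enumeration on 1,000 random ≤4-range × ≤3-state
graphs; diversity statistics are verified against direct-formula oracles
to 1e-9. These sizes keep every check reproducible on a single CPU in a
few minutes while leaving each property comfortably away from its decision
boundary.

## Known limitations

- Bi-allelic sites only; the simulator emits SNPs exclusively so sample
  and reference coordinates stay aligned (the graph itself accepts small
  indels from external VCFs).
- Haploid paths and homozygous output genotypes; heterozygous imputation
  is out of scope.
- The mutation-sprinkling population model has no shared genealogy, so LD
  structure, IBD segments and frequency spectra are not wheat-realistic.
- The k-mer pseudo-mapper ignores base qualities and performs no
  alignment; highly similar haplotypes separated by less than one k-mer's
  worth of difference are indistinguishable to it.
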