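"""Accuracy protocol: coverage arithmetic, down-sampling, concordance.

Concordance compares imputed against truth genotypes site by site, where a
site is identified by (chrom, pos, ref, alt); calls missing in either set
are excluded from both numerator and denominator.  Accuracy can be
stratified by minor-allele-frequency bin (frequencies taken from the
haplotype database, not from the evaluation panel) and by genome group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .popgen import MAF_BIN_LABELS, maf_bin_label

MISSING = -1

SiteKey = tuple[str, int, str, str]          # (chrom, pos, ref, alt)


@dataclass(frozen=True)
class CoverageSpec:
    """Sequencing effort: target size, depth, read geometry."""

    target_bp: float
    coverage: float
    read_len: int = 150
    paired: bool = True

    def __post_init__(self) -> None:
        if self.target_bp <= 0 or self.coverage <= 0 or self.read_len <= 0:
            raise ValueError("target_bp, coverage and read_len must be positive")


def reads_for_coverage(spec: CoverageSpec) -> int:
    """Read (pair) count for a coverage level, rounded half-up.

    count = coverage * target_bp / (read_len * 2 if paired else read_len);
    e.g. 0.01x of a 170 Mb target with 2 x 150 bp reads needs 5,667 pairs.
    """
    bases_per_unit = spec.read_len * (2 if spec.paired else 1)
    return int(math.floor(spec.coverage * spec.target_bp / bases_per_unit + 0.5))


def gbs_target_size(n_sites: int, read_len: int) -> int:
    """Target space of GBS sequencing: retained restriction sites x read
    length (1.96 M PstI-MspI sites x 100 bp reads = 196 Mb)."""
    if n_sites < 0:
        raise ValueError("n_sites must be >= 0")
    return n_sites * read_len


def downsample_reads(
    reads: Sequence, n: int, seed: int, pairs: Sequence | None = None
):
    """Uniform sample of n reads (or read pairs) without replacement.

    Deterministic per (seed, input); input order is preserved.  When
    ``pairs`` is given, both lists are subset with the same indices.
    """
    total = len(reads)
    if n > total:
        raise ValueError(f"requested {n} reads but input has only {total}")
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(total, size=n, replace=False))
    sub1 = [reads[i] for i in keep]
    if pairs is not None:
        return sub1, [pairs[i] for i in keep]
    return sub1


def downsample_fastq(
    in1: str, out1: str, n: int, seed: int, in2: str | None = None,
    out2: str | None = None,
) -> None:
    """seqtk-style deterministic FASTQ down-sampling (pairs kept together)."""
    rec1 = _read_fastq_records(in1)
    if in2 is None:
        sub = downsample_reads(rec1, n, seed)
        _write_fastq_records(out1, sub)
    else:
        rec2 = _read_fastq_records(in2)
        if len(rec1) != len(rec2):
            raise ValueError("paired FASTQ files differ in read count")
        sub1, sub2 = downsample_reads(rec1, n, seed, pairs=rec2)
        _write_fastq_records(out1, sub1)
        _write_fastq_records(out2, sub2)


def _read_fastq_records(path: str) -> list[tuple[str, ...]]:
    import gzip

    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "rt") as fh:
        lines = [line.rstrip("\n") for line in fh]
    if len(lines) % 4:
        raise ValueError(f"{path}: truncated FASTQ")
    return [tuple(lines[i : i + 4]) for i in range(0, len(lines), 4)]


def _write_fastq_records(path: str, records: Sequence[tuple[str, ...]]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write("\n".join(rec) + "\n")


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

@dataclass
class AccuracyReport:
    """Per-accession genotype concordance, overall and stratified."""

    accession: str
    n_overlap: int
    n_match: int
    maf_strata: pd.DataFrame | None = None     # per MAF bin
    group_strata: pd.DataFrame | None = None   # per genome group

    @property
    def accuracy(self) -> float:
        return self.n_match / self.n_overlap


def concordance(
    imputed: Mapping[SiteKey, int],
    truth: Mapping[SiteKey, int],
    accession: str = "sample",
) -> AccuracyReport:
    """Matching genotype calls over overlapped (non-missing in both) calls.

    Sites match on (chrom, pos, ref, alt); a call missing in either set is
    excluded entirely.  Zero overlap is an error (undefined accuracy).
    """
    n_overlap = n_match = 0
    for key, truth_code in truth.items():
        if truth_code == MISSING:
            continue
        imp = imputed.get(key, MISSING)
        if imp == MISSING:
            continue
        n_overlap += 1
        if imp == truth_code:
            n_match += 1
    if n_overlap == 0:
        raise ValueError("no overlapping genotype calls")
    return AccuracyReport(accession, n_overlap, n_match)


def stratified_accuracy(
    imputed: Mapping[SiteKey, int],
    truth: Mapping[SiteKey, int],
    site_maf: Mapping[SiteKey, float],
    genome_groups: Mapping[str, str] | None = None,
    accession: str = "sample",
) -> AccuracyReport:
    """Concordance stratified by database MAF bin and genome group.

    ``site_maf`` carries the allele frequencies of the haplotype database
    (the imputation reference panel); every overlapped site must have one.
    Strata partition the overlap; a ">0.1" union row summarises the four
    common bins.  Empty strata report nan, not 0.
    """
    report = concordance(imputed, truth, accession)
    rows: dict[str, list[int]] = {lab: [0, 0] for lab in MAF_BIN_LABELS}
    grp_rows: dict[str, list[int]] = {}
    for key, truth_code in truth.items():
        if truth_code == MISSING:
            continue
        imp = imputed.get(key, MISSING)
        if imp == MISSING:
            continue
        if key not in site_maf:
            raise ValueError(f"no database MAF for site {key}")
        lab = maf_bin_label(site_maf[key])
        rows[lab][0] += 1
        rows[lab][1] += int(imp == truth_code)
        if genome_groups is not None:
            g = genome_groups.get(key[0], "?")
            grp_rows.setdefault(g, [0, 0])
            grp_rows[g][0] += 1
            grp_rows[g][1] += int(imp == truth_code)

    def table(d: dict[str, list[int]]) -> pd.DataFrame:
        recs = []
        for lab, (n, m) in d.items():
            recs.append(
                {
                    "stratum": lab,
                    "n_overlap": n,
                    "n_match": m,
                    "accuracy": m / n if n else float("nan"),
                }
            )
        return pd.DataFrame(recs)

    maf_tab = table(rows)
    common = [lab for lab in MAF_BIN_LABELS if lab != "0-0.1"]
    n_c = sum(rows[lab][0] for lab in common)
    m_c = sum(rows[lab][1] for lab in common)
    maf_tab = pd.concat(
        [
            maf_tab,
            pd.DataFrame(
                [
                    {
                        "stratum": ">0.1",
                        "n_overlap": n_c,
                        "n_match": m_c,
                        "accuracy": m_c / n_c if n_c else float("nan"),
                    }
                ]
            ),
        ],
        ignore_index=True,
    )
    report.maf_strata = maf_tab
    if genome_groups is not None:
        report.group_strata = table(grp_rows)
    return report


# ---------------------------------------------------------------------------
# HQ-SNP filtering
# ---------------------------------------------------------------------------

def filter_hq_snps(
    calls: np.ndarray, maf_min: float = 0.015, max_missing: float = 0.10
) -> np.ndarray:
    """Boolean keep-mask for high-quality sites in a multi-sample matrix.

    Keeps sites with minor allele frequency >= maf_min and missing-call
    fraction strictly below max_missing.
    """
    calls = np.asarray(calls)
    ok = calls != MISSING
    n = ok.sum(axis=1)
    miss_frac = (calls.shape[1] - n) / calls.shape[1]
    with np.errstate(invalid="ignore"):
        p = np.where(n > 0, (calls == 1).sum(axis=1) / np.maximum(n, 1), np.nan)
    maf = np.minimum(p, 1.0 - p)
    return (miss_frac < max_missing) & (maf >= maf_min)


# ---------------------------------------------------------------------------
# VCF genotype loading (single-sample comparison helper)
# ---------------------------------------------------------------------------

def load_vcf_genotypes(path: str, sample: str | None = None) -> dict[SiteKey, int]:
    """Read one sample's genotypes from a VCF into a site -> code map.

    Heterozygous calls map to MISSING (inbred panels); bi-allelic records
    only.
    """
    import pysam

    out: dict[SiteKey, int] = {}
    with pysam.VariantFile(path) as vf:
        if sample is None:
            sample = list(vf.header.samples)[0]
        for rec in vf.fetch() if vf.index else vf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            gt = rec.samples[sample].get("GT")
            key = (rec.chrom, rec.pos - 1, rec.ref, rec.alts[0])
            if gt is None or None in gt:
                out[key] = MISSING
            elif gt[0] == gt[-1]:
                out[key] = int(gt[0])
            else:
                out[key] = MISSING
    return out
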