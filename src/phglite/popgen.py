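"""Panel diversity and linkage-disequilibrium summaries.

Operates on a bi-allelic genotype matrix (sites x samples, allele codes
0/1, -1 missing).  Windows are defined by SNP count (default 2000 SNPs
stepping 1000) while pi is reported per bp of the window's genomic span.
r^2 is the squared Pearson correlation of allele codes over samples that
are non-missing at both sites (pairwise-complete, PLINK-style).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -1

MAF_BIN_EDGES = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)
MAF_BIN_LABELS = ("0-0.1", "0.1-0.2", "0.2-0.3", "0.3-0.4", "0.4-0.5")


@dataclass
class GenotypeMatrix:
    """Bi-allelic site x sample call matrix.

    sites: DataFrame with columns chrom, pos, ref, alt (pos strictly
    increasing within a chromosome); calls: int array with entries in
    {0, 1, -1}; genome_group optionally maps chromosome -> group label
    (e.g. the A/B/D subgenomes of bread wheat).
    """

    sites: pd.DataFrame
    samples: list[str]
    calls: np.ndarray
    genome_group: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sites), len(self.samples)):
            raise ValueError("calls shape must be (n_sites, n_samples)")
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError(f"positions not increasing on {chrom}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)


def alt_frequency(calls: np.ndarray) -> np.ndarray:
    """Per-site alt allele frequency over non-missing calls (nan if none)."""
    calls = np.atleast_2d(np.asarray(calls))
    ok = calls != MISSING
    n = ok.sum(axis=1)
    with np.errstate(invalid="ignore"):
        return np.where(n > 0, (calls == 1).sum(axis=1) / np.maximum(n, 1), np.nan)


def nucleotide_diversity(positions: Sequence[int], calls: np.ndarray) -> float:
    """Per-bp nucleotide diversity pi over a window of sites.

    pi = sum over sites of 2 p (1-p) n/(n-1), divided by the window span
    (last - first position + 1), with per-site sample size n counted over
    non-missing calls.
    """
    positions = np.asarray(positions)
    calls = np.asarray(calls)
    span = int(positions.max() - positions.min()) + 1
    if span <= 0:
        raise ValueError("window span must be positive")
    ok = calls != MISSING
    n = ok.sum(axis=1)
    use = n >= 2
    p = alt_frequency(calls)[use]
    n = n[use]
    het = 2.0 * p * (1.0 - p) * n / (n - 1.0)
    return float(het.sum() / span)


def _tajima_constants(n: int) -> tuple[float, float]:
    """Variance constants e1, e2 of Tajima's D for sample size n."""
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return e1, e2


def tajimas_d(calls: np.ndarray) -> float:
    """Tajima's D over a window; nan when S = 0 or n < 4.

    Sites with missing data are dropped so that S and the mean pairwise
    difference count the same complete-call sample.
    """
    calls = np.asarray(calls)
    complete = ~(calls == MISSING).any(axis=1)
    calls = calls[complete]
    if calls.size == 0:
        return float("nan")
    n = calls.shape[1]
    if n < 4:
        return float("nan")
    ac = (calls == 1).sum(axis=1)
    seg = (ac > 0) & (ac < n)
    S = int(seg.sum())
    if S == 0:
        return float("nan")
    p = ac[seg] / n
    k = float((2.0 * p * (1.0 - p) * n / (n - 1.0)).sum())  # mean pairwise diff
    a1 = float(np.sum(1.0 / np.arange(1, n)))
    e1, e2 = _tajima_constants(n)
    return (k - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1.0))


def diversity_windows(
    gm: GenotypeMatrix, window_snps: int = 2000, step_snps: int = 1000
) -> pd.DataFrame:
    """Sliding-window pi and Tajima's D (windows by SNP count)."""
    rows = []
    for chrom, grp in gm.sites.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        for start in range(0, max(len(idx) - window_snps + 1, 1), step_snps):
            w = idx[start : start + window_snps]
            if len(w) < 2:
                continue
            pos = gm.sites.loc[w, "pos"].to_numpy()
            calls = gm.calls[w]
            rows.append(
                {
                    "chrom": chrom,
                    "first": int(w[0]),
                    "last": int(w[-1]),
                    "span_bp": int(pos[-1] - pos[0] + 1),
                    "S": int(
                        (
                            (alt_frequency(calls) > 0)
                            & (alt_frequency(calls) < 1)
                        ).sum()
                    ),
                    "pi": nucleotide_diversity(pos, calls),
                    "tajimas_d": tajimas_d(calls),
                }
            )
    return pd.DataFrame(rows)


def maf_spectrum(calls: np.ndarray) -> tuple[np.ndarray, pd.Series, int]:
    """Per-site minor allele frequency plus the binned spectrum.

    Returns (maf array over scored sites, counts per bin, number of
    all-missing sites excluded).  Bins are (0-0.1], (0.1-0.2], ...,
    (0.4-0.5] with the first bin closed at 0.
    """
    p = alt_frequency(calls)
    excluded = int(np.isnan(p).sum())
    p = p[~np.isnan(p)]
    maf = np.minimum(p, 1.0 - p)
    idx = np.clip(np.ceil(maf / 0.1).astype(int) - 1, 0, 4)  # (left, right]
    counts = pd.Series(
        np.bincount(idx, minlength=5), index=list(MAF_BIN_LABELS), name="n_sites"
    )
    return maf, counts, excluded


def maf_bin_label(maf: float) -> str:
    i = int(np.clip(np.ceil(maf / 0.1) - 1, 0, 4))
    return MAF_BIN_LABELS[i]


def pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation over pairwise-complete samples; nan for
    monomorphic pairs or < 2 complete observations."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return float("nan")
    xs, ys = x[ok].astype(float), y[ok].astype(float)
    if xs.std() == 0 or ys.std() == 0:
        return float("nan")
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def ld_decay(
    gm: GenotypeMatrix,
    max_dist: int = 1_000_000,
    bin_width: int = 100_000,
) -> tuple[pd.DataFrame, float]:
    """Binned mean r^2 against pairwise distance, plus half-decay distance.

    The initial LD level is the mean r^2 of the first distance bin; the
    half-decay distance is the midpoint of the first bin whose mean r^2
    drops to half of that level (nan if none does within max_dist).
    """
    sums = np.zeros(int(np.ceil(max_dist / bin_width)))
    counts = np.zeros_like(sums, dtype=int)
    for chrom, grp in gm.sites.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                d = pos[b] - pos[a]
                if d > max_dist:
                    break
                r2 = pairwise_r2(gm.calls[idx[a]], gm.calls[idx[b]])
                if np.isnan(r2):
                    continue
                bi = min(int(d // bin_width), len(sums) - 1)
                sums[bi] += r2
                counts[bi] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    table = pd.DataFrame(
        {
            "dist_lo": np.arange(len(sums)) * bin_width,
            "dist_hi": (np.arange(len(sums)) + 1) * bin_width,
            "mean_r2": mean,
            "n_pairs": counts,
        }
    )
    half_decay = float("nan")
    scored = table.dropna(subset=["mean_r2"])
    if not scored.empty:
        initial = scored["mean_r2"].iloc[0]
        hit = scored[scored["mean_r2"] <= initial / 2.0]
        if not hit.empty:
            row = hit.iloc[0]
            half_decay = float((row["dist_lo"] + row["dist_hi"]) / 2.0)
    return table, half_decay


def ld_prune(
    gm: GenotypeMatrix,
    r2_threshold: float = 0.6,
    window_snps: int = 50,
    step_snps: int = 10,
) -> list[int]:
    """LD-based marker thinning (PLINK indep-pairwise style).

    Within each sliding window, pairs with r^2 >= threshold lose the later
    site; windows slide by step and a removal anywhere is final.  Windows
    never span chromosomes.  Returns retained site indices.
    """
    removed: set[int] = set()
    for chrom, grp in gm.sites.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        for start in range(0, len(idx), step_snps):
            w = idx[start : start + window_snps]
            for a in range(len(w)):
                if w[a] in removed:
                    continue
                for b in range(a + 1, len(w)):
                    if w[b] in removed:
                        continue
                    r2 = pairwise_r2(gm.calls[w[a]], gm.calls[w[b]])
                    if not np.isnan(r2) and r2 >= r2_threshold:
                        removed.add(int(w[b]))
            if start + window_snps >= len(idx):
                break
    return [i for i in range(len(gm.sites)) if i not in removed]
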