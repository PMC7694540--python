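"""Per-population diversity summaries and sliding-window nucleotide diversity.

The quantities here follow the DnaSP conventions used in amplicon
population genomics: complete deletion of gap/missing columns, mean
pairwise differences k per sequence, per-site diversity pi = k/L_valid,
and bias-corrected haplotype diversity Hd = n/(n-1) * (1 - sum p_i^2).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from math import comb

import numpy as np

from .alignio import LocusAlignment, SiteClassification, classify_sites


@dataclass
class DiversitySummary:
    """One table row of per-population summaries: 2n, S, h, Hd, pi, thetaW, k."""

    n2: int
    S: int
    h: int
    Hd: float
    k: float
    pi: float
    theta_w: float
    L_valid: int


@dataclass
class SlidingWindowProfile:
    window_bp: int
    step_bp: int
    #: list of (start, end, pi, n_valid_sites); coordinates are 0-based
    #: half-open on the original alignment columns.
    windows: list[tuple[int, int, float, int]]


def _pairwise_diff_sum(aln: LocusAlignment, columns: list[int]) -> float:
    """Sum over all sequence pairs of the number of differing valid sites.

    Computed per column from allele counts: a column with allele counts
    c_a contributes C(n,2) - sum_a C(c_a,2) differing pairs.
    """
    n = aln.n
    total_pairs = comb(n, 2)
    total = 0
    for j in columns:
        counts = Counter(aln.column(j))
        if len(counts) == 1:
            continue
        total += total_pairs - sum(comb(c, 2) for c in counts.values())
    return float(total)


def mean_pairwise_differences(
    aln: LocusAlignment, sites: SiteClassification | None = None
) -> float:
    """Average number of nucleotide differences k between two sequences."""
    if aln.n < 2:
        raise ValueError("need at least 2 sequences")
    if sites is None:
        sites = classify_sites(aln)
    return _pairwise_diff_sum(aln, sites.segregating_columns) / comb(aln.n, 2)


def nucleotide_diversity(
    aln: LocusAlignment, sites: SiteClassification | None = None
) -> float:
    """Per-site nucleotide diversity pi = k / L_valid."""
    if sites is None:
        sites = classify_sites(aln)
    if sites.L_valid == 0:
        return 0.0
    return mean_pairwise_differences(aln, sites) / sites.L_valid


def haplotype_summary(
    aln: LocusAlignment, sites: SiteClassification | None = None
) -> tuple[int, float]:
    """Haplotype count h and bias-corrected haplotype diversity Hd.

    Haplotypes are distinct full-length strings over the valid columns;
    Hd = (n/(n-1)) * (1 - sum p_i^2).
    """
    if sites is None:
        sites = classify_sites(aln)
    cols = sites.valid_columns
    counts = haplotype_counts(aln, cols)
    n = aln.n
    h = len(counts)
    freqs = np.array(list(counts.values()), dtype=float) / n
    hd = n / (n - 1) * (1.0 - float(np.sum(freqs**2)))
    return h, hd


def haplotype_counts(aln: LocusAlignment, columns: list[int]) -> Counter:
    """Multiplicity of each distinct haplotype string over given columns."""
    keys = ["".join(r.sequence[j] for j in columns) for r in aln.records]
    return Counter(keys)


def watterson_theta(S: int, n2: int) -> float:
    """Watterson's estimator per sequence, thetaW = S / a1."""
    if n2 < 2:
        raise ValueError("need at least 2 sequences")
    if S == 0:
        return 0.0
    a1 = harmonic_number(n2 - 1)
    return S / a1


def harmonic_number(m: int) -> float:
    return float(np.sum(1.0 / np.arange(1, m + 1)))


def diversity_summary(aln: LocusAlignment) -> DiversitySummary:
    """The full per-population summary row."""
    sites = classify_sites(aln)
    k = mean_pairwise_differences(aln, sites)
    pi = k / sites.L_valid if sites.L_valid else 0.0
    h, hd = haplotype_summary(aln, sites)
    return DiversitySummary(
        n2=aln.n,
        S=sites.S,
        h=h,
        Hd=hd,
        k=k,
        pi=pi,
        theta_w=watterson_theta(sites.S, aln.n),
        L_valid=sites.L_valid,
    )


def sliding_window_pi(
    aln: LocusAlignment, window_bp: int = 400, step_bp: int = 100
) -> SlidingWindowProfile:
    """Nucleotide diversity in overlapping windows along the alignment.

    Windows start at column 0 and advance by ``step_bp``; the last
    window is the final one fitting entirely within the alignment.
    Excluded columns inside a window shrink that window's denominator.
    """
    L = aln.length
    if window_bp > L:
        raise ValueError(f"window ({window_bp}) longer than alignment ({L})")
    if window_bp < 1 or step_bp < 1:
        raise ValueError("window and step must be positive")
    sites = classify_sites(aln)
    valid = set(sites.valid_columns)
    seg = set(sites.segregating_columns)
    pairs = comb(aln.n, 2)
    windows = []
    for start in range(0, L - window_bp + 1, step_bp):
        end = start + window_bp
        cols_valid = [j for j in range(start, end) if j in valid]
        cols_seg = [j for j in cols_valid if j in seg]
        n_valid = len(cols_valid)
        if n_valid:
            k_w = _pairwise_diff_sum(aln, cols_seg) / pairs
            pi_w = k_w / n_valid
        else:
            pi_w = 0.0
        windows.append((start, end, pi_w, n_valid))
    return SlidingWindowProfile(window_bp, step_bp, windows)
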