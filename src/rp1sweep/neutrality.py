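"""Neutrality tests: Tajima's D, Fu & Li's D* (no outgroup), Fu's FS.

Tajima's D contrasts the pairwise-difference estimator of theta with
Watterson's S-based estimator; Fu & Li's D* contrasts singleton
mutations with the total mutation count (corrected coefficient set);
Fu's FS is the logit of the probability, under the Ewens sampling
formula with theta estimated by the mean pairwise differences k, of
seeing at least the observed number of haplotypes. All three go
negative under an excess of rare variants (sweep or expansion).

Significance is empirical, from a seeded neutral coalescent null:
fixed-S conditioning for D and D*, theta-parameterised for FS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .alignio import LocusAlignment, classify_sites
from .diversity import (
    diversity_summary,
    harmonic_number,
)


@dataclass
class NeutralityCoefficients:
    """Variance coefficients for a sample of n2 sequences."""

    n2: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float
    cn: float
    dn: float
    u_dstar: float
    v_dstar: float


@dataclass
class NeutralityResult:
    D: float | None
    Dstar: float | None
    FS: float | None
    p_D: float | None = None
    p_Dstar: float | None = None
    p_FS: float | None = None


def coefficients(n2: int) -> NeutralityCoefficients:
    if n2 < 3:
        raise ValueError("coefficients need n2 >= 3")
    n = float(n2)
    a1 = harmonic_number(n2 - 1)
    a2 = float(np.sum(1.0 / np.arange(1, n2) ** 2))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    # Fu & Li's D* chain, corrected (erratum) form
    cn = 2 * (n * a1 - 2 * (n - 1)) / ((n - 1) * (n - 2))
    an1 = a1 + 1 / n  # harmonic number of n
    dn = (
        cn
        + (n - 2) / (n - 1) ** 2
        + (2 / (n - 1)) * (1.5 - (2 * an1 - 3) / (n - 2) - 1 / n)
    )
    v_dstar = (
        (n / (n - 1)) ** 2 * a2
        + a1**2 * dn
        - 2 * (n * a1 * (a1 + 1)) / (n - 1) ** 2
    ) / (a1**2 + a2)
    u_dstar = (n / (n - 1)) * (a1 - n / (n - 1)) - v_dstar
    return NeutralityCoefficients(
        n2, a1, a2, b1, b2, c1, c2, e1, e2, cn, dn, u_dstar, v_dstar
    )


def tajimas_d(k: float, S: int, n2: int) -> float | None:
    """Tajima's D from mean pairwise differences k and S sites.

    Returns None (undefined, reported "-") when S = 0.
    """
    if n2 < 4:
        raise ValueError("Tajima's D needs n2 >= 4")
    if S == 0:
        return None
    c = coefficients(n2)
    var = c.e1 * S + c.e2 * S * (S - 1)
    return (k - S / c.a1) / math.sqrt(var)


def fu_li_dstar(eta: int, eta_s: int, n2: int) -> float | None:
    """Fu & Li's D* (outgroup-free), corrected coefficients.

    eta is the total mutation count, eta_s the singleton count. Returns
    None when eta = 0.
    """
    if n2 < 4:
        raise ValueError("Fu & Li's D* needs n2 >= 4")
    if eta == 0:
        return None
    c = coefficients(n2)
    n = float(n2)
    num = (n / (n - 1)) * eta - c.a1 * eta_s
    var = c.u_dstar * eta + c.v_dstar * eta**2
    return num / math.sqrt(var)


@lru_cache(maxsize=64)
def _log_stirling_row(n: int) -> tuple[float, ...]:
    """log of unsigned Stirling numbers of the first kind |s(n, k)|, k=1..n.

    Computed exactly with big integers via the coefficients of
    x(x+1)...(x+n-1), then logged.
    """
    coeffs = [0, 1]  # polynomial x, coefficient of x^k at index k
    for i in range(1, n):
        new = [0] * (len(coeffs) + 1)
        for k, c in enumerate(coeffs):
            new[k] += i * c
            new[k + 1] += c
        coeffs = new
    return tuple(math.log(coeffs[k]) for k in range(1, n + 1))


def ewens_allele_distribution(n2: int, theta: float) -> np.ndarray:
    """P(K = k) for k = 1..n2 under the Ewens sampling formula.

    P(K=k) = |s(n,k)| theta^k / (theta (theta+1) ... (theta+n-1)),
    evaluated in log space.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    logs = np.array(_log_stirling_row(n2))
    k = np.arange(1, n2 + 1)
    log_num = logs + k * math.log(theta)
    log_den = float(np.sum(np.log(theta + np.arange(n2))))
    return np.exp(log_num - log_den)


def fus_fs(k: float, n_haplotypes: int, n2: int) -> float | None:
    """Fu's FS: logit of S' = P(K >= observed haplotypes | theta = k).

    Returns None when k = 0 (no pairwise differences).
    """
    if k <= 0:
        return None
    p = ewens_allele_distribution(n2, k)
    s_prime = float(p[n_haplotypes - 1:].sum())
    s_prime = min(max(s_prime, 1e-300), 1 - 1e-16)
    return math.log(s_prime / (1.0 - s_prime))


def neutrality_tests(aln: LocusAlignment) -> NeutralityResult:
    """All three statistics for one alignment (no significance)."""
    sites = classify_sites(aln)
    summ = diversity_summary(aln)
    return NeutralityResult(
        D=tajimas_d(summ.k, summ.S, aln.n),
        Dstar=fu_li_dstar(sites.eta, sites.eta_s, aln.n),
        FS=fus_fs(summ.k, summ.h, aln.n),
    )


# ---------------------------------------------------------------------------
# Empirical significance from a seeded neutral coalescent null
# ---------------------------------------------------------------------------

def _null_replicates_fixed_s(
    n2: int, S: int, n_sims: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """(D, D*) under the neutral coalescent conditioned on S mutations."""
    from .simdata import drop_fixed_mutations, kingman_genealogy

    d_vals = np.empty(n_sims)
    ds_vals = np.empty(n_sims)
    pairs = n2 * (n2 - 1) / 2.0
    for r in range(n_sims):
        tree = kingman_genealogy(n2, rng)
        carriers = drop_fixed_mutations(tree, S, rng)
        counts = np.array([len(c) for c in carriers])
        k = float(np.sum(counts * (n2 - counts)) / pairs)
        eta_s = int(np.sum((counts == 1) | (counts == n2 - 1)))
        d_vals[r] = tajimas_d(k, S, n2)
        ds_vals[r] = fu_li_dstar(S, eta_s, n2)
    return d_vals, ds_vals


def _null_replicates_fs(
    n2: int, theta: float, n_sims: int, rng: np.random.Generator
) -> np.ndarray:
    """FS under the neutral coalescent with mutation rate theta."""
    from .simdata import drop_mutations, kingman_genealogy

    out = np.empty(n_sims)
    pairs = n2 * (n2 - 1) / 2.0
    for r in range(n_sims):
        tree = kingman_genealogy(n2, rng)
        carriers = drop_mutations(tree, theta, rng)
        informative = [c for c in carriers if 0 < len(c) < n2]
        counts = np.array([len(c) for c in informative], dtype=float)
        if counts.size == 0:
            out[r] = 0.0  # monomorphic replicate: FS undefined, neutral
            continue
        k = float(np.sum(counts * (n2 - counts)) / pairs)
        keys = [frozenset(j for j, c in enumerate(informative) if i in c)
                for i in range(n2)]
        h = len(set(keys))
        fs = fus_fs(k, h, n2)
        out[r] = 0.0 if fs is None else fs
    return out


def neutrality_significance(
    statistic: str,
    observed: float,
    n2: int,
    S: int | None = None,
    theta: float | None = None,
    n_sims: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Empirical p-value for D, D* or FS from the coalescent null.

    D and D* are two-tailed: twice the smaller tail, each tail
    estimated as (count + 1)/(n_sims + 1), capped at 1 (the doubling
    convention; the null distributions are skewed, so distance from
    the median would overweight the long tail). FS uses Fu's
    one-tailed (lower) convention.
    """
    from .simdata import _as_rng

    rng = _as_rng(seed)
    if statistic in ("D", "Dstar"):
        if S is None or S < 1:
            raise ValueError("fixed-S null needs S >= 1")
        d_vals, ds_vals = _null_replicates_fixed_s(n2, S, n_sims, rng)
        null = d_vals if statistic == "D" else ds_vals
        lo = (int(np.sum(null <= observed)) + 1) / (n_sims + 1)
        hi = (int(np.sum(null >= observed)) + 1) / (n_sims + 1)
        return min(1.0, 2.0 * min(lo, hi))
    if statistic == "FS":
        if theta is None or theta <= 0:
            raise ValueError("FS null needs theta > 0")
        null = _null_replicates_fs(n2, theta, n_sims, rng)
        return (int(np.sum(null <= observed)) + 1) / (n_sims + 1)
    raise ValueError(f"unknown statistic {statistic!r}")


def significance_stars(statistic: str, p: float | None) -> str:
    """Annotation for reports: FS follows Fu's convention that an
    empirical one-tailed P < 0.02 marks significance at the 0.05 level."""
    if p is None:
        return ""
    if statistic == "FS":
        if p < 0.005:
            return "**"
        return "*" if p < 0.02 else ""
    if p <= 0.01:
        return "**"
    return "*" if p <= 0.05 else ""
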