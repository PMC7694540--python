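"""Pairwise population differentiation: FST, GST, HST, KST, NST, Nm.

FST is the sequence-based Hudson/Slatkin/Maddison estimator
1 - Hw/Hb (within vs between mean pairwise differences), the form
consistent with Nm = (1 - FST) / (4 FST). GST and HST work on
haplotype frequencies; KST and NST on pairwise sequence differences,
NST weighting haplotype pairs by their nucleotide distance so that a
phylogeographic signal shows up as NST > GST. Significance comes from
permutation of population labels (sizes preserved, +1/+1 estimator,
ties count as exceedances).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

from .alignio import LocusAlignment, SequenceRecord, classify_sites


@dataclass
class DifferentiationResult:
    pop_a: str
    pop_b: str
    fst: float | None
    hw: float
    hb: float
    gst: float | None
    hst: float | None
    kst: float | None
    nst: float | None
    nm: float | None
    p_hst: float | None = None
    p_kst: float | None = None
    n_perms: int = 0
    seed: int | None = None


def _shared_valid_columns(alns: list[LocusAlignment]) -> list[int]:
    """Columns valid (no gap/missing) in the pooled sample."""
    pooled = _pool(alns)
    return classify_sites(pooled).valid_columns


def _pool(alns: list[LocusAlignment]) -> LocusAlignment:
    records = []
    for aln in alns:
        records.extend(aln.records)
    return LocusAlignment("pooled", records, alns[0].offset_kb)


def _seq_arrays(aln: LocusAlignment, columns: list[int]) -> list[str]:
    return ["".join(r.sequence[j] for j in columns) for r in aln.records]


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _mean_within(seqs: list[str]) -> float:
    n = len(seqs)
    if n < 2:
        return 0.0
    total = sum(_hamming(a, b) for a, b in combinations(seqs, 2))
    return total / comb(n, 2)


def _mean_between(seqs_a: list[str], seqs_b: list[str]) -> float:
    total = sum(_hamming(a, b) for a in seqs_a for b in seqs_b)
    return total / (len(seqs_a) * len(seqs_b))


def hudson_fst(
    aln_a: LocusAlignment, aln_b: LocusAlignment
) -> tuple[float | None, float, float]:
    """(FST, Hw, Hb) with FST = 1 - Hw/Hb on per-valid-site differences.

    Hw is the unweighted mean of the two within-population mean
    pairwise differences, Hb the between-population mean. FST is None
    when Hb = 0 (two identical monomorphic samples).
    """
    if aln_a.n < 2 or aln_b.n < 2:
        raise ValueError("both populations need >= 2 sequences")
    cols = _shared_valid_columns([aln_a, aln_b])
    nsites = len(cols) or 1
    sa = _seq_arrays(aln_a, cols)
    sb = _seq_arrays(aln_b, cols)
    hw = (_mean_within(sa) + _mean_within(sb)) / 2.0 / nsites
    hb = _mean_between(sa, sb) / nsites
    if hb == 0.0:
        return None, hw, hb
    return 1.0 - hw / hb, hw, hb


def nm_from_fst(fst: float | None) -> float | None:
    """Effective migrants per generation, Nm = (1 - FST) / (4 FST).

    None (infinite gene flow) when FST <= 0 or undefined.
    """
    if fst is None or fst <= 0.0:
        return None
    return (1.0 - fst) / (4.0 * fst)


def _haplotype_stats(groups: list[list[str]]) -> tuple[float | None, float | None]:
    """(GST, HST) from haplotype frequencies.

    GST: unweighted deme mean of 1 - sum p^2 against the heterozygosity
    of mean allele frequencies. HST: sample-size-weighted within
    heterozygosity against the pooled-sample heterozygosity.
    """
    haps = sorted({h for g in groups for h in g})
    index = {h: i for i, h in enumerate(haps)}
    freqs = []
    sizes = []
    for g in groups:
        v = np.zeros(len(haps))
        for h in g:
            v[index[h]] += 1
        sizes.append(len(g))
        freqs.append(v / len(g))
    freqs = np.array(freqs)
    sizes = np.array(sizes, dtype=float)

    h_demes = 1.0 - np.sum(freqs**2, axis=1)
    # GST: unweighted deme average vs heterozygosity at mean frequencies
    p_bar = freqs.mean(axis=0)
    ht_g = 1.0 - float(np.sum(p_bar**2))
    gst = None if ht_g == 0 else 1.0 - float(h_demes.mean()) / ht_g
    # HST: weighted by sample size vs pooled-sample heterozygosity
    w = sizes / sizes.sum()
    p_pool = (freqs * sizes[:, None]).sum(axis=0) / sizes.sum()
    ht_h = 1.0 - float(np.sum(p_pool**2))
    hst = None if ht_h == 0 else 1.0 - float(np.sum(w * h_demes)) / ht_h
    return gst, hst


def _kst(groups: list[list[str]]) -> float | None:
    """KST = 1 - KS/KT on mean pairwise sequence differences."""
    sizes = np.array([len(g) for g in groups], dtype=float)
    n = sizes.sum()
    within = np.array([_mean_within(g) for g in groups])
    ks = float(np.sum(sizes / n * within))
    pooled = [s for g in groups for s in g]
    kt = _mean_within(pooled)
    if kt == 0:
        return None
    return 1.0 - ks / kt


def _nst(groups: list[list[str]]) -> float | None:
    """NST: GST generalised by nucleotide distance between haplotypes.

    Computed like KST but from haplotype frequencies weighted by the
    pairwise distance matrix, with the within term an unweighted deme
    average (mirroring GST) so that NST - GST isolates the contribution
    of haplotype relatedness.
    """
    haps = sorted({h for g in groups for h in g})
    index = {h: i for i, h in enumerate(haps)}
    dmat = np.zeros((len(haps), len(haps)))
    for i, a in enumerate(haps):
        for j in range(i + 1, len(haps)):
            dmat[i, j] = dmat[j, i] = _hamming(a, haps[j])
    freqs = []
    for g in groups:
        v = np.zeros(len(haps))
        for h in g:
            v[index[h]] += 1
        freqs.append(v / len(g))
    freqs = np.array(freqs)
    v_demes = np.array([f @ dmat @ f for f in freqs])
    p_bar = freqs.mean(axis=0)
    vt = float(p_bar @ dmat @ p_bar)
    if vt == 0:
        return None
    return 1.0 - float(v_demes.mean()) / vt


def differentiation_suite(
    aln_a: LocusAlignment, aln_b: LocusAlignment
) -> tuple[float | None, float | None, float | None, float | None]:
    """(GST, HST, KST, NST) for one population pair."""
    cols = _shared_valid_columns([aln_a, aln_b])
    groups = [_seq_arrays(aln_a, cols), _seq_arrays(aln_b, cols)]
    gst, hst = _haplotype_stats(groups)
    return gst, hst, _kst(groups), _nst(groups)


def permute_labels_test(
    stat_fn,
    aln_a: LocusAlignment,
    aln_b: LocusAlignment,
    n_perms: int = 10000,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float | None]:
    """(observed statistic, permutation p-value).

    ``stat_fn`` maps two alignments to a scalar (or None). Labels are
    shuffled preserving the two sample sizes; p = (#{perm >= obs} + 1)
    / (n_perms + 1). p is None when the observed statistic is
    undefined.
    """
    from .simdata import _as_rng

    rng = _as_rng(seed)
    observed = stat_fn(aln_a, aln_b)
    if observed is None:
        return observed, None
    records = list(aln_a.records) + list(aln_b.records)
    na = aln_a.n
    count = 0
    for _ in range(n_perms):
        perm = rng.permutation(len(records))
        ra = [records[i] for i in perm[:na]]
        rb = [records[i] for i in perm[na:]]
        pa = LocusAlignment(aln_a.locus_name, _relabel(ra, "permA"))
        pb = LocusAlignment(aln_b.locus_name, _relabel(rb, "permB"))
        val = stat_fn(pa, pb)
        if val is not None and val >= observed:
            count += 1
    return observed, (count + 1) / (n_perms + 1)


def _relabel(records: list[SequenceRecord], pop: str) -> list[SequenceRecord]:
    return [
        SequenceRecord(r.sample_id, pop, r.region, r.sequence) for r in records
    ]


def phylogeography_flag(
    nst: float | None,
    gst: float | None,
    p_nst_gst: float | None,
    alpha: float = 0.05,
) -> bool:
    """True when NST significantly exceeds GST (phylogeographic signal)."""
    if nst is None or gst is None or p_nst_gst is None:
        return False
    return nst > gst and p_nst_gst <= alpha


def nst_minus_gst(aln_a: LocusAlignment, aln_b: LocusAlignment) -> float | None:
    """Test statistic for the phylogeography permutation test."""
    gst, _, _, nst = differentiation_suite(aln_a, aln_b)
    if gst is None or nst is None:
        return None
    return nst - gst


def pairwise_differentiation(
    aln: LocusAlignment,
    n_perms: int = 1000,
    seed: int | None = None,
) -> list[DifferentiationResult]:
    """All pairwise comparisons between the populations of a pooled
    alignment, with permutation p-values for HST and KST."""
    from .simdata import _as_rng

    rng = _as_rng(seed)
    pops = aln.by_population()
    results = []
    for pa, pb in combinations(pops, 2):
        a, b = pops[pa], pops[pb]
        fst, hw, hb = hudson_fst(a, b)
        gst, hst, kst, nst = differentiation_suite(a, b)
        _, p_hst = permute_labels_test(
            lambda x, y: differentiation_suite(x, y)[1], a, b, n_perms, rng
        )
        _, p_kst = permute_labels_test(
            lambda x, y: differentiation_suite(x, y)[2], a, b, n_perms, rng
        )
        results.append(
            DifferentiationResult(
                pa, pb, fst, hw, hb, gst, hst, kst, nst,
                nm_from_fst(fst), p_hst, p_kst, n_perms, seed,
            )
        )
    return results


def pooled_by_region(aln: LocusAlignment) -> dict[str, LocusAlignment]:
    """Concatenate populations per region label (pooled-regions mode)."""
    out: dict[str, list] = {}
    for r in aln.records:
        out.setdefault(r.region, []).append(r)
    return {
        reg: LocusAlignment(aln.locus_name, recs, aln.offset_kb)
        for reg, recs in out.items()
        if len(recs) >= 2
    }
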