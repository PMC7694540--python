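"""Nei-Gojobori synonymous/non-synonymous site counting and pN/pS.

Sites are counted per codon as the fraction of single-base changes that
are synonymous, with changes creating stop codons excluded by
renormalising within each codon position (so every non-stop codon
always contributes exactly 3 sites and syn + nonsyn sums to the coding
length). Site fractions are averaged over all sequences in the sample,
which is why population site totals are fractional.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations

from Bio.Data.CodonTable import standard_dna_table

from .alignio import NUCLEOTIDES, LocusAlignment

CODON_TABLE = dict(standard_dna_table.forward_table)
STOP_CODONS = set(standard_dna_table.stop_codons)


class CodonWarning(UserWarning):
    pass


@dataclass
class CodonCountTable:
    syn_sites: float
    nonsyn_sites: float
    syn_subs: float
    nonsyn_subs: float

    @property
    def pS(self) -> float:
        return self.syn_subs / self.syn_sites if self.syn_sites else 0.0

    @property
    def pN(self) -> float:
        return self.nonsyn_subs / self.nonsyn_sites if self.nonsyn_sites else 0.0

    @property
    def ratio(self) -> float | None:
        """pN/pS; None (reported "-") when it cannot be formed."""
        return pnps(self)


def _codon_site_fractions(codon: str) -> tuple[float, float]:
    """(synonymous, non-synonymous) site fractions of one codon.

    Each position contributes 1 site split by the synonymous fraction
    of its non-stop single-base changes.
    """
    if codon in STOP_CODONS or set(codon) - NUCLEOTIDES:
        raise ValueError(f"cannot count sites of codon {codon!r}")
    aa = CODON_TABLE[codon]
    syn = 0.0
    for pos in range(3):
        n_syn = n_valid = 0
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if alt in STOP_CODONS:
                continue
            n_valid += 1
            if CODON_TABLE[alt] == aa:
                n_syn += 1
        if n_valid:
            syn += n_syn / n_valid
    return syn, 3.0 - syn


def ng_site_fractions(
    coding_aln: LocusAlignment, frame: int = 0
) -> tuple[float, float]:
    """Mean synonymous and non-synonymous site counts across sequences.

    ``frame`` trims leading bases so that codons start at position 0 of
    the remainder; trailing incomplete codons are dropped. Codons
    containing gaps, ambiguity codes or an internal stop are skipped
    (with a warning for stops).
    """
    syn_total = nonsyn_total = 0.0
    n_seqs = 0
    for rec in coding_aln.records:
        seq = rec.sequence[frame:]
        seq = seq[: len(seq) - len(seq) % 3]
        syn = nonsyn = 0.0
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            if set(codon) - NUCLEOTIDES:
                continue
            if codon in STOP_CODONS:
                warnings.warn(
                    f"internal stop codon at {i + 1} in {rec.sample_id}",
                    CodonWarning,
                )
                continue
            s, ns = _codon_site_fractions(codon)
            syn += s
            nonsyn += ns
        syn_total += syn
        nonsyn_total += nonsyn
        n_seqs += 1
    return syn_total / n_seqs, nonsyn_total / n_seqs


def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Average (syn, nonsyn) changes over minimal mutational pathways.

    Pathways passing through a stop codon are discarded; if all are,
    the stop-containing pathways are used as a last resort.
    """
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    results = []
    fallback = []
    for order in permutations(diff):
        cur = codon_a
        syn = nonsyn = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                through_stop = True
                nxt_aa = None
            else:
                nxt_aa = CODON_TABLE[nxt]
            cur_aa = None if cur in STOP_CODONS else CODON_TABLE[cur]
            if cur_aa is not None and nxt_aa is not None and cur_aa == nxt_aa:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        (fallback if through_stop else results).append((syn, nonsyn))
    use = results or fallback
    syn = sum(s for s, _ in use) / len(use)
    nonsyn = sum(n for _, n in use) / len(use)
    return syn, nonsyn


def classify_substitutions(
    coding_aln: LocusAlignment, frame: int = 0
) -> tuple[float, float]:
    """(synonymous, non-synonymous) polymorphic changes in the sample.

    Each polymorphic codon is compared against its most frequent
    (reference) form; multi-hit codons are averaged over minimal
    mutational pathways. Codons with more than two observed forms are
    pathway-averaged against the reference with a warning.
    """
    seqs = []
    for rec in coding_aln.records:
        seq = rec.sequence[frame:]
        seqs.append(seq[: len(seq) - len(seq) % 3])
    L = min(len(s) for s in seqs)
    syn = nonsyn = 0.0
    for i in range(0, L, 3):
        codons = [s[i : i + 3] for s in seqs]
        observed = [
            c for c in codons
            if not (set(c) - NUCLEOTIDES) and c not in STOP_CODONS
        ]
        if not observed:
            continue
        distinct = sorted(set(observed))
        if len(distinct) == 1:
            continue
        counts = {c: observed.count(c) for c in distinct}
        ref = max(distinct, key=lambda c: (counts[c], c))
        if len(distinct) > 2:
            warnings.warn(
                f"codon column {i // 3 + 1} has {len(distinct)} states; "
                "pathway-averaging against the majority codon",
                CodonWarning,
            )
        for alt in distinct:
            if alt == ref:
                continue
            s, ns = _pathway_counts(ref, alt)
            syn += s
            nonsyn += ns
    return syn, nonsyn


def codon_count_table(
    coding_aln: LocusAlignment, frame: int = 0
) -> CodonCountTable:
    syn_sites, nonsyn_sites = ng_site_fractions(coding_aln, frame)
    syn_subs, nonsyn_subs = classify_substitutions(coding_aln, frame)
    return CodonCountTable(syn_sites, nonsyn_sites, syn_subs, nonsyn_subs)


def pnps(counts: CodonCountTable) -> float | None:
    """pN/pS; None when syn_subs = 0 (ratio cannot be formed)."""
    if counts.syn_subs == 0:
        return None
    return counts.pN / counts.pS
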