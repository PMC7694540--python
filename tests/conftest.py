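"""Shared fixtures: table-derived alignment reconstructions and
random-alignment factories used by the brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from rp1sweep.alignio import LocusAlignment, SequenceRecord

BASE_LEN = 1139


def make_alignment(
    seqs: list[str],
    pops: list[str] | None = None,
    regions: list[str] | None = None,
    locus: str = "test",
    offset_kb: float = 0.0,
) -> LocusAlignment:
    pops = pops or ["popA"] * len(seqs)
    regions = regions or ["regionA"] * len(seqs)
    records = [
        SequenceRecord(f"s{i:03d}", p, r, s)
        for i, (s, p, r) in enumerate(zip(seqs, pops, regions))
    ]
    return LocusAlignment(locus, records, offset_kb)


def singleton_alignment(n: int, length: int = BASE_LEN) -> LocusAlignment:
    """n identical sequences except one singleton SNP on one sequence."""
    base = "A" * length
    variant = "G" + base[1:]
    return make_alignment([variant] + [base] * (n - 1))


@pytest.fixture
def palmeira_like() -> LocusAlignment:
    """20 sequences, 1139 bp, one singleton: S=1, h=2, k=19/190."""
    return singleton_alignment(20)


@pytest.fixture
def ikwambi_like() -> LocusAlignment:
    """18 sequences, 1139 bp, one singleton."""
    return singleton_alignment(18)


@pytest.fixture
def magania_like() -> LocusAlignment:
    """32 sequences, 1139 bp, three singletons arranged 2+1 (h=3)."""
    base = "A" * BASE_LEN
    two_hits = "GG" + base[2:]
    one_hit = base[:2] + "G" + base[3:]
    return make_alignment([two_hits, one_hit] + [base] * 30)


def random_alignment(
    rng: np.random.Generator,
    n: int,
    length: int,
    n_pops: int = 1,
    p_gap: float = 0.0,
    p_n: float = 0.0,
    p_variant: float = 0.15,
) -> LocusAlignment:
    """Random alignment around a common backbone, optionally with gap
    and missing columns sprinkled in."""
    backbone = rng.choice(list("ACGT"), size=length)
    mat = np.tile(backbone, (n, 1))
    n_var = rng.binomial(length, p_variant)
    for j in rng.choice(length, size=n_var, replace=False):
        carriers = rng.choice(n, size=rng.integers(1, n), replace=False)
        alt = rng.choice([b for b in "ACGT" if b != backbone[j]])
        mat[carriers, j] = alt
    for j in range(length):
        if rng.random() < p_gap:
            mat[rng.integers(n), j] = "-"
        elif rng.random() < p_n:
            mat[rng.integers(n), j] = "N"
    seqs = ["".join(row) for row in mat]
    pops = [f"pop{1 + i % n_pops}" for i in range(n)]
    return make_alignment(seqs, pops)
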