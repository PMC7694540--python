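"""Alignment input/output, validation and site classification.

The pipeline works on per-locus multiple sequence alignments of *phased*
haplotypes (one FASTA per locus) plus a sample -> population/region map.
Columns are classified once per alignment under the "complete deletion"
convention: any column containing an alignment gap or missing/ambiguous
data is excluded from all nucleotide statistics, and indel columns are
tallied separately (they are never counted as SNPs).

Internally columns are 0-based half-open; report writers use 1-based
inclusive coordinates.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

NUCLEOTIDES = frozenset("ACGT")
GAP = "-"
MISSING = "N"

#: IUPAC ambiguity codes mapped to the set of bases they stand for.
IUPAC_AMBIGUITY = {
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

VALID_CHARS = NUCLEOTIDES | set(IUPAC_AMBIGUITY) | {GAP}

MONOMORPHIC = "monomorphic"
SEGREGATING = "segregating_SNP"
INDEL_COLUMN = "indel_column"
EXCLUDED_MISSING = "excluded_missing"


class AlignmentError(ValueError):
    """Raised for ragged or otherwise malformed alignments."""


class MetadataError(KeyError):
    """Raised when a sample id is missing from the population map."""


@dataclass
class SequenceRecord:
    """One phased haplotype with its population/region labels."""

    sample_id: str
    population: str
    region: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise AlignmentError(f"empty sequence for {self.sample_id!r}")
        bad = set(self.sequence) - VALID_CHARS
        if bad:
            raise AlignmentError(
                f"invalid characters {sorted(bad)} in {self.sample_id!r}"
            )


@dataclass
class LocusAlignment:
    """Aligned phased haplotypes for one locus.

    ``offset_kb`` is the locus position relative to the focal gene start
    (negative = upstream), used by the region-wide sweep scan.
    """

    locus_name: str
    records: list[SequenceRecord]
    offset_kb: float = 0.0

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise AlignmentError("an alignment needs at least 2 records")
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) != 1:
            raise AlignmentError(
                f"ragged alignment {self.locus_name!r}: lengths {sorted(lengths)}"
            )
        ids = [r.sample_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise AlignmentError("duplicate sample ids in alignment")

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def length(self) -> int:
        return len(self.records[0].sequence)

    @property
    def populations(self) -> list[str]:
        """Distinct population labels in input order."""
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.population, None)
        return list(seen)

    def matrix(self) -> np.ndarray:
        """(n, L) array of single characters."""
        return np.array([list(r.sequence) for r in self.records], dtype="U1")

    def column(self, j: int) -> list[str]:
        return [r.sequence[j] for r in self.records]

    def subset(self, sample_ids: Iterable[str]) -> "LocusAlignment":
        wanted = set(sample_ids)
        recs = [r for r in self.records if r.sample_id in wanted]
        return LocusAlignment(self.locus_name, recs, self.offset_kb)

    def by_population(self) -> dict[str, "LocusAlignment"]:
        out: dict[str, LocusAlignment] = {}
        for pop in self.populations:
            recs = [r for r in self.records if r.population == pop]
            if len(recs) >= 2:
                out[pop] = LocusAlignment(self.locus_name, recs, self.offset_kb)
        return out

    def slice_columns(self, start: int, stop: int) -> "LocusAlignment":
        recs = [
            SequenceRecord(r.sample_id, r.population, r.region,
                           r.sequence[start:stop])
            for r in self.records
        ]
        return LocusAlignment(self.locus_name, recs, self.offset_kb)


@dataclass
class SiteClassification:
    """Per-column status plus the counts the neutrality tests need.

    S counts columns with >= 2 states among {A,C,G,T}; eta is the total
    mutation count under an infinite-sites reading (alleles - 1 per
    segregating column); eta_s counts singleton mutations.
    """

    statuses: list[str]
    S: int
    eta: int
    eta_s: int
    n_indels: int

    @property
    def valid_columns(self) -> list[int]:
        return [j for j, s in enumerate(self.statuses)
                if s in (MONOMORPHIC, SEGREGATING)]

    @property
    def L_valid(self) -> int:
        return sum(1 for s in self.statuses if s in (MONOMORPHIC, SEGREGATING))

    @property
    def segregating_columns(self) -> list[int]:
        return [j for j, s in enumerate(self.statuses) if s == SEGREGATING]


def read_pop_map(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read a sample map TSV with header sample_id/population/region."""
    out: dict[str, tuple[str, str]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"sample_id", "population", "region"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise MetadataError(
                f"population map must have columns {sorted(required)}"
            )
        for row in reader:
            out[row["sample_id"]] = (row["population"], row["region"])
    return out


def read_fasta_alignment(
    path: str | Path,
    pop_map: dict[str, tuple[str, str]] | str | Path,
    locus_name: str | None = None,
    offset_kb: float = 0.0,
) -> LocusAlignment:
    """Read a FASTA alignment and attach population labels.

    Input order is preserved. Every FASTA id must be present in the
    population map.
    """
    if not isinstance(pop_map, dict):
        pop_map = read_pop_map(pop_map)
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id not in pop_map:
            raise MetadataError(f"sample {rec.id!r} absent from population map")
        pop, region = pop_map[rec.id]
        records.append(SequenceRecord(rec.id, pop, region, str(rec.seq)))
    if not records:
        raise AlignmentError(f"no sequences in {path}")
    return LocusAlignment(locus_name or path.stem, records, offset_kb)


def write_fasta_alignment(aln: LocusAlignment, path: str | Path) -> None:
    recs = [
        _BioSeqRecord(Seq(r.sequence), id=r.sample_id, description="")
        for r in aln.records
    ]
    SeqIO.write(recs, str(path), "fasta-2line")


def write_pop_map(aln: LocusAlignment, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_id", "population", "region"])
        for r in aln.records:
            w.writerow([r.sample_id, r.population, r.region])


def classify_sites(aln: LocusAlignment) -> SiteClassification:
    """Label every column and count S, eta, eta_s and indel columns.

    Complete deletion: a column containing "-" is an indel column; a
    column containing N or any other ambiguity code is excluded as
    missing; both are dropped from S and from all downstream
    nucleotide statistics.
    """
    statuses: list[str] = []
    S = eta = eta_s = n_indels = 0
    for j in range(aln.length):
        col = aln.column(j)
        chars = set(col)
        if GAP in chars:
            statuses.append(INDEL_COLUMN)
            n_indels += 1
            continue
        if chars - NUCLEOTIDES:
            statuses.append(EXCLUDED_MISSING)
            continue
        if len(chars) == 1:
            statuses.append(MONOMORPHIC)
            continue
        statuses.append(SEGREGATING)
        S += 1
        counts = Counter(col)
        n_alleles = len(counts)
        eta += n_alleles - 1
        ones = sum(1 for c in counts.values() if c == 1)
        # if every allele is a singleton, one of them is the "ancestral"
        eta_s += min(ones, n_alleles - 1)
    return SiteClassification(statuses, S, eta, eta_s, n_indels)


def resolve_heterozygotes(
    diploid_records: Sequence[SequenceRecord],
    mode: str = "split_random",
    seed: int | None = None,
) -> LocusAlignment:
    """Pseudo-phase diploid consensus sequences carrying IUPAC codes.

    ``split_random`` emits two haplotypes per individual, resolving each
    two-base ambiguity code to its two bases assigned uniformly at
    random between the pair (seeded). ``exclude_ambiguous`` emits the
    input with every ambiguous site masked to N. Statistical phasing is
    deliberately not attempted; properly phased input bypasses this.
    """
    if mode not in ("split_random", "exclude_ambiguous"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    out: list[SequenceRecord] = []
    for rec in diploid_records:
        bad = set(rec.sequence) - VALID_CHARS
        if bad:
            raise AlignmentError(f"non-IUPAC characters {sorted(bad)}")
        if mode == "exclude_ambiguous":
            seq = "".join(
                MISSING if c in IUPAC_AMBIGUITY else c for c in rec.sequence
            )
            out.append(SequenceRecord(rec.sample_id, rec.population,
                                      rec.region, seq))
            continue
        hap_a, hap_b = [], []
        for c in rec.sequence:
            if c in IUPAC_AMBIGUITY and c != MISSING:
                choices = IUPAC_AMBIGUITY[c]
                if len(choices) == 2:
                    a, b = choices if rng.random() < 0.5 else choices[::-1]
                else:  # 3/4-base codes: draw two distinct resolutions
                    a, b = rng.choice(list(choices), size=2, replace=False)
                hap_a.append(a)
                hap_b.append(b)
            else:
                hap_a.append(c)
                hap_b.append(c)
        for suffix, hap in (("_a", hap_a), ("_b", hap_b)):
            out.append(SequenceRecord(rec.sample_id + suffix, rec.population,
                                      rec.region, "".join(hap)))
    return LocusAlignment("phased", out)
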