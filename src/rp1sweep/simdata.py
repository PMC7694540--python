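"""Coalescent synthetic-data generator.

Generates phased haplotype alignments that emulate the data regime the
pipeline targets: several populations in two regional groups, six loci
spanning ~120 kb around a focal gene, near-panmixia within groups
(FST ~ 0.02), strong divergence between groups (FST 0.5-0.97), and a
selective sweep that collapses diversity in the swept group with
strength decaying with distance from the focal locus.

Model components
----------------
* Kingman coalescent genealogies (time in units of 2N generations),
  infinite-sites mutation at rate theta/2 per unit branch length,
  mutations mapped to distinct uniform positions on an L-bp sequence.
* Hard/partial sweeps via the star-genealogy approximation: a fraction
  f of sampled lineages coalesces instantly at a very recent common
  ancestor before neutral coalescence of the remainder.
* Population structure via the symmetric n-island structured
  coalescent (per-lineage migration rate M/2) and, between regional
  groups, a clean two-epoch split with no migration, deep enough to put
  between-group FST in the strongly differentiated regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np

from .alignio import LocusAlignment, SequenceRecord

BASES = np.array(list("ACGT"))

#: Locus layout of the scanned region: name -> (offset from the focal
#: gene start in kb, fragment length in bp).
DEFAULT_REGION_LAYOUT = {
    "0BAC": (-34.0, 626),
    "25BAC": (-9.0, 754),
    "CYP6P9a": (0.0, 1139),
    "63BAC": (29.0, 614),
    "95BAC": (61.0, 671),
    "120BAC": (86.0, 633),
}

DEFAULT_GROUPS = {
    "MOZ": "southern", "MAL": "southern", "ZB": "southern", "TZ": "southern",
    "UG": "eastern_central", "DRC": "eastern_central", "CAM": "eastern_central",
}


@dataclass
class SimulationConfig:
    """Study-condition defaults for the six-locus regional dataset.

    theta is per locus (per sequence, not per site); sample sizes mirror
    a ~10-diploid-per-population survey (20 phased haplotypes). The
    sweep strength decays exponentially with distance from the focal
    locus: f(d) = f0 * exp(-d / decay_kb).
    """

    n_per_pop: int = 20
    theta: float = 3.0
    M: float = 10.0
    f0: float = 0.95
    decay_kb: float = 75.0
    t_split: float = 4.0
    swept_group: str = "southern"
    groups: dict = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    layout: dict = field(default_factory=lambda: dict(DEFAULT_REGION_LAYOUT))
    focal_locus: str = "CYP6P9a"
    seed: int = 0

    def sweep_strength(self, offset_kb: float) -> float:
        return float(self.f0 * np.exp(-abs(offset_kb) / self.decay_kb))


@dataclass
class Genealogy:
    """A coalescent tree: nodes 0..n-1 are leaves; parents added later."""

    n: int
    parent: list
    time: list

    def n_nodes(self) -> int:
        return len(self.parent)

    def branch_lengths(self) -> np.ndarray:
        out = np.zeros(self.n_nodes())
        for v, p in enumerate(self.parent):
            if p is not None:
                out[v] = self.time[p] - self.time[v]
        return out

    def leaf_sets(self) -> list[frozenset]:
        """Descendant leaves below each node (below its parent edge)."""
        sets = [set() for _ in range(self.n_nodes())]
        for v in range(self.n):
            sets[v].add(v)
        # parents always have higher index than children by construction
        for v in range(self.n_nodes()):
            p = self.parent[v]
            if p is not None:
                sets[p].update(sets[v])
        return [frozenset(s) for s in sets]

    def total_length(self) -> float:
        return float(self.branch_lengths().sum())


class _TreeBuilder:
    """Incrementally build a genealogy from coalescence events."""

    def __init__(self, n: int):
        self.n = n
        self.parent: list = [None] * n
        self.time: list = [0.0] * n

    def merge(self, a: int, b: int, t: float) -> int:
        new = len(self.parent)
        self.parent.append(None)
        self.time.append(t)
        self.parent[a] = new
        self.parent[b] = new
        return new

    def merge_many(self, nodes: list[int], t: float) -> int:
        new = len(self.parent)
        self.parent.append(None)
        self.time.append(t)
        for v in nodes:
            self.parent[v] = new
        return new

    def done(self) -> Genealogy:
        return Genealogy(self.n, self.parent, self.time)


def kingman_genealogy(n: int, rng: np.random.Generator) -> Genealogy:
    """Neutral panmictic coalescent tree for n lineages."""
    tb = _TreeBuilder(n)
    active = list(range(n))
    t = 0.0
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(1.0 / comb(k, 2))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        active = [v for v in active if v not in (a, b)]
        active.append(tb.merge(a, b, t))
    return tb.done()


def star_sweep_genealogy(
    n: int, f: float, rng: np.random.Generator, eps: float = 1e-9
) -> Genealogy:
    """Partial-sweep genealogy: round(f*n) lineages join a star ancestor.

    The star component coalesces at time ``eps``; the star ancestor and
    the untouched lineages then coalesce neutrally. f=0 reduces to the
    plain Kingman tree; f=1 yields an (almost) star genealogy.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("sweep strength f must lie in [0, 1]")
    m = int(round(f * n))
    tb = _TreeBuilder(n)
    leaves = list(rng.permutation(n))
    if m >= 2:
        star = tb.merge_many([int(v) for v in leaves[:m]], eps)
        active = [star] + [int(v) for v in leaves[m:]]
    else:
        active = [int(v) for v in leaves]
    t = eps
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(1.0 / comb(k, 2))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        active = [v for v in active if v not in (a, b)]
        active.append(tb.merge(a, b, t))
    return tb.done()


def _structured_phase(
    tb: _TreeBuilder,
    lineages: list[tuple[int, int]],
    n_demes: int,
    M: float,
    rng: np.random.Generator,
    t_start: float,
    t_max: float,
) -> tuple[list[tuple[int, int]], float]:
    """Island-model coalescence of (node, deme) lineages until t_max.

    Within-deme pairs coalesce at rate 1 per pair (time in units of
    2N_deme); each lineage migrates to a uniform other deme at rate M/2.
    Returns the surviving lineages and the stop time.
    """
    t = t_start
    while len(lineages) > 1:
        per_deme: dict[int, list[int]] = {}
        for idx, (_, d) in enumerate(lineages):
            per_deme.setdefault(d, []).append(idx)
        coal_rate = sum(comb(len(v), 2) for v in per_deme.values())
        mig_rate = len(lineages) * M / 2.0 if n_demes > 1 else 0.0
        total = coal_rate + mig_rate
        if total == 0.0:
            # isolated singleton lineages: no further event can happen
            return lineages, t
        wait = rng.exponential(1.0 / total)
        if t + wait >= t_max:
            return lineages, t_max
        t += wait
        if rng.random() < coal_rate / total:
            demes = [d for d, v in per_deme.items() if len(v) >= 2]
            weights = np.array([comb(len(per_deme[d]), 2) for d in demes], float)
            d = demes[rng.choice(len(demes), p=weights / weights.sum())]
            i, j = rng.choice(len(per_deme[d]), size=2, replace=False)
            ia, ib = per_deme[d][i], per_deme[d][j]
            node = tb.merge(lineages[ia][0], lineages[ib][0], t)
            lineages = [l for x, l in enumerate(lineages) if x not in (ia, ib)]
            lineages.append((node, d))
        else:
            idx = int(rng.integers(len(lineages)))
            node, d = lineages[idx]
            new_d = int(rng.integers(n_demes - 1))
            if new_d >= d:
                new_d += 1
            lineages[idx] = (node, new_d)
    return lineages, t


def island_genealogy(
    n_per_deme: list[int], M: float, rng: np.random.Generator,
    t_isolation: float = 8.0,
) -> Genealogy:
    """Symmetric island-model structured coalescent to the MRCA.

    With M = 0 the demes never share ancestry under the island model
    proper; the generator then merges the stranded deme ancestors in a
    single ancestral population ``t_isolation`` coalescent time units
    deeper (a long-isolation split, the strongly differentiated
    regime).
    """
    n = sum(n_per_deme)
    tb = _TreeBuilder(n)
    lineages: list[tuple[int, int]] = []
    node = 0
    for d, nd in enumerate(n_per_deme):
        for _ in range(nd):
            lineages.append((node, d))
            node += 1
    lineages, t = _structured_phase(
        tb, lineages, len(n_per_deme), M, rng, 0.0, np.inf
    )
    if len(lineages) > 1:
        active = [v for v, _ in lineages]
        t += t_isolation
        while len(active) > 1:
            k = len(active)
            t += rng.exponential(1.0 / comb(k, 2))
            i, j = rng.choice(k, size=2, replace=False)
            a, b = active[i], active[j]
            active = [v for v in active if v not in (a, b)]
            active.append(tb.merge(a, b, t))
    return tb.done()


def drop_mutations(
    tree: Genealogy, theta: float, rng: np.random.Generator
) -> list[frozenset]:
    """Poisson(theta/2 x branch length) mutations; returns carrier sets."""
    lengths = tree.branch_lengths()
    total = lengths.sum()
    n_mut = rng.poisson(theta / 2.0 * total)
    return _place_mutations(tree, n_mut, lengths, rng)


def drop_fixed_mutations(
    tree: Genealogy, s: int, rng: np.random.Generator
) -> list[frozenset]:
    """Exactly s mutations placed on branches proportionally to length."""
    return _place_mutations(tree, s, tree.branch_lengths(), rng)


def _place_mutations(tree, n_mut, lengths, rng) -> list[frozenset]:
    if n_mut == 0:
        return []
    sets = tree.leaf_sets()
    p = lengths / lengths.sum()
    branches = rng.choice(len(lengths), size=n_mut, p=p)
    return [sets[int(b)] for b in branches]


def sequences_from_mutations(
    carriers: list[frozenset],
    n: int,
    L: int,
    rng: np.random.Generator,
) -> list[str]:
    """Map mutations to uniform positions and emit haplotype strings.

    Positions are drawn without replacement (infinite sites on a finite
    sequence); when mutations outnumber sites the draw falls back to
    sampling with replacement (finite-sites fallback, recurrent hits
    applied in order).
    """
    ancestral = rng.choice(BASES, size=L)
    mat = np.tile(ancestral, (n, 1))
    n_mut = len(carriers)
    if n_mut <= L:
        positions = rng.choice(L, size=n_mut, replace=False)
    else:
        positions = rng.choice(L, size=n_mut, replace=True)
    for pos, leafset in zip(positions, carriers):
        if not leafset or len(leafset) == n:
            continue
        rows = list(leafset)
        current = mat[rows[0], pos]
        derived = rng.choice([b for b in "ACGT" if b != current])
        mat[rows, pos] = derived
    return ["".join(row) for row in mat]


def _make_alignment(
    seqs: list[str],
    labels: list[tuple[str, str]],
    locus_name: str,
    offset_kb: float = 0.0,
) -> LocusAlignment:
    counters: dict[str, int] = {}
    records = []
    for seq, (pop, region) in zip(seqs, labels):
        counters[pop] = counters.get(pop, 0) + 1
        records.append(
            SequenceRecord(f"{pop}_h{counters[pop]:03d}", pop, region, seq)
        )
    return LocusAlignment(locus_name, records, offset_kb)


def coalescent_locus(
    n: int, theta: float, L: int, seed: int | np.random.Generator | None = None,
    locus_name: str = "sim", population: str = "simpop", region: str = "simregion",
) -> LocusAlignment:
    """Neutral coalescent sample of n haplotypes of length L."""
    if n < 2:
        raise ValueError("need n >= 2")
    rng = _as_rng(seed)
    tree = kingman_genealogy(n, rng)
    carriers = drop_mutations(tree, theta, rng)
    seqs = sequences_from_mutations(carriers, n, L, rng)
    return _make_alignment(seqs, [(population, region)] * n, locus_name)


def apply_star_sweep(
    n: int, theta: float, L: int, f: float,
    seed: int | np.random.Generator | None = None,
    locus_name: str = "sim_sweep", population: str = "simpop",
    region: str = "simregion",
) -> LocusAlignment:
    """Coalescent sample whose genealogy carries a partial star sweep."""
    rng = _as_rng(seed)
    tree = star_sweep_genealogy(n, f, rng)
    carriers = drop_mutations(tree, theta, rng)
    seqs = sequences_from_mutations(carriers, n, L, rng)
    return _make_alignment(seqs, [(population, region)] * n, locus_name)


def island_model_dataset(
    npops: int, n_per_pop: int, theta: float, M: float,
    seed: int | np.random.Generator | None = None,
    L: int = 1000, locus_name: str = "sim_island",
) -> LocusAlignment:
    """Structured sample under the symmetric island model.

    Returns one pooled alignment with population labels pop1..popN;
    use :meth:`LocusAlignment.by_population` for the partitions.
    """
    if npops < 2:
        raise ValueError("need npops >= 2")
    rng = _as_rng(seed)
    tree = island_genealogy([n_per_pop] * npops, M, rng)
    carriers = drop_mutations(tree, theta, rng)
    n = npops * n_per_pop
    seqs = sequences_from_mutations(carriers, n, L, rng)
    labels = [(f"pop{d + 1}", "simregion")
              for d in range(npops) for _ in range(n_per_pop)]
    return _make_alignment(seqs, labels, locus_name)


def two_group_sweep_genealogy(
    group_sizes: dict[str, list[int]],
    swept_group: str | None,
    f: float,
    M: float,
    t_split: float,
    rng: np.random.Generator,
) -> tuple[Genealogy, list[str]]:
    """Two regional groups of demes, split t_split ago, optional sweep.

    Within each group demes exchange migrants at rate M (island model);
    between groups there is no migration until the ancestral merge at
    t_split. In the swept group a fraction f of all its lineages first
    coalesces in a star at time ~0.

    Returns the genealogy and the group label of each leaf in order.
    """
    group_names = list(group_sizes)
    n_total = sum(sum(v) for v in group_sizes.values())
    tb = _TreeBuilder(n_total)
    leaf_groups: list[str] = []
    per_group_lineages: dict[str, list[tuple[int, int]]] = {}
    node = 0
    for g in group_names:
        lineages = []
        for d, nd in enumerate(group_sizes[g]):
            for _ in range(nd):
                lineages.append((node, d))
                leaf_groups.append(g)
                node += 1
        per_group_lineages[g] = lineages

    if swept_group is not None and f > 0:
        lineages = per_group_lineages[swept_group]
        m = int(round(f * len(lineages)))
        if m >= 2:
            idx = rng.choice(len(lineages), size=m, replace=False)
            chosen = [lineages[int(i)] for i in idx]
            star = tb.merge_many([v for v, _ in chosen], 1e-9)
            rest = [l for x, l in enumerate(lineages) if x not in set(int(i) for i in idx)]
            per_group_lineages[swept_group] = rest + [(star, chosen[0][1])]

    survivors: list[tuple[int, int]] = []
    for g in group_names:
        lin, _ = _structured_phase(
            tb, per_group_lineages[g], len(group_sizes[g]), M, rng,
            1e-9, t_split,
        )
        survivors.extend(lin)
    # ancestral panmictic phase
    active = [v for v, _ in survivors]
    t = t_split
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(1.0 / comb(k, 2))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        active = [v for v in active if v not in (a, b)]
        active.append(tb.merge(a, b, t))
    return tb.done(), leaf_groups


def rp1_region_dataset(
    config: SimulationConfig | None = None,
    seed: int | np.random.Generator | None = None,
) -> dict[str, LocusAlignment]:
    """Six-locus regional dataset emulating the sweep/structure signal.

    The swept group receives a star sweep of strength f(|offset|) at
    every locus (maximal at the focal locus); both groups are island
    models internally and split ``t_split`` coalescent time units ago.
    Returns one labelled alignment per locus, keyed by locus name.
    """
    config = config or SimulationConfig()
    rng = _as_rng(config.seed if seed is None else seed)
    group_pops: dict[str, list[str]] = {}
    for pop, g in config.groups.items():
        group_pops.setdefault(g, []).append(pop)
    out: dict[str, LocusAlignment] = {}
    for locus, (offset, L) in config.layout.items():
        group_sizes = {g: [config.n_per_pop] * len(pops)
                       for g, pops in group_pops.items()}
        f = config.sweep_strength(offset)
        tree, leaf_groups = two_group_sweep_genealogy(
            group_sizes, config.swept_group, f, config.M, config.t_split, rng
        )
        carriers = drop_mutations(tree, config.theta, rng)
        n = tree.n
        seqs = sequences_from_mutations(carriers, n, L, rng)
        labels = []
        for g in group_pops:
            for pop in group_pops[g]:
                labels.extend([(pop, g)] * config.n_per_pop)
        out[locus] = _make_alignment(seqs, labels, locus, offset)
    return out


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
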