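"""Statistical-parsimony (TCS-style) haplotype networks.

Haplotypes are collapsed over full-length sequences with the alignment
gap kept as a fifth character state (a 3-bp deletion therefore counts
as 3 mutational steps). Haplotypes are joined in increasing distance
order up to the 95% connection limit, inserting unobserved
intermediate nodes so that every edge spans exactly one mutational
step; by default links that would close a cycle are dropped
(single-spanning-forest mode).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx

from .alignio import LocusAlignment


@dataclass
class Haplotype:
    id: str
    sequence: str
    frequency: int
    pop_composition: dict[str, int] = field(default_factory=dict)


@dataclass
class ParsimonyNetwork:
    graph: nx.Graph
    j95: int
    haplotypes: list[Haplotype]

    @property
    def components(self) -> list[set[str]]:
        return [set(c) for c in nx.connected_components(self.graph)]

    def to_dot(self) -> str:
        lines = ["graph haplotype_network {", "  node [shape=circle];"]
        for node, data in sorted(self.graph.nodes(data=True)):
            freq = data.get("frequency", 0)
            if freq:
                lines.append(f'  "{node}" [label="{node}\\n{freq}"];')
            else:
                lines.append(
                    f'  "{node}" [label="", shape=point];'
                )
        for a, b in sorted(self.graph.edges()):
            lines.append(f'  "{a}" -- "{b}";')
        lines.append("}")
        return "\n".join(lines)


def collapse_haplotypes(aln: LocusAlignment) -> list[Haplotype]:
    """Merge identical sequences (gap = fifth state) into haplotypes.

    Haplotypes are numbered H1, H2, ... in decreasing frequency, ties
    broken by first appearance in the alignment.
    """
    order: dict[str, int] = {}
    freq: dict[str, int] = {}
    pops: dict[str, dict[str, int]] = {}
    for i, rec in enumerate(aln.records):
        seq = rec.sequence
        if seq not in order:
            order[seq] = i
            freq[seq] = 0
            pops[seq] = {}
        freq[seq] += 1
        pops[seq][rec.population] = pops[seq].get(rec.population, 0) + 1
    ranked = sorted(freq, key=lambda s: (-freq[s], order[s]))
    return [
        Haplotype(f"H{i + 1}", seq, freq[seq], pops[seq])
        for i, seq in enumerate(ranked)
    ]


def parsimony_probability(j: int, L: int) -> float:
    """Probability that a j-step connection over L characters is
    non-homoplasious.

    Per-site change counts are modelled as Poisson with mean lambda
    estimated from the observed difference fraction j/L
    (lambda = -ln(1 - j/L)); a connection is parsimonious when each of
    the j differing sites changed exactly once, so
    P_j = [lambda e^-lambda / (1 - e^-lambda)]^j. P_j is non-increasing
    in j for fixed L.
    """
    if j <= 0:
        return 1.0
    if j >= L:
        return 0.0
    lam = -math.log(1.0 - j / L)
    r = lam * math.exp(-lam) / (1.0 - math.exp(-lam))
    return r**j


def parsimony_connection_limit(L_valid: int, alpha: float = 0.95) -> int:
    """Largest j with parsimony probability >= alpha (connection limit)."""
    if L_valid < 1:
        raise ValueError("need at least one character")
    j = 0
    while j + 1 < L_valid and parsimony_probability(j + 1, L_valid) >= alpha:
        j += 1
    return j


def _fifth_state_distance(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def build_statistical_parsimony_network(
    haplotypes: list[Haplotype],
    j95: int,
    allow_cycles: bool = False,
) -> ParsimonyNetwork:
    """Join haplotypes in increasing distance order up to j95 steps.

    Ties are broken by (higher joint frequency first, then
    lexicographic id pair); multi-step links insert unobserved
    intermediate nodes named "<a>~<b>/<i>". With ``allow_cycles`` all
    equal-distance admissible links are retained for display; the
    default keeps a spanning forest.
    """
    g = nx.Graph()
    for h in haplotypes:
        g.add_node(h.id, frequency=h.frequency,
                   pop_composition=dict(h.pop_composition),
                   sequence=h.sequence)
    pairs = []
    for i, a in enumerate(haplotypes):
        for b in haplotypes[i + 1:]:
            d = _fifth_state_distance(a.sequence, b.sequence)
            pairs.append((d, -(a.frequency + b.frequency),
                          tuple(sorted((a.id, b.id))), a, b))
    pairs.sort()
    for d, _, _, a, b in pairs:
        if d > j95:
            continue
        if nx.has_path(g, a.id, b.id):
            joined = allow_cycles and nx.shortest_path_length(
                g, a.id, b.id) == d
            if not joined:
                continue
        prev = a.id
        for step in range(1, d):
            mid = f"{a.id}~{b.id}/{step}"
            g.add_node(mid, frequency=0, pop_composition={}, sequence=None)
            g.add_edge(prev, mid, steps=1)
            prev = mid
        g.add_edge(prev, b.id, steps=1)
    return ParsimonyNetwork(g, j95, haplotypes)


def haplotype_network(
    aln: LocusAlignment,
    alpha: float = 0.95,
    allow_cycles: bool = False,
) -> ParsimonyNetwork:
    """Collapse haplotypes, set the connection limit, build the network."""
    haps = collapse_haplotypes(aln)
    j95 = parsimony_connection_limit(aln.length, alpha)
    return build_statistical_parsimony_network(haps, j95, allow_cycles)


def network_tables(net: ParsimonyNetwork) -> tuple[str, str]:
    """(node TSV, edge TSV) for report files."""
    pops = sorted({p for h in net.haplotypes for p in h.pop_composition})
    node_lines = ["\t".join(["id", "frequency"] + pops)]
    for h in net.haplotypes:
        row = [h.id, str(h.frequency)] + [
            str(h.pop_composition.get(p, 0)) for p in pops
        ]
        node_lines.append("\t".join(row))
    edge_lines = ["node_a\tnode_b\tsteps"]
    for a, b in sorted(net.graph.edges()):
        edge_lines.append(f"{a}\t{b}\t1")
    return "\n".join(node_lines) + "\n", "\n".join(edge_lines) + "\n"
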