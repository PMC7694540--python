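"""TSV report writers for the per-locus summary tables."""

from __future__ import annotations

import numpy as np

from .alignio import LocusAlignment, classify_sites
from .codonsel import CodonCountTable
from .diversity import diversity_summary
from .neutrality import (
    fu_li_dstar,
    fus_fs,
    neutrality_significance,
    significance_stars,
    tajimas_d,
)

SUMMARY_COLUMNS = ["population", "2n", "S", "h", "hd", "pi", "D", "Dstar", "FS"]


def _fmt(value, digits, star="") -> str:
    if value is None:
        return "-"
    txt = f"{value:.{digits}f}"
    return f"{txt} {star}" if star else txt


def diversity_table_tsv(
    aln: LocusAlignment,
    per_population: bool = True,
    n_sims: int = 0,
    seed: int | None = None,
) -> str:
    """Per-population summary rows (2n, S, h, hd, pi, D, D*, FS).

    Undefined statistics are rendered "-"; with ``n_sims`` > 0,
    significance stars from the seeded coalescent null are appended.
    Ends with an "Overall" row across all sequences.
    """
    rng = np.random.default_rng(seed)
    groups: list[tuple[str, LocusAlignment]] = []
    if per_population:
        groups.extend(aln.by_population().items())
    groups.append(("Overall", aln))
    lines = ["\t".join(SUMMARY_COLUMNS)]
    for name, sub in groups:
        sites = classify_sites(sub)
        summ = diversity_summary(sub)
        d = tajimas_d(summ.k, summ.S, sub.n)
        dstar = fu_li_dstar(sites.eta, sites.eta_s, sub.n)
        fs = fus_fs(summ.k, summ.h, sub.n)
        stars = {"D": "", "Dstar": "", "FS": ""}
        if n_sims > 0:
            if d is not None:
                p = neutrality_significance("D", d, sub.n, S=summ.S,
                                            n_sims=n_sims, seed=rng)
                stars["D"] = significance_stars("D", p)
            if dstar is not None:
                p = neutrality_significance("Dstar", dstar, sub.n, S=summ.S,
                                            n_sims=n_sims, seed=rng)
                stars["Dstar"] = significance_stars("Dstar", p)
            if fs is not None:
                p = neutrality_significance("FS", fs, sub.n, theta=summ.k,
                                            n_sims=n_sims, seed=rng)
                stars["FS"] = significance_stars("FS", p)
        hd = "-" if summ.S == 0 else f"{summ.Hd:.2f}"
        lines.append("\t".join([
            name, str(summ.n2), str(summ.S), str(summ.h), hd,
            f"{summ.pi:.5f}",
            _fmt(d, 2, stars["D"]),
            _fmt(dstar, 2, stars["Dstar"]),
            _fmt(fs, 2, stars["FS"]),
        ]))
    return "\n".join(lines) + "\n"


PNPS_COLUMNS = [
    "population", "syn_sites", "syn_subs", "pS",
    "nonsyn_sites", "nonsyn_subs", "pN", "pN_pS",
]


def pnps_table_tsv(counts: dict[str, CodonCountTable]) -> str:
    """Per-population codon polymorphism table (sites, subs, pS, pN,
    pN/pS), with "-" when the ratio cannot be formed."""
    lines = ["\t".join(PNPS_COLUMNS)]
    for name, c in counts.items():
        ratio = c.ratio
        lines.append("\t".join([
            name,
            f"{c.syn_sites:.2f}", f"{c.syn_subs:g}", f"{c.pS:.3f}",
            f"{c.nonsyn_sites:.2f}", f"{c.nonsyn_subs:g}", f"{c.pN:.3f}",
            "-" if ratio is None else f"{ratio:.2f}",
        ]))
    return "\n".join(lines) + "\n"
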