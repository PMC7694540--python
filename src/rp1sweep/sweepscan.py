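"""Region-wide sweep scan: per-locus, per-population profiles and
cross-group diversity ratios.

Orchestrates the single-locus modules over a region layout (six loci
spanning ~120 kb around a focal resistance gene), groups populations
into regions (e.g. southern vs eastern/central Africa), computes the
per-locus ratio of group mean diversity and calls locus-group pairs
"swept" against configurable thresholds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .alignio import LocusAlignment, classify_sites, read_fasta_alignment
from .diversity import diversity_summary
from .neutrality import neutrality_significance, significance_stars, tajimas_d


@dataclass
class LocusSpec:
    name: str
    offset_kb: float
    alignment: LocusAlignment


@dataclass
class RegionConfig:
    """Layout of the scanned region plus the population grouping."""

    loci: list[LocusSpec]
    groups: dict[str, str]
    focal_locus: str

    def __post_init__(self) -> None:
        offsets = [l.offset_kb for l in self.loci]
        if len(set(offsets)) != len(offsets):
            raise ValueError("locus offsets must be unique")
        names = [l.name for l in self.loci]
        if self.focal_locus not in names:
            raise ValueError(f"focal locus {self.focal_locus!r} not in loci")

    @classmethod
    def from_file(cls, path: str | Path) -> "RegionConfig":
        """Load a YAML/JSON config: loci (name, offset_kb, fasta),
        groups (population -> group), focal_locus, pop_map."""
        path = Path(path)
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        base = path.parent
        pop_map_path = cfg.get("pop_map")
        pop_map = None
        if pop_map_path:
            from .alignio import read_pop_map

            pop_map = read_pop_map(base / pop_map_path)
        loci = []
        for entry in cfg["loci"]:
            aln = read_fasta_alignment(
                base / entry["fasta"],
                pop_map if pop_map is not None else {},
                locus_name=entry["name"],
                offset_kb=float(entry["offset_kb"]),
            )
            loci.append(LocusSpec(entry["name"], float(entry["offset_kb"]), aln))
        return cls(loci, dict(cfg["groups"]), cfg["focal_locus"])


@dataclass
class SweepThresholds:
    """Sweep-call configuration.

    A locus-group pair is "swept" when the group's mean pi and Hd fall
    below the given fractions of the reference group's means at the
    same locus and the group's mean Tajima's D is negative-significant
    (p <= alpha when a permutation/simulation p is available, else
    D <= d_max). A monomorphic group is flagged outright.
    """

    pi_frac: float = 0.25
    hd_frac: float = 0.5
    d_max: float = -1.0
    alpha: float = 0.05


def region_config_from_alignments(
    alignments: dict[str, LocusAlignment],
    groups: dict[str, str],
    focal_locus: str,
) -> RegionConfig:
    loci = [
        LocusSpec(name, aln.offset_kb, aln)
        for name, aln in alignments.items()
    ]
    return RegionConfig(loci, groups, focal_locus)


def per_locus_profile(
    config: RegionConfig,
    n_sims: int = 0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Hd, pi and Tajima's D for every (locus, population).

    One row per pair; statistics undefined for monomorphic samples are
    NaN (rendered "n.a" by the report writer). ``n_sims`` > 0 adds
    empirical significance for D from the fixed-S coalescent null.
    """
    rows = []
    rng = np.random.default_rng(seed)
    for spec in config.loci:
        pops = spec.alignment.by_population()
        for pop in config.groups:
            if pop not in pops:
                rows.append(
                    dict(locus=spec.name, offset_kb=spec.offset_kb,
                         population=pop, group=config.groups[pop],
                         n2=0, S=np.nan, h=np.nan, Hd=np.nan, pi=np.nan,
                         D=np.nan, p_D=np.nan, flagged_missing=True)
                )
                continue
            aln = pops[pop]
            summ = diversity_summary(aln)
            # D needs n2 >= 4; smaller samples get an undefined cell
            d = tajimas_d(summ.k, summ.S, aln.n) if aln.n >= 4 else None
            p_d = np.nan
            if d is not None and n_sims > 0:
                p_d = neutrality_significance(
                    "D", d, aln.n, S=summ.S, n_sims=n_sims, seed=rng
                )
            rows.append(
                dict(locus=spec.name, offset_kb=spec.offset_kb,
                     population=pop, group=config.groups[pop],
                     n2=summ.n2, S=summ.S, h=summ.h, Hd=summ.Hd,
                     pi=summ.pi, D=np.nan if d is None else d, p_D=p_d,
                     flagged_missing=False)
            )
    return pd.DataFrame(rows)


def group_pi_ratio(
    table: pd.DataFrame,
    comparison_group: str,
    reference_group: str,
    mode: str = "mean",
    config: RegionConfig | None = None,
) -> pd.Series:
    """Per-locus ratio of group diversity, comparison over reference.

    ``mean`` (default): ratio of unweighted means of per-population
    pi. ``pooled``: ratio of pi computed on the per-group pooled
    alignments (requires ``config``). Loci whose reference mean is 0
    get NaN (undefined, flagged).
    """
    if mode == "pooled":
        if config is None:
            raise ValueError("pooled mode needs the RegionConfig")
        out = {}
        for spec in config.loci:
            pis = {}
            for grp in (comparison_group, reference_group):
                pops = [p for p, g in config.groups.items() if g == grp]
                recs = [r for r in spec.alignment.records
                        if r.population in pops]
                sub = LocusAlignment(spec.name, recs, spec.offset_kb)
                pis[grp] = diversity_summary(sub).pi
            ref = pis[reference_group]
            out[spec.name] = np.nan if ref == 0 else pis[comparison_group] / ref
        return pd.Series(out, name="pi_ratio")
    if mode != "mean":
        raise ValueError(f"unknown mode {mode!r}")
    means = (
        table.dropna(subset=["pi"])
        .groupby(["locus", "group"], sort=False)["pi"]
        .mean()
        .unstack("group")
    )
    ref = means[reference_group]
    ratio = means[comparison_group] / ref.where(ref > 0)
    ratio.name = "pi_ratio"
    return ratio


def sweep_report(
    table: pd.DataFrame,
    reference_group: str,
    thresholds: SweepThresholds | None = None,
    config: RegionConfig | None = None,
) -> dict:
    """Flag swept locus-group pairs and summarise the sweep extent."""
    thr = thresholds or SweepThresholds()
    groups = [g for g in table["group"].unique() if g != reference_group]
    calls = []
    for locus in table["locus"].unique():
        sub = table[table["locus"] == locus]
        ref = sub[sub["group"] == reference_group]
        ref_pi = float(ref["pi"].mean())
        ref_hd = float(ref["Hd"].mean())
        offset = float(sub["offset_kb"].iloc[0])
        for grp in groups:
            g = sub[(sub["group"] == grp) & (~sub["flagged_missing"])]
            if g.empty:
                continue
            g_pi = float(g["pi"].mean())
            g_hd = float(g["Hd"].mean())
            g_d = float(g["D"].mean()) if g["D"].notna().any() else np.nan
            g_p = float(g["p_D"].mean()) if g["p_D"].notna().any() else np.nan
            monomorphic = bool((g["S"] == 0).all())
            if monomorphic:
                swept = True
            else:
                low_pi = ref_pi > 0 and g_pi <= thr.pi_frac * ref_pi
                low_hd = ref_hd > 0 and g_hd <= thr.hd_frac * ref_hd
                if not np.isnan(g_p):
                    d_sig = g_d < 0 and g_p <= thr.alpha
                else:
                    d_sig = not np.isnan(g_d) and g_d <= thr.d_max
                swept = low_pi and low_hd and d_sig
            calls.append(
                dict(locus=locus, offset_kb=offset, group=grp,
                     swept=bool(swept), mean_pi=g_pi, mean_Hd=g_hd,
                     mean_D=None if np.isnan(g_d) else g_d,
                     monomorphic=monomorphic)
            )
    swept_calls = [c for c in calls if c["swept"]]
    extent = None
    if swept_calls:
        offsets = [c["offset_kb"] for c in swept_calls]
        extent = dict(min_offset_kb=min(offsets), max_offset_kb=max(offsets),
                      span_kb=max(offsets) - min(offsets))
    return dict(
        reference_group=reference_group,
        thresholds=vars(thr),
        calls=calls,
        n_swept=len(swept_calls),
        extent=extent,
    )


def scan_table_tsv(
    table: pd.DataFrame,
    ratios: pd.Series | None = None,
) -> str:
    """Region-scan report: one locus row, per-population hd / pi*1e3 / D
    cell triplets, with "n.a" for undefined statistics."""
    pops = list(dict.fromkeys(table["population"]))
    header = ["locus", "offset_kb"]
    for p in pops:
        header += [f"{p}_hd", f"{p}_pi_x1e3", f"{p}_D"]
    if ratios is not None:
        header.append("pi_ratio")
    lines = ["\t".join(header)]
    for locus in dict.fromkeys(table["locus"]):
        sub = table[table["locus"] == locus].set_index("population")
        row = [str(locus), f"{sub['offset_kb'].iloc[0]:g}"]
        for p in pops:
            if p not in sub.index or sub.loc[p, "flagged_missing"]:
                row += ["n.a", "n.a", "n.a"]
                continue
            r = sub.loc[p]
            # monomorphic samples: Hd and D are reported "n.a", pi as 0
            hd = ("n.a" if np.isnan(r["Hd"]) or r["S"] == 0
                  else f"{r['Hd']:.2f}")
            pi = "n.a" if np.isnan(r["pi"]) else f"{1e3 * r['pi']:.2f}"
            if np.isnan(r["D"]):
                dcell = "n.a"
            else:
                star = significance_stars(
                    "D", None if np.isnan(r["p_D"]) else r["p_D"]
                )
                dcell = f"{r['D']:.2f}" + (f" {star}" if star else "")
            row += [hd, pi, dcell]
        if ratios is not None:
            val = ratios.get(locus, np.nan)
            row.append("n.a" if np.isnan(val) else f"{val:.2f}")
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def sweep_report_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True)
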