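# rp1sweep

Population-genetic analysis of selective sweeps and gene-flow barriers
from per-locus amplicon alignments of phased haplotypes, built around
the workflow used to characterise insecticide-resistance sweeps in the
malaria vector *Anopheles funestus*: the *CYP6P9a* resistance gene and
five flanking fragments spanning ~120 kb of the *rp1* (resistance to
pyrethroids 1) QTL, surveyed in populations from southern, eastern and
central Africa.

It is aimed at molecular ecologists and vector-biology groups who
sequence a handful of loci in a few dozen individuals per population
and want DnaSP/TCS/MEGA-style analyses as a scriptable, seeded,
reproducible pipeline.

## What it computes

For each locus and population, with complete deletion of gap/missing
columns:

- **Diversity** — segregating sites *S*, mean pairwise differences
  *k*, nucleotide diversity π = k/L, haplotype count *h* and diversity
  Hd = n/(n−1)(1 − Σp²), Watterson's θ_W = S/a₁, and sliding-window π
  (default 400 bp windows, 100 bp steps).
- **Neutrality tests** — Tajima's D = (k − S/a₁)/√(e₁S + e₂S(S−1));
  Fu & Li's D* (no outgroup, corrected coefficients), contrasting
  singleton with total mutations; Fu's F_S = ln(S′/(1−S′)) with
  S′ = P(K ≥ h_obs | θ̂ = k) under the Ewens sampling formula.
  Significance is empirical, from a seeded neutral-coalescent null
  (fixed-S for D and D*, θ̂-parameterised for F_S).
- **Codon selection** — Nei–Gojobori synonymous/non-synonymous site
  and substitution counts and the pN/pS polymorphism-rate ratio.
- **Differentiation** — Hudson's F_ST = 1 − H_w/H_b with
  Nm = (1−F_ST)/(4F_ST), plus G_ST, H_ST, K_ST and N_ST with
  10,000-permutation significance and an N_ST > G_ST phylogeography
  test.
- **Haplotype networks** — statistical parsimony (TCS-style) with the
  95% connection limit, gaps as a fifth character state, and explicit
  intermediate nodes; TSV/DOT output.
- **Trees** — Kimura 2-parameter distances, neighbour joining with
  column-bootstrap supports, and NJ trees on pairwise F_ST distances;
  Newick output.
- **Sweep scan** — per-locus, per-population profiles across a region
  layout, cross-group π-ratios, and threshold-based sweep calls.
- **Synthetic data** — a coalescent generator (Kingman, island-model
  structure, star-genealogy partial sweeps, two-epoch group splits)
  that emulates the sweep/structure regime end to end, so the whole
  pipeline runs with no external data.

## Worked example

Build a 20-haplotype, 1139-bp alignment containing a single singleton
SNP (the configuration of the least-diverse southern-African sample in
the study) and run the diversity stage:

```python
from rp1sweep.alignio import (LocusAlignment, SequenceRecord,
                              write_fasta_alignment, write_pop_map)
base = "A" * 1139
seqs = ["G" + base[1:]] + [base] * 19
recs = [SequenceRecord(f"MOZ_h{i:03d}", "Palmeira", "southern", s)
        for i, s in enumerate(seqs)]
aln = LocusAlignment("CYP6P9a", recs)
write_fasta_alignment(aln, "demo.fasta")
write_pop_map(aln, "demo.tsv")
```

```sh
rp1sweep diversity --alignment demo.fasta --pops demo.tsv \
    --out demo_out --seed 1 --sims 1000
cat demo_out/diversity.tsv
```

prints

```text
population	2n	S	h	hd	pi	D	Dstar	FS
Palmeira	20	1	2	0.10	0.00009	-1.16	-1.54	-0.88
Overall	20	1	2	0.10	0.00009	-1.16	-1.54	-0.88
```

Reading the row: 20 phased haplotypes with one segregating site
collapse to 2 haplotypes (Hd = 0.10) and π = 9 × 10⁻⁵ per site; all
three neutrality statistics are negative — an excess of rare variants,
the footprint a selective sweep leaves — though a single singleton is
not by itself significant against the coalescent null (no stars).

A full synthetic region can be generated and scanned in one pair of
commands:

```sh
rp1sweep simulate --seed 7 --out sim/
rp1sweep sweep-scan --region-config sim/region.yaml --seed 8 --out scan/
```

which writes a per-locus table of Hd/π/D per population, the
eastern-central / southern π-ratio per locus, and a JSON sweep report
flagging the swept locus-group pairs.

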