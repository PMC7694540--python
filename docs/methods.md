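# Methods

This note documents the statistical conventions, model assumptions and
numerical choices behind rp1sweep, in the spirit of the methods
documentation of coalescent and population-genetics toolkits.

## Site filtering and counting conventions

All nucleotide statistics use **complete deletion**: an alignment
column containing a gap ("-") is tallied as an indel column, a column
containing N or any other IUPAC ambiguity code is excluded as missing,
and neither contributes to S, π, θ_W or the neutrality tests. Indels
are counted separately and are never treated as SNPs; in haplotype
*networks* (only there) the gap is retained as a fifth character
state, so a 3-bp deletion separates haplotypes by three mutational
steps.

S counts columns with ≥2 states among {A,C,G,T}. The total mutation
count η follows an infinite-sites reading: a column with *a* observed
alleles contributes *a*−1 mutations. Singletons η_s are alleles
observed exactly once (capped at *a*−1 per column, so a two-sequence
difference is one singleton, not two). Columns are 0-based half-open
internally and 1-based inclusive in reports.

Statistical phasing is out of scope: the pipeline expects phased
haplotypes. `resolve_heterozygotes` provides a documented fallback for
diploid consensus sequences — random seeded splitting of each
ambiguity code into its two bases, or masking ambiguous sites to N —
and the synthetic generator emits phased haplotypes directly.

## Diversity and neutrality statistics

- k = Σ_{i<j} d_ij / C(n,2) over valid columns (computed per column
  from allele counts); π = k / L_valid.
- Hd uses the unbiased n/(n−1) correction. With 19:1 haplotype
  frequencies at n = 20 this gives exactly 0.10, matching the DnaSP
  convention.
- Tajima's D uses the full 1989 coefficient chain
  (a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂); undefined (reported "-") when
  S = 0.
- Fu & Li's D* is the outgroup-free form with the corrected
  (erratum) coefficient set: c_n = 2(n a₁ − 2(n−1))/((n−1)(n−2)),
  d_n = c_n + (n−2)/(n−1)² + (2/(n−1))(3/2 − (2a_{n+1}−3)/(n−2) − 1/n),
  v* = [(n/(n−1))² a₂ + a₁² d_n − 2 n a₁(a₁+1)/(n−1)²]/(a₁²+a₂),
  u* = (n/(n−1))(a₁ − n/(n−1)) − v*. This set reproduces the
  reference values −1.54 (n=20, η=η_s=1) and −1.50 (n=18).
- Fu's F_S estimates θ̂ by k (per sequence, not per site), computes
  S′ = P(K ≥ h_obs | θ̂) from the Ewens sampling formula with
  unsigned Stirling numbers of the first kind (computed exactly with
  big integers, evaluated in log space; rows cached per n), and
  returns the logit of S′. S′ is clamped away from {0, 1} before the
  logit.

**Significance** is empirical from a seeded coalescent null rather
than lookup tables. For D and D* the null conditions on the observed S
(S mutations placed on a Kingman genealogy proportionally to branch
length); for F_S the null is parameterised by θ̂. D and D* are
two-tailed by the doubling convention — twice the smaller tail, each
tail estimated with the (count+1)/(n_sims+1) rule — because the null
distributions are skewed and a distance-from-the-median definition
systematically under-calls the short tail. F_S follows Fu's
convention: one-tailed (lower), with significance at the nominal 0.05
level declared when the empirical P < 0.02.

## Codon-level selection (Nei–Gojobori)

Synonymous site fractions are counted per codon from its nine
single-base neighbours under the standard genetic code. Changes
creating stop codons are excluded by renormalising within each codon
position, so every sense codon contributes exactly 3 sites and
syn + nonsyn sites always sum to the coding length — the convention
consistent with published tables where population site totals sum
exactly to the frame length while varying fractionally between
populations (site fractions are averaged across all sequences in the
sample, which is also why they are non-integer). Substitutions are
classified against the most frequent codon at each position;
multi-state and multi-hit codons are averaged over minimal mutational
pathways, discarding pathways through stop codons unless no other
exists. pN/pS is undefined (reported "-") when there is no synonymous
substitution.

## Differentiation statistics

F_ST is the sequence-based Hudson/Slatkin/Maddison estimator
1 − H_w/H_b, with H_w the unweighted mean of the two within-population
mean pairwise differences and H_b the between-population mean, per
valid site. This is the member of the F_ST family consistent with the
island-model conversion Nm = (1 − F_ST)/(4 F_ST) (F_ST = 0.0225 ↔
Nm ≈ 10.86). The haplotype-frequency statistics use the uncorrected
estimators: G_ST compares the unweighted deme mean of 1 − Σp² with the
heterozygosity of the mean allele frequencies; H_ST weights demes by
sample size against the pooled-sample heterozygosity. K_ST is
1 − K_S/K_T on mean pairwise sequence differences with sample-size
weighting of the within term; N_ST is the G_ST-style statistic
generalised by the nucleotide distance between haplotypes, so
N_ST − G_ST isolates the contribution of haplotype relatedness and its
permutation significance tests for phylogeographic structure. The
exact estimator variant behind legacy software output is not
recoverable; these choices are documented and the brute-force
definitions are what the oracles in the test suite enumerate.

Permutation tests shuffle population labels preserving sample sizes
and use the (count+1)/(n_perms+1) estimator with ties counted as
exceedances; raw p-values are reported with no multiplicity
correction.

## Statistical-parsimony networks

Haplotypes are collapsed over full-length sequences (gap = fifth
state) and joined in increasing distance order up to the 95%
connection limit j₉₅, inserting unobserved intermediates so that every
edge is one mutational step. Ties are broken by higher joint frequency
then lexicographic id; links that would close a cycle are dropped by
default (a spanning forest; an option retains equal-length alternative
links for display). The connection limit models per-site change counts
as Poisson with mean λ̂ = −ln(1 − j/L) and declares a j-step
connection parsimonious when every differing site changed exactly
once: P_j = [λ̂e^{−λ̂}/(1−e^{−λ̂})]^j, with j₉₅ the largest j with
P_j ≥ 0.95. P_j is non-increasing in j, one step is always
connectable at realistic L, and j₉₅(633 bp) = 8. For very short toy
sequences (L below ~30 bp) the limit is legitimately 0.

## Distances and trees

K2 distances use d = −½ln(1−2P−Q) − ¼ln(1−2Q) over jointly
unambiguous sites, raising a saturation error when a log argument is
non-positive. Neighbour joining is the Saitou–Nei agglomeration with
two deterministic conventions: pair-selection ties break
lexicographically on cluster names (the smallest leaf label inside a
cluster), and negative branch-length estimates are clamped to zero
with the deficit transferred to the sister branch. Bootstrap resamples
alignment columns (not codons) and reports the percentage of replicate
trees containing each internal bipartition; replicates whose resampled
distances saturate are skipped. F_ST trees floor negative estimates at
zero. Maximum-likelihood inference and substitution-model selection
are deliberately out of scope — the NJ/K2 pathway is the tree surface,
and HKY+G is noted as unimplemented.

## Synthetic-data generator

The generator emulates the study regime rather than any particular
dataset: seven populations in two regional groups (four
southern-African populations carrying the sweep; Uganda, DR Congo and
Cameroon as the eastern/central comparison), six loci at offsets
−34, −9, 0, +29, +61 and +86 kb with the study's fragment lengths
(626–1139 bp), near-panmixia within groups and strong divergence
between them.

Model components, time in units of 2N generations:

- **Neutral backbone**: Kingman coalescent; mutations Poisson with
  rate θ/2 per unit branch length (E[k] = θ at n = 2 and
  E[S] = θ·a₁, which the calibration tests verify); infinite sites,
  positions drawn uniformly without replacement on L, with a
  finite-sites fallback (sampling with replacement) only when
  mutations outnumber sites.
- **Sweeps**: the star-genealogy approximation — round(f·n) lineages
  coalesce at a very recent ancestor before neutral coalescence of
  the remainder. This is deliberately not a forward hitchhiking
  simulation: it reproduces the low-π/low-Hd/negative-D/dominant-
  haplotype signature the pipeline must detect at desk scale, but not
  recombination-mediated partial linkage or the exact frequency
  spectrum of a parameterised selection coefficient. Sweep strength
  decays with distance from the focal locus as
  f(d) = f₀·e^{−d/λ}, defaults f₀ = 0.95 and λ = 75 kb (so
  f(86 kb) ≈ 0.30), spanning the near-fixed sweep at the focal locus
  and the weak residual signal at the region edge.
- **Structure**: symmetric island model (per-lineage migration rate
  M/2), default M = 10 per group, putting within-group F_ST near
  0.02. Between groups there is no migration; surviving lineages
  merge into a single ancestral population t_split = 4 units back, a
  two-epoch split that lands between-group F_ST in the 0.5–0.97
  regime robustly (a calibrated low-M regime would be far noisier at
  these sample sizes). With M = 0 inside `island_genealogy` the demes
  can never share ancestry, so stranded deme ancestors are merged
  after an explicit 8-unit isolation epoch.
- Defaults of n = 20 haplotypes per population and θ = 3 per locus
  mirror a ~10-diploid-per-population amplicon survey with
  central-African-like diversity (π of order 10⁻³ over ~1 kb).

Everything is driven by one numpy Generator, so identical seeds give
byte-identical FASTA output. What passing the simulation-based tests
shows is that the pipeline detects the modelled sweep/structure
signal at these sample sizes; it does not validate behaviour under
recombination within loci, sequencing error, or unphased input.

## Sweep calls and π-ratios

The region scan computes Hd/π/D per (locus, population) and the
per-locus ratio of group mean π (comparison over reference). The
default ratio is the unweighted mean of per-population π within each
group — the simplest reading of "relative diversity between regions";
a pooled-alignment mode (concatenating each group's populations before
computing π) is available because the two definitions differ whenever
sample sizes or between-population divergence differ. A locus-group
pair is called "swept" when group mean π and Hd fall below configured
fractions of the reference group's means (defaults 0.25 and 0.5) and
mean Tajima's D is negative-significant (empirical p ≤ 0.05 when
available, else D ≤ −1.0); a monomorphic group is flagged outright.
The thresholds are configuration, not science: the underlying study
makes sweep calls qualitatively, and the defaults are calibrated only
in the sense that the test suite checks they flag a f₀ = 0.95 sweep
and stay quiet on neutral data.

## Problem sizes in the shipped tests

Distributional checks run at desk scale chosen for statistical
sufficiency: 2000 replicates for the neutral D/D*/F_S calibration
(standard-error bounds), 5000 for the E[S] and E[k] closed-form
checks, 500 per point for sweep-monotonicity and migration-rate
monotonicity grids, and 20 seeded six-locus datasets at n = 20 per
population for π-ratio peak recovery.

## Known limitations

- No recombination within loci, either in the statistics (F_S and the
  network assume non-recombining fragments) or in the generator.
- The GST/HST estimator variants of legacy software are approximated,
  not reverse-engineered; permutation p-values near thresholds may
  disagree with beta-approximation-based significance stars.
- The TCS connection-limit probability is a documented Poisson
  single-hit model, not a byte-level reimplementation of the original
  program's recursion.
- pN/pS uses raw polymorphism proportions; no Jukes–Cantor multiple-
  hit correction and no codon-model inference.
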