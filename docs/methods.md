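# Methods

## Data model

An InDel marker is a PCR assay of an insertion/deletion polymorphism: each
accession shows the A band, the B band, both (heterozygote — the markers are
co-dominant) or no product (missing). The pipeline's central input is the
N × L call grid; all distance-based stages operate on its binary
allele-presence expansion, two columns per locus:

| call     | (A column, B column) |
|----------|----------------------|
| hom A    | (1, 0)               |
| hom B    | (0, 1)               |
| het AB   | (1, 1)               |
| missing  | (NaN, NaN)           |

Heterozygotes encode as (1,1) because presence is scored per allele; this
shrinks their Ochiai distance to both homozygote classes and is the standard
binary scoring for co-dominant bands. Missing calls propagate as missing —
scoring them 0 would conflate "band absent" (information) with "no call"
(no information) and bias every downstream distance.

## Allele frequencies

p = allele count / 2N with the denominator fixed at **all** accessions, so at
a locus with missing calls the declared frequencies sum to less than 1; the
deficit is reported as a residual class. Sampling variance is p(1−p)/N. Both
conventions were chosen because they reproduce the reference panel's
published per-locus values from its published genotype-class counts (the
per-scored-chromosome denominator is available behind `scored_only=True`).
At the six loci with heterozygotes the published Var/SD values are not
self-consistent under any single convention (one locus's row duplicates
another's); the package applies p(1−p)/N uniformly.

## Diversity statistics

Over allele-class frequencies pᵢ at a locus:

* gene diversity (expected heterozygosity) D = 1 − Σ pᵢ²;
* PIC = 1 − Σ pᵢ² − Σᵢ<ⱼ 2 pᵢ² pⱼ² (Botstein's correction for uninformative
  matings), so PIC ≤ D always;
* observed heterozygosity H_obs = heterozygous accessions / N.

**Residual-class rule.** When declared frequencies sum to < 1 (beyond a 1e-6
float-noise tolerance) the deficit forms a third class entering D and PIC and
raising the allele-class count A to 3. This is how binary-scored data behave
in the standard marker software and is the unique convention under which the
reference panel's published D/PIC are reproducible from its published
frequencies (e.g. a locus at p = 0.2990/0.6275 gives D = 0.5115 with the
residual class, 0.5168 without; the published value is 0.5115).

The heterozygosity column is *observed* heterozygosity even though such
tables are often headed "expected": the reference panel's per-locus values
equal het-count/N exactly (e.g. 50/204 = 0.2451) and its mean 0.0193 is
described as observed.

Informativeness labels: high (D ≥ 0.5 and PIC ≥ 0.4), low (D ≤ 0.3 and
PIC ≤ 0.2), else moderate.

## Phenotype statistics

Descriptives use the bias-adjusted G1/G2 skewness/kurtosis estimators; CV is
reported as a proportion (sd/mean). Pearson correlations carry two-sided
t-test p-values (t = r√((n−2)/(1−r²))) with pairwise deletion of missing
values and star labels at p ≤ 0.05 / p ≤ 0.01. PCA and the UPGMA trait
clustering both operate on z-standardized traits — the traits mix mm and g,
and TGW's variance (≈8 g²) would otherwise dominate the geometry entirely;
per-cluster means are reported on the raw scale.

## Distances and trees

Otsuka–Ochiai dissimilarity d = 1 − a/√((a+b)(a+c)) — the cosine distance of
presence profiles — with pairwise deletion over columns missing in either
accession; a pair with no shared scoreable presence gets the maximal d = 1
(logged). UPGMA trees come from average-linkage agglomeration with node
height = half the merge distance (so cophenetic distances reproduce an
ultrametric input exactly). Neighbor joining is the Saitou–Nei algorithm,
exact on additive inputs; negative limb lengths are clamped to zero with the
deficit moved to the sibling edge, leaving the topology unchanged.

Bootstrap support resamples **marker loci**, not binary columns: a locus's
two allele columns are one statistical observation and move together.
Support is the percentage of replicate trees containing each non-trivial
bipartition of the point-estimate tree. Replicate b of a run seeded s draws
from the stream seeded (s, b), so raising the replicate count never
reshuffles earlier replicates.

## PCoA

Gower double-centering of −½d², eigendecomposition, coordinates scaled by
√eigenvalue. The Ochiai matrix is generally non-Euclidean, so negative
eigenvalues occur; they carry no coordinates and are excluded from the
percent-explained denominator (their total magnitude is reported
separately).

## AMOVA / Φ_PT

Single-level variance partition on squared-Euclidean distances between
binary profiles (the convention of binary/dominant-marker software):
SS_total = Σᵢ<ⱼ d²ᵢⱼ/N, SS_within analogous per group, V_within = MS_within,
V_among = (MS_among − V_within)/n₀ with the standard unequal-size n₀, and
Φ_PT = V_among/(V_among + V_within). The reported V_among and Φ_PT are
clamped at 0, but the permutation test compares the **unclamped** statistic —
comparing clamped values makes null p-values pile up at 1. p uses the
add-one correction: (hits + 1)/(B + 1). Missing binary cells are mean-imputed
per column within group before distances (AMOVA needs complete pairwise
distances); the imputation is optional but on by default.

Grain-type subpopulations are GL bins: short < 7.5 mm ≤ medium < 8.5 mm ≤
long ≤ 9.5 mm < extra-long (ties at 7.5 → medium, at 9.5 → long, per the
quoted bin definitions). Groups with a single member cannot enter a variance
partition; the pipeline drops them with a warning while the core `amova`
function treats them as an error.

## Association and pyramiding

Per locus and trait, accessions are grouped by allele class (A- and
B-homozygotes; the heterozygote class enters as a third group only when it
has ≥ `min_group_n` = 20 members, otherwise it is excluded rather than merged
— merging would contaminate a homozygote class). One-way fixed-effects ANOVA
gives F and p; Duncan's multiple range test assigns letters using
studentized-range quantiles at protection levels α_p = 1 − (1−α)^(p−1) with
the harmonic-mean (Kramer) sample size, via the standard stepwise procedure
(a span whose extremes are within its critical range is homogeneous, and its
sub-spans are never tested).

**Favorable-allele rule.** A *major* allele class has ≥ 20 carriers (the
carrier-count threshold was preferred over the alternative "frequency ≥ 0.2"
phrasing, which would imply ≈41 carriers and contradicts the published
membership). A major class is *favorable* for a trait when (i) its marker's
ANOVA p ≤ 0.05 for that trait, (ii) its group mean beats the breeding
threshold (GL > 8.0 mm), and (iii) it holds the top Duncan letter. The
significance condition is what keeps high-mean groups at non-associated
markers out of the favorable set. The non-favorable comparison set contains
the remaining major groups at the markers that contributed a favorable
allele — including, where present, the heterozygote group, which two-allele
report layouts omit as a row but which belongs in the cumulative mean; with
the reference panel's published group means this reproduces the published
cumulative non-favorable GL mean (7.62) exactly. Cumulative FA / N-FA values
are unweighted means ± SD of member group means, compared by Welch's t-test.
Raw p-values are reported (the design runs 14 × 4 tests uncorrected, as such
studies conventionally do); a Benjamini–Hochberg column can be added by the
caller from the association table.

## Synthetic panel generator

The generator emulates the motivating 204-accession rice panel, the study
condition for every stochastic test:

* **Genotypes** are drawn per locus as genotype *classes* (hom-A, hom-B, het,
  missing) with default probabilities equal to the published class counts /
  204 — not via Hardy–Weinberg pairing, because the panel is a collection of
  mostly-inbred uniform lines whose heterozygosity is a panel property (near
  zero everywhere except one locus at ≈0.245), not a function of allele
  frequency. Loci are drawn independently (no linkage disequilibrium).
* **Structure**: four grain-type subpopulations of sizes 55/78/48/23
  (short/medium/long/extra-long). Within subpopulation g the hom-B
  probability is shifted by divergence·ladder_g·sign(GL effect), with the
  base ladder (−1.5, −0.5, +0.5, +1.5) centered to size-weighted mean zero so
  panel-wide frequencies stay at their published values (clipping at extreme
  loci can still move them; the truth record stores the exact post-clipping
  mixture frequencies). Default divergence 0.16 was chosen once so the
  pairwise Φ_PT ladder spans roughly the published 0.03–0.45 range, with the
  short vs extra-long pair maximal.
* **Traits**: additive allele effects (hom-B = the published group contrast,
  het = midpoint, missing = expected dose) plus correlated Gaussian
  residuals. Effects are planted at **one causal marker per gene** (the
  markers of one gene assay the same variant; planting the contrast at each
  would double-count genetic variance) and only for traits with published
  p ≤ 0.05. The residual covariance is the target covariance (published
  trait SDs and correlation signs) minus the analytic genetic covariance
  Σ_l Var(g_l)·e_l e_lᵀ computed under the exact subpopulation mixture,
  projected to positive definite — so simulated marginal moments and
  correlations match the published ones rather than stacking on top of them.
* **Determinism**: one integer seed; draws occur in a fixed locus-by-
  subpopulation order; the truth record (labels, per-subpopulation class
  probabilities, mixture frequencies, effects, intercepts, residual
  covariance) suffices to recompute every planted quantity.

What the generator does **not** emulate: linkage disequilibrium between loci
of different genes, the non-additive heterozygote behavior seen at the GS7
locus (its observed het mean sits below both homozygote means; the additive
model puts it at the midpoint), genotyping error correlated across loci, and
any pedigree structure. Tests passing on synthetic panels therefore
demonstrate correctness of the estimators and calibration of the tests under
the stated model, not robustness to those real-data features.

## Numerical choices

* Residual-class tolerance 1e-6 separates true frequency deficits from float
  noise; Σp > 1 + 1e-9 is an error.
* Ochiai matrices are symmetrized ((d + dᵀ)/2) and clipped to [0, 1] to
  remove accumulation noise; undefined pairs → d = 1, counted and warned.
* Eigenvalues below 1e-10 are treated as zero in PCoA.
* Duncan critical values are cached per (α, p, df) — the studentized-range
  ppf is expensive.
* Permutation p-values use the add-one correction and a 1e-12 slack in the
  ≥ comparison to absorb float ties.
* Problem sizes in tests (replicate counts for calibration, bootstrap and
  permutation counts) are scaled to keep the suite fast while leaving the
  binomial/KS bands discriminating; the defaults in the CLI (B = 100
  bootstraps, 999 permutations) are practical analysis settings, and both are
  plain parameters for users who want the 10,000-replicate settings of the
  original workflow.

## Known limitations

* Strictly biallelic loci (plus the heterozygote and residual classes);
  panels with > 2 declared alleles per marker are out of scope.
* Single-level AMOVA only (no region/population/individual hierarchy), and
  Φ_PT rather than allele-frequency F_ST estimators.
* No mixed-model (Q+K) association correction for population structure; the
  one-way ANOVA is the intended, simple design of this analysis class, and
  structured panels will show inflated associations at structured loci.
* The phenotype clustering reports a cut at user-chosen k; no automatic
  cluster-number selection.
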