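# Methods

This note records the models behind each stage, the defaults and why
they were chosen, what the synthetic panel does and does not emulate,
and the numerical conventions a user auditing results will want.

## Genotypes and filters

Genotypes are additive alt-allele dosages (0/1/2, `-1` missing) with a
1-based variant table; VCF is the interchange format (biallelic diploid
GT only; multiallelic records are skipped with a warning, not split).
Variant filters are strict inequalities — MAF **>** 0.05 and missing
fraction **<** 0.20 by default — matching the usual wording of
panel-filter descriptions; both knobs are exposed because published
pipelines are often ambiguous between a 10% and a 20% missingness cut.
Filtering is idempotent and order-preserving.

## The synthetic panel

The generator exists so that every downstream stage has ground truth.
It emulates a worldwide selfing-crop diversity panel:

* **Structure** — `n_subpops` (10) subpopulations with Balding–Nichols
  allele-frequency divergence `subpop_divergence` (F = 0.08, the
  magnitude typical of regional crop germplasm groups).
* **LD** — independent blocks of `ld_block_size_bp` (2 Mb); within a
  block every haplotype copies a founder allele and flips it with a
  probability tuned per SNP so the expected pairwise dosage r² equals
  `within_block_r2` (0.8 by default: local LD in a selfing crop with
  megabase-scale decay is strong).  The tuning solves
  `(1-2ε)·sqrt(p(1-p)/(q(1-q))) = ρ^{1/4}` by fixed point, so the
  calibration holds across founder frequencies (measured: mean
  within-block r² 0.796 for a target of 0.8; between-block r² 0.005).
  Blocks are exchangeable — r² does not decay *within* a block, so
  decay curves from this generator are step-like rather than smooth.
* **Phenotypes** — 12 component traits on the log scale (positivity is
  required by the ratio traits), exponentiated, with counts rounded.
  Per replicate observation, log-variance components (defaults):
  shared accession-level size factor 0.04 (an i.i.d. stable "vigor"
  effect: it is shared across the weight/count traits and cancels in
  ratios, but is deliberately not tracked by genome-wide kinship —
  see below), per-trait polygenic background 0.005 (a sum of ~300
  small SNP effects, so kinship-based mixed models absorb it as they
  do real polygenic variance), per-subpopulation trait effect 0.005
  (the geography-correlated variance worldwide panels show), year
  0.005, genotype x year 0.01, residual 0.08.  These give a
  single-spike CV near 28%, entry-mean H² ≈ 0.8 for direct traits and
  visibly lower H² for ratio traits — the pattern real spike-morphology
  trials report.  QTL effects are sized so one QTL explains `qtl_h2`
  of the single-observation variance of each trait it touches; QTL LD
  blocks are excluded from the polygenic-background SNP pool (with only
  ~50 blocks genome-wide a random background would otherwise park ~2%
  of its variance on the causal block and contaminate effect-size
  truth — a desk-scale artifact that a 40M-SNP panel does not have).
* **Why the size factor is i.i.d.** If the shared factor were itself
  polygenic, the mixed model would absorb it for component traits and
  erase most of the ratio traits' power advantage; modeled as a stable
  accession effect (seed quality, plot micro-environment), it is
  irreducible noise for component-trait scans yet cancels exactly in
  log-ratios.  This is the mechanism that makes assimilate-partitioning
  ratios expose antagonistic loci, and the generator encodes it
  explicitly.
* **Not emulated** — hexaploid subgenome homoeology, imputation error,
  realistic demography or selection, within-block LD decay, trait
  covariance beyond the single shared factor.  Passing tests therefore
  demonstrate correctness of the machinery and the qualitative
  mechanisms, not field-data effect sizes.

A separate linear-scale two-way generator
(`simulate_anova_observations`) produces plain `μ + g + y + gy + e`
trials for variance-component recovery checks, where exponentiation
would distort the generating components.

## Trait dissection

All 15 ratios are computed per (accession, year, replicate) **before**
any averaging — ratio-of-means and mean-of-ratios differ, and the
per-replicate order is asserted by test.  Records with nonpositive or
missing denominators are dropped and counted, never imputed.

## Variance components, H², BLUEs, LSD

Variance components come from expected mean squares of the two-way
ANOVA (`var_e = MS_error`, `var_GxE = (MS_GxY − MS_error)/r`,
`var_G = (MS_G − MS_GxY)/(r·y)`), negatives clamped to zero with a
flag; this closed form matches the classical ANOVA framing, is exactly
testable, and on 500 genotypes x 2 years x 5 reps recovers generating
components within a few percent.  F tests use MS_GxY as denominator
for genotype and year.  Near-balanced designs use the mean cell count
for r.

H² is on an entry-mean basis with year and replicate divisors
generalizing the two-year printed form.  It is computed from
replicate-level components; a repeatability-style alternative (from
BLUE-level residuals) would give smaller denominators — the pipeline
reports the component-based value.

BLUEs treat genotype as fixed with year and genotype x year random.
A literal "all effects random" reading would yield BLUPs (shrunken
genotype means), under which the estimates are no longer *unbiased*
genotype values; genotype-fixed is therefore the implemented
definition.  Balanced complete designs short-circuit to the exact
closed form (the raw genotype mean); unbalanced designs use direct
covariance-matrix REML (Nelder–Mead on log variance ratios), verified
against lme4 and against explicit GLS normal equations.  This path is
O(n³) in observations and intended for the panel sizes it meets here
(≤ a few thousand records per trait).

LSD uses the pooled one-way ANOVA MSE and t critical value; letters
come from maximal runs of mutually non-significant groups after
sorting by mean (ties in the display can in principle miss a
non-contiguous non-significant pair under severe imbalance; the
significant-pairs-never-share-a-letter direction always holds).

## Kinship, PCA, LD, Tajima's D

Kinship is the simple matching coefficient: the fraction of loci with
identical genotype *category* (0/1/2), missing excluded pairwise; it is
symmetric with unit diagonal, and is floored-eigenvalue bent
(`eigenvalues >= 1e-6`) before mixed-model use because pairwise
missing-data exclusion can leave it slightly indefinite.

PCA LD-prunes first, mean-imputes, centers by 2p and scales by
`sqrt(2p(1−p))`; scores come from the SVD, and variance fractions are
relative to the total of the standardized matrix.

r² is the squared Pearson correlation of unphased dosages over jointly
called accessions (the genotypic r² Plink and PopLDdecay report), never
a haplotype-EM D′.  LD decay bins all intra-chromosomal pairs by
distance; two decay summaries are reported because the field uses
both: the half-maximum distance (first bin at or below half the
maximum bin mean, no interpolation; if the curve is flat the decay is
complete within the first bin) and the interpolated distance at
r² = 0.50.

Tajima's D uses allele counts from diploid genotypes, n = 2 x
accessions chromosomes (the VCFtools convention for unphased GT), the
standard a₁…e₂ constants, and per-site chromosome counts for π under
missingness.  Verified against an independently coded oracle to 1e-9
and centered (|mean| < 0.3) on neutral-SFS simulations.

## Mixed-model scan

The null model is fitted by REML over the variance ratio
λ = σ²_g/σ²_e via the eigendecomposition of K, Brent-searched on
log λ ∈ [−10, 10] with the boundary checked explicitly.  The approx
(P3D/EMMAX) scan fixes λ and tests each SNP by GLS in the rotated,
whitened space; the Wald statistic is the t ratio β̂/se with
df = n − covariates − 1, so with K = I it reduces *exactly* to OLS
(asserted at 1e-8).  Exact mode re-optimizes λ per SNP.  Missing
dosages are mean-imputed inside the test only.  P-values are floored
at the smallest positive double.

**LOCO kinship.**  At desk scale (thousands of SNPs, dense LD blocks)
a tested SNP's own block is a non-negligible eigen-direction of the
all-SNP kinship, and the mixed model shrinks away most of a true
signal (proximal contamination; measured: −log10 p 3.4 with all-SNP K
versus 10.9 with leave-one-chromosome-out K on the same data).  At
tens of millions of markers the block's share of K is ~1e-4 and the
effect vanishes, which is why single-K software is fine there.  The
pipeline therefore scans each chromosome against a kinship built from
the other chromosomes (`loco=True`, the standard LOCO practice); the
all-SNP kinship remains available (`loco=False`) and is what the
kinship output stage writes.

**Thresholds.**  Bonferroni is α/n with n from a Plink-style sliding
window prune (50 kb window, step 5, r² > 0.2 removes the
later-positioned SNP; after the stepped passes converge, full-anchor
sweeps run until no surviving pair within a window exceeds the limit —
stepped anchors alone cannot guarantee that invariant).  The
permutation threshold shuffles phenotypes across accessions (S and K
fixed, preserving the structure correction — shuffling genotypes would
destroy K), records each permutation's genome-wide minimum p, and
returns the 0.05 empirical quantile of those minima; for m independent
tests this sits near −ln(0.95)/m, i.e. about 0.05/m, well below the
per-test α.  The working threshold for peak calling defaults to
−log10 p = 5.00.

## Peaks, candidate genes, haplotypes

Intervals are connected components of the r² > 0.1 graph over the
significant SNPs of one trait (LD computed among significant SNPs
only); bounds are member min/max positions; the lead SNP is the most
significant member with position as the tie-break.  Adjacent intervals
merge while their lead SNPs are strictly closer than 5 Mb, re-deriving
the lead after each merge until stable; `is_peak` requires strictly
more than 10 member SNPs.  Cross-trait regions collapse any base-pair
overlap between per-trait peaks and flag regions supported only by
ratio traits.  Delineation happens per trait with overlap afterwards
(one consistent reading of interval-then-merge descriptions that mix
traits).

Candidate genes intersect ±500 kb (inclusive) around the lead SNP;
distance is zero if the lead falls inside the gene span, else base
pairs to the nearest edge; the expression screen passes a gene with
FPKM ≥ 1.0 (a conventional "expressed" floor; "high expression" is
qualitative, so the threshold is a parameter) in any of the six spike
developmental stages; ranking is passes-expression first, then
distance.

Haplotypes are exact dosage strings over the region's polymorphic
SNPs — genotype combinations, not phased haplotypes, appropriate for a
crop with minimal heterozygosity.  Groups with frequency ≥ 0.05 become
Hap-1, Hap-2, … by descending count (string order breaks ties for
determinism); accessions with missing calls join a major haplotype
only when they match exactly one at every called site, else "minor".
Effects are reported per trait as group means, percent difference
versus a reference haplotype together with the absolute difference,
and LSD letters (haplotypes with < 3 carriers are tabulated but not
tested).  Frequency tables group by region or by release period
(everything to 1970, then 10-year bins to 2020).

## Pipeline and reproducibility

Every stage writes plain TSV/JSON/VCF into the run directory, the
manifest records config hash, seed and per-stage row counts, and all
randomness flows from the single config seed through named CRC-derived
substreams, so a rerun is byte-identical.  Stage failures abort with
the stage name; earlier outputs are retained.

## Problem sizes

Tests and the acceptance script use panels of 80–306 accessions and
300–5,000 SNPs, 10–100 simulation seeds per stochastic claim — sizes
at which every mechanism (calibration, power, recovery) is measurable
on one CPU in minutes while keeping per-claim Monte-Carlo error well
inside the asserted margins.

## Known limitations

* Simple-matching kinship is not the centered GRM; λ estimates are not
  comparable across kinship conventions.
* The balanced-design BLUE short-circuit assumes completeness; heavy
  unbalance falls back to O(n³) REML.
* The permutation description in the literature this models is
  ambiguous ("0.05 quantile of ranked P-values"); the minimum-p
  quantile convention is implemented and documented rather than
  resolved.
* Compact letter displays can, under severe group-size imbalance,
  fail to letter a non-contiguous non-significant pair.
* The generator's step-block LD cannot produce smooth decay curves;
  decay-distance summaries on synthetic data reflect block geometry.
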