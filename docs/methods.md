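# Methods

## Genome model and meiosis

The simulated genome is a linkage map discretised into fixed-width genetic
bins (default 0.1 cM, half-open intervals `[lo, hi)` tiling each
chromosome).  A simulated haplotype is an array of founder-haplotype
indices over bins (ancestry tracking): marker alleles are looked up from
the founder haplotype recorded in the marker's bin, so two markers in the
same bin co-segregate exactly and no allele can appear that is absent from
both parents (no mutation).

Meiosis per chromosome: the crossover count is Poisson with rate λ equal
to the chromosome's genetic length in Morgans; positions are i.i.d.
uniform along the chromosome (no interference); the starting haplotype is
Bernoulli(1/2).  Crossovers act at bin resolution — each position is
rounded to the nearest bin boundary and the ancestry source switches
there.  These assumptions imply the Haldane map function
r = (1 − e^(−2d))/2, which the test suite verifies empirically
(3-standard-error bands at 2 × 10⁴ gametes), along with Poisson
equidispersion of crossover counts and independent assortment across
chromosomes.  None of the three assumptions (no interference, no
mutation, no sex difference in recombination) is configurable; they define
the model.

Inbred lines are derived by self-fertilisation with single-seed descent
(one offspring carried forward per generation, default 6 generations),
the standard procedure for a selfing crop.  Under this scheme the
expected fraction of initially heterozygous loci still heterozygous after
g generations is (1/2)^g ≈ 0.0156 at g = 6, also verified by simulation.

## Coordinate projection

Physical positions are projected to the genetic scale by local polynomial
regression on an anchor table of (bp, cM) pairs: degree 2, tricube
weights, with the span parameter (fraction of anchors in each local
window) defaulting to 0.189.  Chromosomes with fewer than 10 anchors are
rejected.  Because a smoothed fit can locally invert marker order, the
projected positions are repaired: any successive gap below 10⁻⁶ cM
(including all non-positive gaps) is set to 10⁻⁶ cM and positions
re-accumulated cumulatively, so downstream positions shift by the
accumulated corrections.  The alternative — inserting the floor gap
locally without shifting downstream positions — would preserve absolute
positions but can require iterating; cumulative re-accumulation is
single-pass and order-preserving.  Marker→bin assignment is by nearest
bin midpoint, ties to the lower-index bin (deterministic).

## Prediction models

All models regress a single trait on all markers (dosage coding 0/1/2,
per-marker mean imputation of missing values after QC).  No fixed-effect
covariates are used in prediction models.

* **RR (RR-BLUP/GBLUP).**  y = 1μ + Zβ + e with β ~ N(0, σ²β I).
  Variance components are estimated by REML on the equivalent kinship
  model (VanRaden G = ZZ′/c, c = 2Σp(1−p)) using one eigendecomposition
  of G and bounded 1-D optimisation of the profiled restricted likelihood
  over log(σ²e/σ²g).  Marker effects are recovered in the dual form
  β = Z′V⁻¹(y − μ̂)σ²g/c; the tests verify β against dense-inverse
  closed-form arithmetic and the GEBV identity with the kinship-model
  BLUPs.  The frequency centring is folded into the stored intercept so
  prediction is literally μ + Xβ.
* **BL / EBL / Bayes C.**  Single-site Gibbs samplers with conjugate
  updates (numba-compiled; the seed fixes the whole chain, so fits are
  bit-reproducible).  BL uses the normal–exponential scale mixture of the
  double-exponential prior with a common Gamma-updated rate λ².  EBL adds
  marker-specific rate multipliers η²ⱼ ~ Gamma(ψ, θ); the default rate
  θ = 10⁻⁴ makes the per-marker shrinkage nearly free, which is what
  turns the fit into a sparse association scan.  Bayes C uses a
  spike-and-slab prior with common slab variance (scaled-inverse-χ²
  updated) and inclusion probability π, Beta-updated unless fixed;
  posterior-mean inclusion probabilities are returned per marker.
  Defaults: 1500 iterations, 500 burn-in; effect estimates are
  post-burn-in means.  Hyperprior defaults beyond θ follow the methods'
  original formulations and are all surfaced in `ShrinkageConfig`.
* **RKHS.**  Kernel mixed model with Gaussian kernel
  K(x, x′) = exp(−‖x − x′‖²/(h·m)); bandwidth h defaults to the median
  pairwise squared distance divided by m (median heuristic).  Fitted with
  the same spectral REML; prediction uses the kernel against the training
  genotypes.

Additional model kinds can be registered through the same
`fit_model`/`MarkerEffectModel` interface without changes elsewhere
(weighted shrinkage variants and random-forest regression are deliberately
out of scope here).

**Accuracy** is the Pearson correlation between observed phenotypes and
leave-one-out cross-validated GEBVs (n folds, each fold refits the model
from scratch; Gibbs folds get distinct derived seeds).  Two behaviours are
worth knowing about.  First, accuracy increases with trait heritability
and is bounded by √h² in expectation; the tests check the monotone trend
and the bound loosely.  Second, for a trait with *no* genetic signal a
model that estimates zero genetic variance predicts each held-out
individual with the training-fold mean, and the Pearson correlation of
leave-one-out fold means with the held-out values is strongly negative by
construction (the classic LOOCV anti-correlation artefact) even though
the predictions are nearly constant.  The sampler-fitted models, whose
held-out predictions retain posterior variance, give the intuitive ≈ 0
accuracy under permutation nulls; the permutation tests therefore use
those.  Interpret strongly negative LOOCV accuracies as "no usable
signal", not as true anti-prediction.

## GWAS

The mixed-linear-model scan tests each marker in
y = PCs·α + xⱼβⱼ + u + e with u ~ N(0, σ²g·K), K the VanRaden kinship and
6 leading dosage principal components as fixed covariates (defaults).
Variance components are estimated once on the null model and reused for
every marker (the P3D/EMMAX approximation); Wald t statistics use the
fixed covariance.  `exact=True` re-estimates the components per marker.
With identity kinship and no PCs the exact mode reproduces the OLS
t-test; the default mode matches the slopes exactly but its p-values for
true-effect markers are conservative because the null-model residual
variance includes the marker's own contribution.  Markers with zero
dosage variance are skipped (missing p).  Multiplicity is controlled by
Benjamini–Hochberg FDR at 5%; the realised p-value cutoff is reported.
Null calibration (type-I error at nominal 0.05 within the binomial band
over 2000 structured-population markers) is part of the test suite.

The EBL scan is the same code path as the EBL prediction fit.  Because
the posterior-mean effect profile has no natural significance threshold,
associations are *called* where |effect| exceeds k standard deviations of
all marker effects (default k = 5, configurable, reported alongside the
effects).  This call rule is a package policy, and it is imperfect by
nature: under a pure-noise trait the adaptive-lasso effect profile is
heavy-tailed, so a small false-call rate (on the order of a percent of
markers) persists for any practical k.  Treat the called set as a
shortlist for inspection against the effect plot, not as an
error-controlled discovery set — the FDR-controlled MLM scan is the
inferential tool.

The marker-assisted-selection assessment regresses the trait on the
FDR-significant markers by OLS with bidirectional stepwise selection
minimising AIC (started from the full candidate model; exactly collinear
candidates are dropped first; a single candidate skips selection),
reporting the selected-marker count and model r².  On polygenic simulated
traits the scan typically finds no significant markers at all while
whole-genome prediction retains substantial accuracy — the qualitative
contrast that motivates GS over marker-assisted selection.

## Heritability

Broad-sense heritability uses the one-way ANOVA with individual as the
factor on per-year observations (one plant per individual per year):
σ²E = MS_within, σ²G = (MS_between − MS_within)/n₀ with n₀ the effective
replicate count (equal to the year count when balanced), negative σ²G
truncated to zero, h² = σ²G/(σ²G + σ²E) and 0/0 defined as 0.  With
n = 200 individuals and 4 years the estimator recovers generating values
across h² ∈ {0.1, 0.5, 0.9} within ±0.05 (mean over seeds).

## LD

r² is the squared Pearson correlation of allele indicators across the 2n
phased haplotypes (no EM phase inference — both real post-phasing data
and simulated data are phased; this convention is fixed).  Monomorphic
markers yield a missing value.  The finite-sample expectation of r²
between independent markers is ≈ 1/(2n), which the tests use as a
sampling-bias oracle.

## Breeding scheme

Selection ranks candidates by GEBV per target trait, descending, ties
broken by candidate index.  If an individual makes the top list of both
traits it stays with the trait where it ranks better (ties to the first
trait) and the other trait takes its next-ranked candidate, repeated to a
fixpoint — this preserves the stated parent counts (4 in the first cycle,
8 after).  The crossing ring alternates the two trait groups
(TFW₁, SSC₁, TFW₂, SSC₂, …) so that every cross pairs a high scorer of
one target with a high scorer of the other, which is the only ring
ordering consistent with the scheme's purpose of combining the traits;
this ordering is a package policy.  k parents give k crosses of N/k
progeny (N must be divisible by k; k = 2 degenerates to one cross of N).
Founders compete only in the first cycle; later cycles select among the
previous generation's progeny.  Models are trained once on the founders
and never retrained on simulated progeny.  Replicates run on independent
substreams spawned from the master seed, so runs are reproducible and
replicates independent.  Cross direction is immaterial (the model has no
cytoplasmic inheritance).  A random-parent mode provides the negative
control: with selection disabled, generation-mean GEBVs drift with no
systematic trend.

## Synthetic data

Founder panels are ancestral mosaics: each founder haplotype copies
segments from a small pool of ancestral haplotypes (default 8) with
exponentially distributed segment lengths at the LD scale (default
20 cM), producing LD that decays over tens of cM.  This is an emulation
chosen for cheapness and seedability, not a model of any crop's history;
in particular it does not reproduce realistic allele-frequency spectra,
population structure gradients, or pericentromeric recombination
suppression beyond the monotone nonlinear bp↔cM warp used to exercise the
projection tooling.  Ancestral minor alleles are placed on 2–6 of the 8
ancestors so that the founder MAF spectrum clears the QC thresholds for
the large majority of markers.  Passing tests on these panels show the
algorithms behave correctly under long-range LD; they do not certify
performance on any particular real panel.

Traits are additive: one pleiotropic QTL set (default 50 QTLs) with
per-QTL effect vectors drawn from N(0, C) across traits, C the target
genetic correlation matrix; the drawn effect matrix is decorrelated and
recoloured so its sample correlation equals C exactly, leaving only
LD-induced distortion in the realised breeding-value correlations.  The
default architecture has 20 traits with heritabilities spanning 0.10–1.00
and a −0.5 genetic correlation between the two target traits, emulating
the yield/flavour antagonism; per-year noise is scaled so the per-year
broad-sense heritability hits the target (h² = 0 zeroes the genetic
signal; h² = 1 has no year noise), which closes the loop with the ANOVA
estimator.  True breeding values are returned for oracle tests.

Fixture presets: `tiny` (12 individuals × 80 markers × 3 traits, for
seconds-scale tests) and `panel96` (96 × 10⁴ × 20, the study scale).
Bundles are byte-identical for a given seed.

## Problem sizes in the test and acceptance runs

The acceptance-style checks use: the panel96 founder set (96 × 10⁴
markers) with Bayes C/EBL models for the two targets and RR for tracked
non-targets; 5 generations × 5 replicates at n = 96; 10⁴ crossover draws
and 2 × 10⁴ gametes for the Poisson/Haldane oracles; 2000 single-seed-
descent replicates; heritability recovery at n = 200 × 4 years × 8 seeds;
and MLM calibration over 2000 markers on a structured panel of 200.
These sizes keep every statistical band (3 SE or binomial CI) tight
enough to be meaningful while the whole suite runs in well under a minute
per component on one CPU.

## Known limitations

* No crossover interference, mutation, or sex-specific recombination —
  faithful to the model, but real genomes deviate.
* Single-trait prediction models only; no multi-trait joint models,
  dominance or epistasis terms.
* The P3D approximation slightly miscalibrates p-values for markers with
  large effects (conservative); use `exact=True` when that matters.
* The EBL call threshold is a heuristic shortlist rule (see above).
* Selection assumes GEBV ranking only; optimal-contribution selection and
  mate allocation are out of scope, though the interfaces admit them.
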