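# Methods

This note documents the models behind `orchardgs`, the choices made where
the design was genuinely open, and what the synthetic data do and do not
establish.

## 1. The synthetic cross (`simcross`)

The generator emulates a biparental F1 population of two highly
heterozygous outbred parents — the pseudo-testcross design used for
mapping in stone fruits.

**Markers and segregation classes.** Each SNP is assigned to `ab x aa`
(heterozygous in parent 1 only), `aa x ab` (parent 2 only) or `ab x ab`
(both) with default class probabilities (0.45, 0.35, 0.20). The real
population's class mix is not reported anywhere we could anchor to, so
these are free parameters chosen to make parent-1 markers somewhat more
abundant (as observed in the real linkage maps, where the female map
carried more markers). Homozygous parents carry the reference allele;
heterozygote phase is random. Default layout: 8 chromosomes of 90 cM
(the real parental maps average roughly 70–105 cM per linkage group)
carrying 80 markers each — 640 SNPs, about 1% of the real panel — with
153 progeny.

**Meiosis.** Crossover counts are Poisson(L/100) with uniform placement
and a random start phase: no interference, i.e. Haldane-consistent.
Kosambi's map function is provided for distance/recombination conversion,
but validation oracles use Haldane because that is the generative truth
here. Modelling interference would change two-locus probabilities only
mildly at the map densities involved and is out of scope.

**Phenotypes.** For trait t,

```
y_ijk = mu + TBV_i + year_j + lot_k + gxy_ij + e_ijk
```

with `TBV = Q eff` over `n_qtl` pleiotropic loci drawn among the
simulated markers. Per-locus effect vectors are multivariate normal with
correlation `genetic_corr`; after drawing, the effect vectors are
linearly recombined so that the *realized* TBV covariance equals the
target exactly. This matters: linkage leaves only ~2–4 independently
segregating segments per chromosome in an F1 cross, so without the
recombination step the realized genetic correlation wanders by ±0.3
around its target even with 80 QTL. The recombination preserves the
truth invariant `TBV = Q eff`.

`major_qtl_share` rescales one designated locus to carry a set fraction
of the genetic variance (0.5 reproduces the "one major QTL explaining
half the genetic variance" architecture seen for fruit colour and
ethylene-type traits).

**Heritability bookkeeping.** `h2_target` is defined at the genotype-mean
level: `h2 = Vg / (Vg + s2_gy/ny + s2_e/(ny nl))`. Year main effects are
shared by all genotypes and cancel from genotype-level variance, so they
are parameterized separately (`var_year`, relative to Vg). `var_gxy` is
the share of the non-genetic genotype-level variance carried by G x Y
(default 0.25), which keeps any target in (0, 1] internally consistent.
Maturity lots enter as fixed shifts (default -0.5, 0, +0.5 genetic SDs),
mirroring firmness-sorted fruit batches.

**What the generator does not emulate:** genotyping errors (only
missingness), segregation distortion, multi-generation pedigrees,
spatial field structure, non-Gaussian residuals. Tests passing on these
data show the estimators are correct under the stated model, not that
field data meet the model.

## 2. Phenotype adjustment (`pheno`)

Two REML fits per trait, both by direct maximization of the restricted
log-likelihood over log variance components (L-BFGS with the analytic
gradient `d l / d s2_k = -1/2 [tr(P G_k) - y' P G_k P y]`; convergence
ftol 1e-11, 200 iterations, non-convergence flagged, never silent):

* *adjustment model* — genotype and G x Y random, year and lot fixed;
  adjusted value = overall fixed-effect mean + genotype BLUP. BLUPs are
  shrunken, so their variance is below that of raw genotype means.
* *all-random model* — genotype, year, lot, G x Y random — supplying the
  five components of the genotype-mean-basis H2 formula. Fitting year and
  lot as random in a 2-year x 3-lot design estimates those components
  from 2 and 3 levels; the H2 formula dilutes them by ny and nl, so their
  imprecision contributes little.

A single-year/single-lot table degenerates to genotype means with a
warning. The log transform for strongly right-skewed rate traits
(ethylene production) is natural-log with a +1 offset so zero readings
survive; base and offset are configurable since neither is dictated by
the chemistry.

Hue angle is the quadrant-correct `atan2(b*, a*)` in degrees, the CIELAB
convention.

## 3. Genotype QC and the GRM (`genotypes`)

Dosages count alternative-allele copies (0/1/2, NaN for missing).
Filters: per-marker genotype quality > 20 and missing rate < 5%
(defaults), then a Mendelian segregation test per marker — chi-square
goodness of fit against 1:1 or 1:2:1 at p < 1e-6, with the ratio chosen
from the marker's known segregation class when available and inferred
from the observed genotype classes otherwise (two classes → 1:1, three →
1:2:1; an exact binomial test replaces chi-square when expected counts
fall below 1). Missing calls are imputed by the per-marker mean of
observed dosages, which preserves marker means and leaves observed
entries untouched.

The GRM is VanRaden's `A = W W' / 2 sum p_i (1 - p_i)`. `W` defaults to
dosage minus `2 p_i` (frequency-centered; the plain {-1, 0, 1}
heterozygote coding is its p = 0.5 special case and is available
uncentered). Frequencies come from the data at hand by default and can be
overridden (e.g. founder frequencies). A 1e-6 ridge keeps `A` invertible
for BLUP solvers. Within a single full-sib family the centered GRM's mean
off-diagonal is ~0, with pairwise IBD variation appearing as spread
around it; the textbook 0.5 expectation for full sibs presumes parents
drawn from an outer base population, which a single cross does not have.

Individuals with corrupt genotype profiles are removed via an explicit
exclusion list — the package does not guess an anomaly criterion.

## 4. Whole-genome regression (`wgr`)

**RR-BLUP / GBLUP.** Single-kernel REML on the eigendecomposition of
`ZZ'` (or `A`): the variance ratio `delta = s2_e/s2_u` is profiled on a
40-point log grid refined by bounded Brent iteration (tolerance 1e-8 on
log delta). Marker effects use the kernel identity
`u = Z'(ZZ' + delta I)^-1 (y - X beta)`, so cost scales with n (153),
not p. GBLUP predicts unphenotyped individuals through the
validation-by-training block of `A`. The two models agree to numerical
precision when `A` is built from the same centered markers — a standing
test.

**Bayesian alphabet.** One numba-compiled Gibbs kernel serves BRR,
BayesA, BayesB, BayesC and the Bayesian LASSO; single-site conjugate
updates on a running residual, sampled intercept, scaled-inverse-chi-
square residual variance. Priors follow common practice for these
samplers: nu = 5 for marker and residual variances, scales set so the
prior mode corresponds to markers explaining R2 = 0.5 of phenotypic
variance; BayesB's prior null probability pi = 0.95 (fixed), BayesC's
pi ~ Beta(1, 1) (sampled), BL's lambda^2 ~ Gamma(1.1, rate matched to
the usual initialization). All exposed in the constructor. Default
chain 12,000 iterations / 2,000 burn-in / thin 5; tests and experiments
use shorter chains (3,000/500/2 and similar) — the BRR-vs-ridge check
runs 20,000 iterations because it asserts agreement at 0.999. Chains are
seed-reproducible bit for bit; a non-finite residual variance aborts with
diagnostics rather than returning garbage.

**QTL as fixed covariates.** `fit_qtl_fixed` moves chosen tag SNPs from
the random term into the fixed design (intercept first, genome order,
duplicates collapsed, collinear columns dropped keeping the first). The
remaining markers stay random under RR-BLUP. An empty QTL list reduces
exactly to the baseline model.

## 5. QTL scanning (`qtl`)

Full composite interval mapping is deliberately replaced by a
marker-based scan with forward-selected cofactors: markers here are dense
relative to the map, so testing at markers rather than walking intervals
changes little while keeping the scan a pure linear-model computation
(`LOD = (n/2) log10(RSS_red/RSS_full)`, vectorized over markers via
residualized correlations). Markers within a 10 cM window of a cofactor
are excluded from the conditional scan. Permutation thresholds permute
the phenotype jointly against the whole genotype matrix (preserving
marker LD) and take the empirical `(1 - alpha)` quantile of the
genome-wide max LOD; 1,000 permutations at alpha = 0.01 are the
paper-faithful settings, 200 the fast default in experiments. Detection
iterates scan → promote top marker above threshold → rescan, capped at 5
peaks (and never more than n/3); peak R2 is the partial variance
explained in the joint model over all peaks.

**Tag selection for the fixed-covariate model.** When fold-wise detection
feeds `fit_qtl_fixed` inside cross-validation, peaks are reduced to one
tag SNP per distinct QTL: peaks are taken in decreasing LOD order and
kept only if their dosage correlates below 0.5 with every kept tag, and
the fold scan uses a 30 cM exclusion window. Rationale: LD in an F1
cross decays roughly as (1 - 2r), still ~0.8 at 10 cM, so narrower
windows let forward selection promote near-duplicates of one region;
fixing several strongly collinear unshrunk covariates was measured to
cost up to 0.36 accuracy in single folds. One tag per region matches the
intent of using SNPs tightly linked to distinct QTL as covariates.

## 6. Multi-trait prediction (`multitrait`)

The bivariate GBLUP stacks the observed records of both traits;
`u ~ N(0, Sigma_u (x) A)` and residuals are independent across
individuals with trait-pair covariance only for co-observed records
(missing at random). REML maximizes over Cholesky factors of `Sigma_u`
and `Sigma_e` (L-BFGS-B, bounded, ftol 1e-11), so estimates are positive
semi-definite by construction — no bending step is ever needed, and the
genetic correlation `r_g = Su12 / sqrt(Su11 Su22)` is always in [-1, 1].
With both covariances forced diagonal the likelihood factorizes, and that
case is fitted by its exact factorization (two univariate REML fits),
making the decoupling and nesting invariants hold to numerical precision.
Genetic values for all individuals — including those unphenotyped for one
trait — come from the mixed-model equations through the covariance
structure.

The model-based index is two-stage: single-trait proxy GEBVs enter the
focal model as a fixed covariate whose coefficient is estimated by
generalized least squares inside the same mixed model (not plugged in
from the proxy fit); predictions add the covariate contribution to the
GRM-structured random effect. A zero-variance proxy degrades gracefully
to univariate GBLUP.

Only trait pairs are implemented; the experiments of interest are
pairwise.

## 7. Cross-validation (`cv`)

Each replicate draws a fresh random 75/25 partition
(training = floor(0.75 n)); individuals are never duplicated within a
replicate. A bootstrap-training mode (training set resampled with
replacement) exists behind a flag for comparison, but plain subsets are
the default because duplicated individuals would corrupt the mixed-model
assumptions and the 43/76/115 training-size design implies subsets.
Validation phenotypes are the adjusted genotype-level values, consistent
with training. Accuracy is the Pearson correlation between predicted and
observed validation values; constant vectors yield a missing value, not
zero. Summaries are plain means and sample SDs per factor cell (no
Fisher z). Variance components are re-estimated per replicate. Replicate
failures are logged and skipped; more than 20% failures aborts the run.

Scenarios: baseline (model comparison), training-set size (43/76/115 —
25/50/75% of 153), marker density (random SNP subsets), fold-wise QTL
detection feeding the fixed-covariate model, and the focal-trait
missing-rate sweep (0–90%) for the multi-trait methods.

## 8. Experiment problem sizes (`experiments`)

The canned experiments run at the study's dimensions — 153 progeny,
8 chromosomes, 640 SNPs — with these specifics:

* *Marker density* uses a denser 3,200-SNP panel (8 x 400). The point of
  the density experiment is a panel saturated well below full density
  (the real panel plateaued at 10%); a 640-SNP panel is not yet saturated
  at 10% of itself, so it cannot exhibit the regime being demonstrated.
* *Directional comparisons at the ±0.03 scale* (QTL-fixed vs baseline;
  index vs univariate) average over several independent simulated
  populations times cross-validation replicates (e.g. 5 x 20), because a
  single simulated trait is one draw of the genetic architecture and its
  truth-level variance dominates differences of that size.
* The QTL-fixed experiment contrasts a trait with one QTL at 50% of
  genetic variance against a no-major-QTL trait (30 modest loci, top
  shares 10–15%), both at h2 = 0.6. The trait-assisted experiments use a
  focal trait at h2 = 0.45 with a proxy at h2 = 0.9 and genetic
  correlation 0.8 — an easy, heritable proxy standing in for a costly
  trait.
* Heritability recovery feeds GBLUP genotype-level phenotypes
  (TBV + noise at the target h2) and reports
  `s2_u mean(diag A) / (s2_u mean(diag A) + s2_e)`; the diagonal scaling
  matters because within-family GRMs have mean diagonal ~0.75 under the
  default class mix.

## 9. Known limitations

* Mean imputation flattens LD information; no haplotype-aware imputation.
* The scan tests at markers only; interval positions between markers are
  not interpolated, and two-QTL epistasis scans are absent.
* The Bayesian samplers report posterior means only (no full posterior
  summaries beyond the stored diagnostics).
* Bivariate (not general t-trait) multi-trait models.
* REML in the adjustment module is dense (O(n^3) per likelihood
  evaluation) and comfortable up to a few thousand records, not field
  networks of trials.
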