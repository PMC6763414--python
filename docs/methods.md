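# Methods

This note documents the models behind `wheatgs`, the choices made where
the design was genuinely open, and what the synthetic data generator
does and does not emulate.

## Trait catalogue and scales

Ten traits: grain yield (GY, dt/ha), protein content (PC, %), protein
yield (PY, dt/ha), water uptake (WU, %), dough development time (DEV,
min), stability (STAB, min), softening (SOFT, FU), extensibility (EXT,
mm), resistance to extension (RES, EU) and dough energy (ENG, cm²).
Softening is recorded lower-is-better; `preprocess_softening` inverts
it (×−1) once — a processed flag in `DataFrame.attrs` guards against
double inversion — so that all rheology traits point in the favourable
direction and the strength group correlates positively. Protein yield
is GY·PC/100 wherever it appears: in true genetic values, at plot
level, and never as an independently drawn trait.

## Synthetic breeding programme

The generator supplies ground-truthed data with the statistical
structure the analysis assumes; it is first-class, tested code.

**Genotypes.** Gene dropping through a founder pool: a handful of
ancestral haplotypes (default 4) define block-wise allele frequencies;
25 founder lines (two haplotype mosaics each, switch probability 0.08
per marker interval) are reused as parents across families, exactly as
elite parents recur in a practical programme. Each line is a doubled
recombinant gamete of an F1 between two founders, with 2 % residual
heterozygosity (dosage 0) to exercise the heterozygote-coding rule.
Parent reuse matters: without it the realized kinship matrix is too
close to isotropic for variance components to be identifiable in
100-line validation sets, and no amount of marker data fixes that.
Defaults (480 lines / 394 families / 21 × 350 markers) mirror the
population size the pipeline targets; the full generator runs in a few
seconds.

**Trait architecture.** Background effects sit on 300 random markers
with across-trait covariance proportional to a fixed correlation matrix
Σ_G (unit diagonal, PSD; cor(GY, PC) = −0.6, strength-group
correlations 0.6, viscosity pair 0.6, WU weakly attached, yield mildly
negative against the rheology traits). The generating correlations are
a calibration choice — they are set so that the realized GEBV-level
yield/protein trade-off lands near the strongly negative values
reported for real elite material — and are config-overridable. The
polygenic part is standardized to unit variance per trait, then
glutenin-locus contributions are added in SD units (Glu-D1 strongest,
acting on the strength group), so a locus effect of 0.5 means half a
background-genetic SD per allele substitution. Trait values are
mean + genetic-SD × standardized value on the measured scale.

**Trials.** Plot value = trial effect + genetic value + AR1(ρ_row) ⊗
AR1(ρ_col) Gaussian field + iid error. Noise scales are derived from
target plot-level heritabilities (default 0.6 agronomic, 0.4 rheology)
with 30 % of the non-genetic variance spatial. The default series — 6
agronomic trials covering 50 % of lines each and 5 rheology trials
covering 60 %, line sets staggered so consecutive trials interleave,
3 checks replicated 3–4× — is a deliberate reduced-scale rendering of
a 136/86/66/29-trial programme. The staggering is load-bearing: it
guarantees each line sits in ~3 trials per series, so the h² trial
filters (which legitimately drop 10–25 % of rheology trait-trials at
this scale, given only ~9 error degrees of freedom from the checks)
almost never orphan a line.

**What the generator does not emulate:** realistic recombination maps,
selection history, dominance/epistasis, genotype-by-environment
interaction beyond trial main effects, non-Gaussian measurement error,
and year structure beyond a label. Tests passing on this data show the
estimators work when their assumptions hold at realistic sizes; they do
not certify performance on data violating those assumptions.

All randomness flows from one integer seed through
`numpy.random.SeedSequence` spawning, in a fixed order per stage.

## Stage-one spatial analysis

For one trial × trait, the model is y = X τ + Z_r u_r + Z_c u_c + ε
with genotype fixed (one-hot, no intercept — BLUEs are the
coefficients), optional random row/column effects, and
Cov(ε_i, ε_j) = σ²_e ρ_row^|Δrow| ρ_col^|Δcol| (ρ = 0 collapses a
direction to independence, so one formula covers all four residual
structures). REML is maximized by L-BFGS-B over log variance ratios
and atanh correlations with the residual scale profiled analytically;
dense Cholesky algebra is used throughout (trials ≤ ~500 plots).
Numerical choices: ratio bounds [1e−6, 1e6] (ratios at the lower bound
reported as 0, boundary-flagged), ρ bounded to ±0.95, optimizer ftol
1e−10, a 1e−8 diagonal ridge for factorization stability. A single
row or column pins the corresponding ρ at 0 and removes it from the
parameter count.

AIC = −2·logLik_REML + 2·(number of variance parameters). Comparing
REML likelihoods across the 16 candidates is valid because they share
identical fixed effects; only the random structure varies. Ties break
toward fewer variance parameters, then toward the earlier candidate
(baseline first).

BLUEs require genotype fixed; σ²_G requires genotype random — each
trial is fitted twice under the selected structure, with identical
residual specification. MVD is the mean over all line pairs of
Var(BLUE_i − BLUE_j) from the GLS covariance, and
h² = σ²_G/(σ²_G + MVD/2).

For rheology trials, where only checks are replicated, the error
variance is pooled from check replicates (assuming other lines share
it) and σ²_G comes from the moment estimator
max(var(line means) − σ²_e/r̄, 0) with r̄ the mean replication. A
genotype-random REML variant was tried and rejected: with ~9 check
plots it collapses to the zero boundary far too often, whereas the
moment estimator degrades gracefully. A trial with no replication at
all is a passthrough (BLUEs = plot values) flagged un-assessable; such
trials are retained for rheology traits, matching the rationale that
these phenotypes are too costly to discard.

Trial filters: agronomic h² > 0.3 (strict), rheology drops h² < 0.1
(strict), un-assessable kept. Stage two is ordinary least squares with
genotype fixed and sum-to-zero trial coding (unweighted — the
across-trial model carries no weights; a smoothed weighting is left as
future work), with h² again from a genotype-random REML fit plus the
OLS MVD. Trial connectivity is checked by union-find; a fully
disconnected trial set is an error, partial groups are flagged.

Whether the stage-one genotype effect should be fixed or random is a
known open point in two-stage analysis; fixed is the default here
(BLUEs feed stage two), and the genotype-random fit exists solely to
supply σ²_G.

## Genotype processing

QC thresholds: call rate < 90 %, MAF < 0.05, missingness > 10 % (all
strict as stated). Imputation is chromosome-wise only. The default
imputer is an iterative nearest-marker classifier: initialize with
column modes, then re-predict each originally missing entry as the
weighted majority vote over the ≤ 5 most correlated same-chromosome
markers (weights r², votes sign-aligned, the column mode casting a
prior vote of a quarter of the total weight), looping to convergence
(≤ 5 passes). It is a deliberately simple iterative classifier in the
spirit of forest-based imputers, and on masked-entry experiments it
beats plain column-mode imputation whenever LD is present. The GRM
uses the Endelman–Jannink/VanRaden form with denominator
2Σ p_k(1−p_k) > 0 and p_k computed from the imputed matrix (computing
it before imputation would change little; after is the defensible
default since downstream algebra uses the imputed dosages).

Glutenin recoding: Glu-A1 0→−1, {1, 2*}→+1; Glu-B1 6+8→−1,
{7+8, 7+9}→+1; Glu-D1 5+10→−1, 2+12→+1; heterozygous → 0; unknown
strings are errors, not warnings. Unscreened lines are coded 0
(neutral) for model matrices, with a drop-lines alternative.

Modified Rogers' distance for dosages z ∈ {−1, 0, +1}:
D_ij = √(Σ_k (z_ik − z_jk)²/(4m)), the biallelic reduction of the
allele-frequency form; 0 for identical lines, 1 for opposite
homozygotes at every locus.

## Genomic prediction

Single-kernel REML profiles the restricted likelihood on
δ = σ²_e/σ²_u after one eigendecomposition of the kernel projected
orthogonal to the fixed effects (a q×q eigenproblem when the kernel is
a low-rank Z Z'), then a bounded scalar search over log δ ∈ [−15, 15];
endpoint wins are reported as boundary estimates (δ → ∞ is σ²_u = 0).
This is exact and O(n) per likelihood evaluation after the
decomposition.

WBLUP-fixed absorbs the three locus columns into the GLS fixed effects
(columns constant in training are dropped with a warning). WBLUP-random
gives each locus its own variance — differential shrinkage — estimated
by the general dense REML over (σ²_u, σ²_A1, σ²_B1, σ²_D1, σ²_e);
locus BLUPs are β̂_j = σ²_j M_j' V⁻¹(y − μ̂). Marker-only prediction
omits the genomic kernel entirely (the alternative reading, keeping
u_G, is exactly WBLUP and already available). Predictions for untested
lines go through Cov(u_test, y_train) = σ²_u K[test, train].

Genomic heritability in a validation set:
h²_GEN = (σ²_P − σ²_e)/σ²_P with σ²_P the sample phenotypic variance
and σ²_e from the validation-only GBLUP fit, clamped to [0.01, 1] with
a flag — the floor prevents division blow-ups in the accuracy
denominator. At n = 100 this estimator is honest but noisy (sd ≈ 0.2
with realistic kinship); its mean recovers the configured entry-mean
heritability, which is what the pipeline relies on.

## Selection indices

Weights solve G b = a on centred and standardized GEBVs; the solver
refuses condition numbers above 1e8 with a pointer to drop collinear
components — no silent ridge. Sub-indices (STRH over RES, ENG, STAB,
inverted SOFT; VISC over EXT, DEV; both with all-ones gains) are
re-standardized before entering the four-component combined indices,
so λ and γ are in the same SD units as the single-trait gains. Water
uptake never enters an index. Conventions chosen here: sample (n−1)
standard deviations throughout; the standardization reference within an
evaluation replicate is the validation candidate set (the set actually
being ranked), with whole-population standardization available; G and
b are re-solved inside every replicate from that replicate's predicted
GEBVs. The default λ, γ sweep grid is 0, 0.1, …, 1.0.

If a trait's fit lands on the zero-genomic-variance boundary its GEBVs
are constant; the evaluation harness carries that column as exact
zeros (with a warning) so that only indices including the dead trait
fail, and they fail loudly through the condition-number check.

## Evaluation

Partitions are disjoint simple random samples (default 300 train / 100
validation, 100 replicates; reduced presets for quick runs), shared
across all predictors within a run so method comparisons are paired.
Ability is Pearson r between predictor values and observed validation
BLUEs; accuracy divides by √h²_GEN of the **target** trait (the
convention that makes cross-trait accuracies comparable); values beyond
|1| are reported as computed and flagged. Response to selection
standardizes observed values within the validation set, selects the
top 10 % by the predictor (ties broken by line ID for determinism) and
returns h²_GEN × mean(selected standardized values). When true genetic
values are available the realized standardized true gains of the same
selected set are recorded alongside — this is the ground-truth check
that the predicted responses track reality.

The λ/γ sweep reuses per-replicate fitted states, so each grid point
costs only index algebra; the argmax is reported for a configured
objective (protein-yield accuracy by default).

## Known limitations

- Stage-one REML uses numeric gradients; pathological trials
  (near-singular layouts) fall back to boundary reports rather than
  failing, but fits are not guaranteed global optima.
- The checks-only heritability has ~9 error degrees of freedom at the
  default design and is accordingly coarse; it is a trial filter, not
  an estimand of interest.
- The marker-only and WBLUP models handle exactly the three glutenin
  loci; arbitrary major-gene panels would need a generalized design
  matrix (straightforward, not wired up).
- Multi-trait mixed models, Bayesian whole-genome regressions, G×E
  kernels and economic-weight (phenotypic) indices are out of scope.
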