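# Methods

## The scientific problem

Classical twin designs estimate how much of the individual variation in a
phenotype is attributable to genetic differences by comparing monozygotic
(MZ) twins, who share all their segregating genes, with same-sex dizygotic
(DZ) twins, who share half on average. Here the phenotypes are not
questionnaire traits but scores derived from a multi-trial belief-formation
task about personal risk: on each trial a participant estimates the
probability that an adverse event will happen to them (the *prior* or first
estimate), sees the base rate in a demographically similar population (the
*information*), and later re-estimates (the *posterior* or second
estimate); a subset of events is additionally rated on vividness of
imagination, negativity, familiarity and past experience, and probed for
recall of the presented base rate.

The package implements the complete chain — phenotype derivation, twin
similarity via permutation partial correlations, and maximum-likelihood
ACE/ADE variance decomposition — plus a synthetic-cohort generator with
known variance-component ground truth so every stage can be validated
without access to a real twin registry.

## Phenotype definitions

Per trial:

* **update** = |second − first|, signed positive when the second estimate
  moved toward the information (overshooting still counts as toward) and
  negative when it moved away. When the first estimate already equals the
  information the direction is undefined; such trials are excluded and the
  exclusion count is logged. This avoids an arbitrary sign assignment at
  the cost of a handful of trials.
* **estimation error** = |first − information|.

Per subject: mean update; the **learning score** (Pearson correlation of
update with estimation error across usable trials, requiring ≥ 3 trials
with variance on both sides — a subject who scales their update by how far
off they were scores near 1); the **memory score** (% of recall probes
matching the presented information; "correct" defaults to exact integer
match, the strictest reading, with a configurable ± tolerance); means of
the four 1–6 ratings over the rated events (the design forces this:
unrated events have no ratings); and the mean prior. Subjects missing more
than half of a phenotype's inputs get a missing value rather than a noisy
one. Group-level checks are one-sample t-tests of mean update and learning
score against zero, and per-subject prior/rating correlations compared to
zero across subjects.

## Twin similarity: permutation partial correlations

Within a zygosity group, the correlation between "twin A" and "twin B"
depends on the arbitrary assignment of pair members to the two roles. Each
pair's members are therefore independently relabelled A/B with probability
½, 10,000 times; each relabelling yields one partial correlation, and the
distribution is summarised by its mean and 2.5/97.5 percentiles. Disjoint
MZ and DZ intervals with the MZ band higher is the qualitative signature
of heritability.

Each correlation is partial. Controls are the within-pair differences
(twin A mean − twin B mean) of the other task factors — prior, the four
ratings, memory score, plus estimation error when the focal phenotype is
update — and the pair's age. Two policy details: memory is not a control
for the prior (the prior is given before the information that memory
refers to), and age enters at the pair level because twins share age, so
an A−B age difference would be an identically-zero column and could not
control for anything. The focal phenotype is never among its own controls.
Partial correlation is computed by double residualization (least-squares
projection of both focal vectors on the covariates plus intercept),
equivalent to the textbook recursive formula; the permutation engine
batches the per-relabelling solves. Pairs missing a needed value are
dropped listwise per phenotype. An exhaustive mode enumerates all 2^n
assignments for small groups and anchors the Monte-Carlo tests.

## Variance decomposition

The biometric model writes twin *i* of pair *j* as
y_ij = μ + x_ij'β + A_ij + C_j + E_ij, giving each pair a bivariate normal
likelihood with common variance σ²_A + σ²_C + σ²_E and within-pair
covariance R_j σ²_A + σ²_C, R_j = 1 (MZ) or ½ (DZ). The ADE family
replaces C with a dominance component D whose DZ coefficient is ¼ (the
standard biometric value for full siblings). Submodels AE, CE and E drop
components; DE is rejected as unidentified (dominance cannot be estimated
without additive effects).

Implementation choices:

* **Parameterization.** Path coefficients (a, c/d, e) are optimized and
  squared into variances, guaranteeing nonnegativity without constraints;
  σ²_E is floored at 10⁻⁶ × the phenotypic variance to keep the
  likelihood bounded on the degenerate ridge.
* **Covariates** (age, sex coded female = 1, age×sex, and the same task
  control factors as the permutation analysis, with the same per-phenotype
  exclusions) enter as fixed effects on the mean, identical coefficients
  for both twins, z-scored internally for conditioning; constant columns
  are dropped.
* **Optimization** is multi-start (equal-split variances, Falconer-style
  moment estimates, random Dirichlet splits, plus any nested model's
  solution) L-BFGS-B followed by a Nelder-Mead polish. In model selection
  the submodels are fitted first and their solutions seed the richer
  models, so a richer model never fits worse than a model it nests.
* **Bookkeeping** follows the twin literature: ep counts the intercept
  plus variance components (E: 2, AE/CE: 3, ACE/ADE: 4; covariate
  coefficients excluded), df = 2·n_pairs − ep, AIC = −2LL + 2·ep, smaller
  is better, ties broken toward fewer parameters. −2LL includes the full
  Gaussian normalizing constant; only within-phenotype differences are
  meaningful.
* **Confidence intervals** are profile likelihood on the standardized
  (percentage) scale: the set of shares whose profiled −2LL stays within
  χ²₁(0.95) = 3.841 of the minimum, found by bisection with warm-started
  inner optimizations, truncated to [0, 100]. Lower limits collapsing to
  zero flag boundary solutions (the analogue of printed values like
  1.6e-14). The single-component E model has a degenerate interval at
  100%. A component's profile CI treats the remaining components'
  proportions via stick-breaking logits, so ACE/ADE intervals profile over
  the nuisance split.

## The synthetic-data generator

Latent subject traits (learning rate, vividness propensity, negativity
propensity, memory fidelity, prior offset) are standardized sums
√v_A·A + √v_C·C + √v_D·D + √v_E·E with A shared fully by MZ co-twins and
split √½ shared / √½ unique for DZ (dominance: √¼ / √¾), so the implied
within-pair covariances are exactly v_A + v_C + v_D (MZ) and
½v_A + v_C + ¼v_D (DZ) with unit marginal variance. C and D are mutually
exclusive in one scenario (ACE vs ADE worlds) and fractions renormalize
to 1.

Trial records are minimal linear maps with clipping — the object under
test is the phenotype definitions, not the generative model, so every
coefficient is exposed on `SimulationConfig`:

* Event base rates: 40 integers uniform on [10, 70], shared by all
  subjects; half the events carry a genetic-predisposition label for the
  stratified analysis.
* Rating latents: trait + N(0, 0.8) per trial; observed ratings are the
  latents cut into six equal-probability bins (1–6). The *same* trial
  latent shifts the first estimate (vividness +3, negativity −1.5,
  familiarity +2.5, experience +2.5 estimate units per latent SD), which
  is what produces the within-subject prior/rating correlations the task
  exhibits.
* First estimate = clip(round(base rate + 8·prior_offset + rating shifts
  + N(0, 5)), 3, 77); the 3–77 bounds and the 10–70 base-rate range match
  the task design (equal room to over- and under-estimate).
* Second estimate moves a per-subject gain = clip(0.5 + 0.25·learning
  rate, 0, 1) of the way toward the information, plus noise: a maximal
  learner with no noise lands exactly on the information.
* Recall equals the information with probability clip(0.65 +
  0.25·memory fidelity, 0, 1), otherwise it is displaced by a nonzero
  integer up to ±15. Exactly 20 of the 40 events per subject (a per-
  subject random subset) carry ratings and recall.
* Demographics mimic a volunteer twin registry: pair-shared age from
  N(52, 14) truncated to [18, 90], 88% female pairs.

Defaults are the study scale — 184 MZ + 80 DZ pairs — in an AE world with
v_A = 0.35, the middle of the heritability range such task phenotypes
show.

**What the generator does not emulate:** realistic per-event base rates
(no population-statistics sourcing); valence asymmetries in updating;
any genetic correlation *between* traits (each is drawn independently, so
the control factors carry almost none of the focal traits' genetic
structure); and realistic recall behaviour — because simulated priors
track the true base rates and recall reproduces them, the within-subject
prior/recall correlation is far stronger than real participants show.
Passing tests therefore demonstrate that the machinery recovers known
ground truth under the stated assumptions, not that real data meet those
assumptions.

## Validation design and problem sizes

* Covariance algebra: 50,000 pairs per zygosity, empirical within-pair
  covariances within 0.01 of the σ-algebra.
* Likelihood oracle: on 30 covariate-free pairs, the optimizer's deviance
  is compared with an exhaustive 0.01-resolution grid over
  (σ²_A, σ²_C, σ²_E) with the grand mean profiled out by GLS (agreement
  within 0.05 deviance units).
* Permutation oracle: exhaustive 2^10 enumeration on 10 pairs vs the
  10,000-draw Monte-Carlo mean (within 0.01); with no covariates the
  permutation mean is also checked against the one-way ANOVA intraclass
  correlation.
* CI calibration: 200 AE cohorts at study scale (184/80, true A = 35%);
  the 95% profile CI covers truth in 90–99% of runs and mean |Â − 35| <
  5 points.
* Model selection: 150 replicates per world at study scale, candidate set
  {ACE, AE, CE, E}. World strengths were set by a power analysis at this
  n: E world (v_E = 1), AE world (v_A = 0.7), CE world (v_C = 0.8). Note
  an intrinsic ceiling: when the truth lies on a submodel boundary, the
  one-extra-parameter model steals the AIC win whenever its
  likelihood-ratio improvement exceeds 2, with asymptotic probability
  ½·P(χ²₁ > 2) ≈ 7.9% — so even arbitrarily strong worlds top out near
  92% correct selection, and weaker worlds (e.g. v_A = 0.4) fall to
  ~80% through genuine AE/CE confusion at 80 DZ pairs.
* Falconer consistency: at 50,000 pairs per zygosity the fitted
  standardized A agrees with 2(r̄MZ − r̄DZ)·100 within 2 points.

## Known limitations

* Fitting assumes bivariate normal phenotypes within pairs; derived
  scores (a correlation, a percentage) are bounded and only approximately
  normal.
* Profile CIs use the χ²₁ cutoff throughout; at variance boundaries the
  true null distribution is a χ² mixture, making the intervals mildly
  conservative there (coverage slightly above nominal, as the calibration
  check shows).
* Absolute −2LL/AIC values depend on the covariate coding and the
  Gaussian constant; only within-phenotype model rankings are
  interpretable.
* The permutation intervals quantify assignment ambiguity, not sampling
  uncertainty over pairs (by design; no bootstrap over pairs).
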