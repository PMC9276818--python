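# twinbeliefs

Twin-design heritability analysis of belief-formation task phenotypes.

## The problem

How much of the individual variation in the way people form beliefs about
personal risk — how strongly they update toward new information, how well
they remember it, how vividly they imagine adverse events and how
negatively they evaluate them — is attributable to genetic differences?
The classical twin design answers this by comparing monozygotic (MZ)
twins, who share all their segregating genes, with same-sex dizygotic
(DZ) twins, who share half on average: greater MZ than DZ similarity on a
phenotype indicates a genetic contribution.

The phenotypes come from a multi-trial belief-formation task: on each of
40 adverse life events a participant estimates the probability the event
will happen to them (the *prior*, bounded to 3–77%), sees the base rate
in a demographically similar population (10–70%), and later re-estimates;
20 randomly chosen events are additionally rated 1–6 on vividness,
negativity, familiarity and past experience, and probed for recall of the
base rate. Derived scores per subject: mean signed **update** (positive
when toward the information), the **learning score** (within-subject
correlation of update with estimation error |prior − information|), the
**memory score** (% correct recall), rating means, and the mean prior.

The package implements the full analysis chain for cohorts of this form —
and a synthetic twin-cohort generator with known variance-component
ground truth, so every stage is testable end to end:

1. **`twinbeliefs.synthetic`** — twin cohorts whose latent traits have
   within-pair covariance σ²_A + σ²_C (MZ) and ½σ²_A + σ²_C (DZ)
   (dominance variant: coefficients 1 and ¼), plus trial-level task data.
2. **`twinbeliefs.metrics`** — per-subject phenotypes and group tests.
3. **`twinbeliefs.permutation`** — twin similarity as the distribution of
   partial correlations under 10,000 random twin-A/twin-B reassignments,
   controlling for age and the within-pair differences of the other task
   factors, separately for MZ and DZ pairs.
4. **`twinbeliefs.biometric`** — maximum-likelihood ACE/ADE variance
   decomposition (pairwise bivariate-normal likelihood with covariance
   R_j σ²_A + σ²_C off-diagonal), submodels AE/CE/E, AIC = −2LL + 2·ep
   model selection, and profile-likelihood CIs for the standardized
   components.
5. **`twinbeliefs.pipeline`** — one-seed reproducible runs and a
   covariate-sensitivity comparison; `twinbeliefs.cli` exposes the verbs
   `simulate`, `metrics`, `twincorr`, `biometric`, `run`,
   `compare-covariates`.

The numbered scripts under `analysis/` walk the chain on a study-scale
synthetic cohort (184 MZ + 80 DZ pairs) and write their tables under
`results/`; `docs/methods.md` documents the models, parameter choices and
limitations.

## Worked example

```bash
python analysis/01_simulate_cohort.py
python analysis/02_derive_phenotypes.py
python analysis/03_twin_similarity.py
python analysis/04_variance_decomposition.py
```

prints, for the default cohort (an additive-genetic/unique-environment
world with 35% trait heritability):

```
update_mean: M = 4.24, SD = 2.86, t(527) = 34.075, p = 2.51e-135
learning_score: M = 0.39, SD = 0.22, t(527) = 40.333, p = 3.17e-163
prior ~ vividness: mean r = 0.102 (SD 0.23), t(522) = 10.12, p = 4.11e-22
...
update_mean: rMZ = 0.61 (0.59/0.63), rDZ = 0.41 (0.34/0.46) -> overlap: False, larger: MZ
learning_score: rMZ = 0.39 (0.37/0.41), rDZ = 0.04 (-0.02/0.09) -> overlap: False, larger: MZ
memory_score: rMZ = 0.31 (0.30/0.33), rDZ = 0.17 (0.12/0.22) -> overlap: False, larger: MZ
...
update_mean: winner AE, A = 47.0% (CI 35.4/57.1), E = 53.0% (CI 42.9/64.6), AIC = 2332.27, n = 264 pairs
memory_score: winner AE, A = 30.7% (CI 17.9/42.4), E = 69.3% (CI 57.6/82.1), AIC = 4865.51, n = 264 pairs
```

Reading the output: subjects update toward the information (mean update
4.2 points, t-test against zero) and scale updates by their estimation
error (mean learning score 0.39); priors correlate within subject with
vividness (positively) and negativity (negatively). MZ pairs are more
similar than DZ pairs on updating, learning and memory, with
non-overlapping 2.5–97.5% reassignment intervals — the signature of
heritability — and the AE model wins by AIC with standardized A around
the generating 35% (individual phenotypes scatter around it; with only
80 DZ pairs some draws land a CE winner, which is what the power analysis
in `docs/methods.md` predicts at this heritability).

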