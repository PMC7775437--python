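# Methods

## Scope and model

`readclock` implements targeted epigenetic age prediction for mouse
blood around three age-associated amplicons (Prima1, Hsf4, Kcns1,
covering 4, 12 and 21 neighboring CpGs). Age information enters through
per-CpG DNAm-vs-age trajectories: for CpG *i*, the methylated fraction
(beta) is modelled as

    beta_i(a) = intercept_i + slope_i * a        (a in weeks)

fit by ordinary least squares on a training cohort. Everything else is
built on top of these lines:

* **CpG selection** takes, per amplicon, the CpGs with the highest
  |Pearson r| between DNAm and age (ties to the lower index), the
  classic design being one CpG per amplicon (3-CpG clock).
* **Multivariable clock**: OLS of age on the selected betas. Rows with
  any missing selected beta are dropped, never imputed — cohorts are
  small and imputation would be silent invention.
* **Lasso clock**: coordinate-descent lasso (via scikit-learn) on
  internally standardised predictors, coefficients reported back on the
  beta-fraction scale. The penalty grid is glmnet-style: 100 log-spaced
  values from lambda_max (smallest penalty with an all-zero solution)
  down by a factor 1e-4; lambda is chosen by 10-fold cross-validation
  with a deterministic seeded fold shuffle, ties toward the sparser
  penalty. An independent proximal-gradient solver exists only in the
  test/verification layer as an oracle.
* **Evaluation** reports the squared Pearson correlation of predicted
  versus chronological age as the headline R² and also the identity-line
  R² (1 − SSres/SStot), since scatter-plot R² conventions differ;
  errors are median and mean |predicted − chronological| in weeks.

## Single-read age assignment

Individual bisulfite reads carry a binary sequel of methylated/
unmethylated CpGs. Under the stochastic-aging interpretation —
neighboring CpGs gain methylation independently rather than coherently —
a read pattern *x* from an animal of age *a* has likelihood

    L(a) = prod_i p_i(a)^{x_i} * (1 - p_i(a))^{1 - x_i},
    p_i(a) = clip(intercept_i + slope_i * a, eps, 1 - eps)

and is assigned argmax L(a) over the integer grid 0..200 weeks. Design
choices, all documented as interpretation rather than reconstruction:

* independent-Bernoulli likelihood (a neighbor-dependent model would
  contradict the empirical near-independence of neighboring CpGs);
* grid step 1 week, bounds fixed at 0 and 200; ties resolved to the
  lowest age (deterministic, conservative);
* eps = 0.01 keeps the log-likelihood finite where a trajectory leaves
  [0,1]; eps = 0 is rejected;
* missing calls drop out of the likelihood; reads missing at more than
  half their CpGs are excluded so partial reads cannot pile up at the
  grid boundaries;
* the per-sample prediction is the read-count-weighted mean of read
  ages; the per-sample grid distribution is stored as linear relative
  frequencies (log-scaling is presentation, applied only at plotting);
* the final per-animal age is the equal-weight mean over available
  amplicons (weights configurable).

Amplicon-level models keep *all* CpGs with a defined trajectory, not
only the top-correlated ones: weakly age-associated CpGs still shift
the likelihood.

## Read calling

Amplicon products are fixed-layout, so calling is alignment-free:
after orientation detection the read is compared positionally to the
reference. At each CpG cytosine, C ⇒ methylated, T ⇒ unmethylated,
anything else (or a read ending earlier) ⇒ missing. Two per-read QC
statistics gate every read:

* conversion rate — fraction of non-CpG reference cytosines read as T
  (bisulfite completeness); default floor 0.9;
* mismatch fraction — disagreement over the non-convertible positions;
  default ceiling 0.1.

These defaults are standard bisulfite practice, not reconstructions of
any particular pipeline's thresholds. Bottom-strand reads are detected
by comparing mismatch under both orientations and called in G/A space
after reverse-complement normalisation. Read 1 of a pair is assumed to
cover the amplicon; overlapping-pair reconciliation is out of scope.

## ddPCR quantification

With k positive droplets out of N in a channel, the mean copies per
droplet is lambda = −ln(1 − k/N); percent methylation is
100·λ_meth/(λ_meth+λ_unmeth). Conventions where instrument software is
a black box: channel counts are treated independently (a double-positive
droplet counts in both channels — this is what the per-channel Poisson
formula assumes); a saturated channel (k = N) is capped at −ln(1/(2N))
and flagged rather than failing; the 95% CI propagates the binomial
standard error of k/N through the log transform and the ratio (delta
method), truncated to [0,100]. With both channels empty the percent is
undefined (NaN, flagged).

## Synthetic cohort generator

The simulator provides the study conditions every other module is
tested under. It emulates:

* **bell-shaped age-association across an amplicon**:
  slope_i = peak_slope · exp(−(i − center)²/(2·width²));
* **stochastic per-read methylation**: given per-sample probabilities
  q_i = clip(baseline + slope_i·a′ + N(0, noise_sd), 0, 1), read states
  are independent Bernoulli draws; an optional latent-Gaussian knob
  (inter_cpg_rho) shares a per-read normal factor across CpGs, keeping
  the marginals while inducing positive within-read correlation, so the
  single-read model can be stressed against its own independence
  assumption;
* **strain acceleration** as a transform of chronological age before
  the trajectories are evaluated: identity (reference strain), linear
  s·a, or logarithmic A·ln(1 + a/tau). The logarithmic default is
  A = 60, tau = 8 weeks: tau must sit well below the cohort age range,
  otherwise ln(1+a/tau) ≈ a/tau and the transform degenerates to
  near-linear.

Defaults (chosen once, as the package's standing study conditions):
ages uniform over 0–130 weeks; 2,000 reads per amplicon per sample;
training n = 24 and validation n = 21; amplicons of 4/12/21 CpGs with
baseline 0.10, peak slope 0.004 fraction/week (≈10% → 60% DNAm over a
130-week lifespan at the central CpG, a realistic span for strongly
age-associated amplicons), profile width n/5 CpG units, per-sample
noise sd 0.03 on the probability scale. Cohorts are bit-reproducible
under (config, seed).

Reads can be rendered to bisulfite-converted FASTQ (non-CpG C→T, CpG C
kept iff methylated; optional per-site conversion-failure probability),
and the round-trip through the caller recovers the generating pattern
tables exactly when conversion is complete.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: sequencing errors and indels, quality-score
structure, PCR amplification bias between methylated and unmethylated
strands, cell-type composition shifts with age, nonlinear DNAm
trajectories, and real inter-mouse correlation structure beyond a single
Gaussian noise term per CpG.

### Analytic noise floor

For honest accuracy claims the simulator exposes the best achievable
error under its own generating model: each amplicon's peak CpG gives an
age estimate with variance (noise_sd² + q(1−q)/R)/slope²; the
inverse-variance combination across amplicons yields a variance floor,
and 0.6745·sigma converts to a median |error|. The pipeline test
requires the trained clock to come within 2× of this floor (≈3.2 weeks
at the defaults).

## Numerical and degenerate-input choices

* Zero-variance betas: trajectory slope 0 with Pearson r undefined
  (flagged NaN, never silently 0); such CpGs are excluded from
  single-read models and CpG selection.
* Rank-deficient clock designs raise an error naming the collinear
  columns instead of returning a pseudo-inverse fit.
* Pearson correlations from pattern tables use count-weighted moments
  over reads non-missing at both CpGs; zero-variance pairs are NaN with
  a warning.
* Beta scale is fraction [0,1] everywhere in memory; disk formats carry
  percent. Floats are serialised at 17 significant digits so round
  trips are exact.
* Problem sizes in tests and the acceptance script mirror the default
  study conditions (45 mice, 3 amplicons, 2,000 reads each; 1,000
  random oracle instances; 200 replicate ddPCR wells), the package's
  standing choice for a desk-scale, fully reproducible analysis.

## Known limitations

* The default panel's reference sequences are synthetic stand-ins with
  the right CpG counts and layout; analyses of real FASTQ require a
  user-supplied panel file.
* Calling is indel-intolerant by design; reads from amplicons with
  length polymorphisms will fail mismatch QC rather than be rescued.
* The single-read model assumes linear trajectories and independence
  within reads; both are approximations, and the rho knob exists
  precisely to measure sensitivity to the latter.
* Negative predicted ages are possible and reported as-is; clamping is
  left to the caller.
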