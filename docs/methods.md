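# Methods

This note documents the models, parameter choices and numerical decisions
behind `datedelay`, and what the synthetic-data tests do and do not show
about real data.

## Task geometry and timing

The default screen is a 1920×1080 display of 698.4 × 392.85 mm viewed from
1900 mm, which makes pixels isotropic (0.36375 mm/px) and reproduces the
nine-point calibration grid's printed visual angles (9.19° horizontal,
4.90° vertical, 10.38° diagonal) to within 0.01°.  Coordinates are 0-based
pixels, origin top-left, y downward; visual angles are measured from the
screen centre as atan(offset in mm / viewing distance).

The four AOIs (reward/time × left/right) default to 9.76° × 2.46° boxes
whose centres lie at a radial eccentricity of exactly 6.93° from the screen
centre.  Only the eccentricity of the attribute centres is determined by
the task description; the split between horizontal and vertical offset is
not, so the layout takes a configurable elevation angle (default 40° above/
below the horizontal meridian — the smallest round value at which all four
boxes fit on screen with clear separation, reward above time on each side).
Whether the eccentricity applies radially or horizontally was also open;
it is implemented radially and is configurable.  Points outside every AOI
are labelled `none`, never clipped; AOI boxes are closed (edge points count
as inside, with a 1e-9 px tolerance for roundoff).

Trial timing: a 6 s decision window and a uniform 4–8 s inter-trial jitter.
Unused decision time is appended to the trial-end fixation, so total trial
duration is decision window + jitter regardless of RT — the analytic mean
is exactly 12 s.  Block plans alternate conditions (A-B-A-B from a
counterbalanced start), randomise trial order within block, assign the SIR
side to half the items, and mirror the sides in blocks 3/4.

## Synthetic-data generator

The generator encodes the study conditions the analyses are calibrated
against; its defaults are fixed, not tuning knobs.

* **Sample**: 31 participants × 108 trials (27 items × 2 conditions × 2
  blocks).
* **Items**: 27 SIR/LLR/delay triples whose implied equivalence rates
  k* = (LLR/SIR − 1)/D are jittered log-spaced over ~3 orders of magnitude
  (2.5e-4 to 0.25 per day), with LLR/SIR premia kept in the realistic
  1.1–2.5× range by pairing high rates with short delays, as the standard
  menu does.  The standard menu itself is not printed in the task
  description, so the generated bank is configurable and a published menu
  can be loaded from CSV.
* **Choices**: hyperbolic-softmax with group distributions
  ln k ~ N(−5.27, 1.2²) per day (centred on the study's delay-condition
  group mean), premium ~ N(−0.43, 0.55²) (the study's group effect with a
  between-subject SD chosen to give realistic person-to-person variability),
  inverse temperature lognormal(−0.7, 0.4²) on the currency scale of the
  menu.  The likelihood link (logistic in the SV difference) is the
  package's choice; the study does not state its own.
* **RTs**: lognormal with sdlog 0.30 (within-participant skewness ≈ 0.9)
  and meanlog 0.77/0.91 s for delay/date, matching the reported condition
  means (2.26 vs 2.59 s); draws beyond 6 s are timeouts with missing
  choices.
* **Gaze**: per trial a fixation period on the central cross followed by a
  decision period generated as a Markov chain over the four AOIs with
  condition-specific transition weights and gamma dwell times.  The date
  profile has more time–time (horizontal) transitions (weight 1.8 vs 0.7)
  and longer time dwell (380 vs 280 ms), the delay profile relatively more
  vertical transitions — the qualitative oculomotor signature of date
  framing.  These magnitudes were set so that trial validity (all four
  AOIs fixated, answered in time) lands near the realistic ~70–80% per
  condition.  A constant per-trial drift offset (SD 25 px), Gaussian sample
  noise (SD 6 px) and blink runs (1.08% of samples, 80–250 ms) are added;
  blinks carry no position samples.  Default sampling rate 1000 Hz,
  reducible (tests use 250–500 Hz).

What the generator does **not** emulate: saccade kinematics (positions jump
between AOI centres), within-AOI refixations (the transition chain has a
zero diagonal, so within-AOI saccade counts are near zero on synthetic
sessions although the pipeline measures them), smooth pursuit, pupil size,
item-level RT dependencies, learning/fatigue across blocks, and any
dependence of gaze on the upcoming choice.  Passing pipeline-recovery tests therefore shows the
measures recover the transition/dwell structure they target, not that the
fixation detector would match a proprietary event parser on real recordings.

## Hierarchical discounting model

Participant-level parameters (lnk_delay, premium, log inverse temperature,
plus logit β for the quasi-hyperbolic form) get normal group distributions.
Priors are weakly informative: group means N(−5, 3) on ln k (covering
roughly e−9 to e−1 per day), N(0, 1) on the premium (no sign preference),
N(0, 2) on log inverse temperature, N(2, 1.5) on logit β; group SDs
half-normal(2).  Estimation is entirely in ln k space.  The quasi-
hyperbolic form uses A·β·δ^D with D in days and β applied for D > 0,
parameterised as δ = exp(−exp(lnk)) so the premium structure carries over.

The sampler is an adaptive Metropolis-within-Gibbs scheme.  Internally it
works in (lnk_delay, lnk_date) coordinates, in which the likelihood
separates across condition blocks and coordinate-wise random-walk updates
mix well; the hierarchy stays on (lnk_delay, premium).  Per recorded draw
it runs 5 sweeps of: vectorised per-participant coordinate updates (target
acceptance 0.44, per-participant step adaptation during warmup), conjugate
Gibbs draws for the group means, and random-walk updates on the log group
SDs (half-normal prior, log-Jacobian included).  Defaults: 4 chains ×
1000 warmup + 1000 draws, which keeps split-R̂ of all monitored parameters
at or below 1.01 on synthetic 31-participant data; a `ConvergenceWarning`
carries the offending R̂ values otherwise.  All-one-sided choosers have
unbounded MLEs but finite posteriors under the hierarchy (tested).

Point estimates are posterior means; intervals are 95% highest-density
intervals computed as the shortest sorted-sample window (with a
multimodality warning when a histogram shows two well-separated peaks,
since a single interval then misleads).

**LOO.** Model comparison uses PSIS-LOO on the pointwise trial
log-likelihoods (arviz's Pareto-smoothed importance sampling).  Trials a
model predicts almost deterministically have near-constant log-likelihood
across draws; their importance weights are constant and the Pareto tail
fit degenerates even though their LOO value is exact, so such rows are
evaluated directly and excluded from the k diagnostics.  A warning is
raised when >10% of remaining Pareto-k exceed 0.7 or when the top elpd
difference is within 2 SE.

**Date premium.** The group-level premium summary is a BEST-style Bayesian
paired-difference model on the per-participant point estimates: Student-t
likelihood with broad priors (location N(mean, 1000·SD), scale uniform on
log over ±3 decades around the sample SD, ν−1 exponential with mean 29),
sampled with emcee.  Reported: posterior mean, 95% HDI, P(mean < 0).

**Screening.** The per-annum screening interval uses k_annum = 365·k_day —
simple proportional scaling; refitting in annual units would give slightly
different posteriors but the rule is a coarse gate.  Exclusion triggers
when the interval lies entirely below 0, includes 0, or lies entirely
above 2.

No numerical equivalence with any particular published point estimates is
claimed: the original estimation code, priors and likelihood link are not
public, so synthetic-recovery calibration (rank correlation of recovered
rates, HDI coverage of the generating premium) is the validation standard.

## Eye-tracking pipeline

Per trial: (1) drift correction constants (dx, dy) = cross − mean valid
gaze over the last 4 s of the pre-trial fixation period are added to all
decision samples (trials with <100 ms valid window data are flagged
uncorrectable); (2) I-VT fixation detection at a 30°/s velocity threshold,
50 ms minimum duration, 5-sample moving-average smoothing, 25 ms trimmed
around blinks — standard equivalents for a proprietary parser's defaults,
all config-exposed; (3) fixation centroids are assigned to closed AOI
boxes; (4) a change of fixated AOI counts as one between-AOI saccade,
classified horizontal-reward, horizontal-time, vertical-left/right (same
side) or diagonal.  `none` fixations are transparent for transition
counting by default (a chain-breaking mode is available); diagonal
transitions enter neither V nor H in the Payne index.  Within-AOI saccades
are counted as consecutive same-AOI fixations, the fixation-based reading
of an ambiguous definition.

Validity: a trial is valid iff answered within the 6 s window, drift-
correctable, and all four AOIs were fixated at least once; a participant is
excluded from gaze analyses when more than 20 trials are invalid in either
condition.  Data quality: blink loss is the percentage of invalid
decision-period samples; accuracy/precision combine per-axis mean/SD
deviations from the cross euclideanly, in degrees.  Outlier trimming
removes values beyond 2.5 SDs of the sample mean in a single pass.

## Statistical layer

All within-subject factors here have two levels, so every rm-ANOVA effect
is a 1-df contrast: F equals the squared paired t of per-participant
contrast scores and partial η² = F/(F + df_error).  This is exact (verified
against an independent implementation) and needs no sphericity correction.
g_av is the Hedges-corrected mean difference over the average of the two
condition SDs.  The skewed-RT robustness check is a log-transform followed
by the same paired t, not a nonparametric test.

The mixed-effects logistic choice model (LLR choice on effect-coded
condition, absolute Δreward, Δtime — z-scored — and their interactions,
participant random intercept) is fitted by maximum likelihood with 15-node
Gauss–Hermite quadrature and an analytic gradient; standard errors come
from the finite-difference observed information and Wald z p-values (the
convention of standard GLMM software).  Two deterministic starts (moderate
and near-zero random-effect SD) guard against stalling on the flat σ→0
boundary; apparent separation triggers a weakly L2-penalised refit with a
warning.  Whether the study's Δreward/Δtime were absolute or signed is
ambiguous in its description; absolute is the default with a flag.

The power analysis inverts the noncentral-t power function (smallest N
whose one-sided paired-t power reaches the target).

## fMRI design

Canonical double-gamma HRF (peak 6, undershoot 16, ratio 6).  Condition
boxcars run from trial onset to the response, are built on a microtime grid
of 16 bins per TR (TR 2.5 s), convolved, and sampled at TRs.  Modulator
values are demeaned within condition; modulated columns are Gram–Schmidt
orthogonalised against the unmodulated column and earlier modulators of the
same condition (serial, in entry order — so with two objective modulators
the second-entered explains only its unique variance, and both entry orders
are available).  Unanswered trials produce no event.  The 128-s high-pass
filter projects out a discrete-cosine basis (periods above cutoff,
including the constant).  Verification is by OLS recovery of known
coefficients from synthetic BOLD at SNR ≈ 1 on ~500-scan runs.

## Problem sizes used in verification

The test suite and acceptance script run at the study's scale where the
quantity depends on it (31 participants × 108 trials for recovery; 20
replicate fits at 2 chains × 400 warmup + 400 draws for premium-coverage
calibration; 2000-rep null simulations for type-I calibration; 250 Hz gaze
for pipeline tests) and at reduced scale elsewhere; the acceptance script's
single full fit uses the default 4 × (1000 + 1000) sampler settings.

## Known limitations

* The sampler is tailored to this model family (conditionally independent
  participants, normal hierarchy); it is not a general-purpose MCMC engine.
* Wald inference in the mixed model is mildly anticonservative below ~15
  participants; the type-I calibration holds at the study's sample sizes.
* Posterior shrinkage toward the group mean is guaranteed only for
  participants with two-sided choice behaviour; one-sided responders have
  skewed, prior-truncated posteriors whose means can sit beyond their
  (unbounded) MLE distance.
* The fixation detector is a generic I-VT; no claim is made that it
  reproduces proprietary event parsers sample-for-sample.
* The date condition is modelled through a condition-specific discount
  rate only; the immediate option is taken at D = 0 in both framings.
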