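# Methods

This note documents the models, estimators, and design choices behind `pitgimme`: what
is simulated, how the euSEM is estimated and searched, which knobs matter, and what the
synthetic benchmarks do and do not demonstrate.

## Task simulation

**Instrumental phase.** Each 180-s session is a discrete 1-s clock.  In window *w* the
agent makes the correct avoidance press with probability interpolating linearly from
`learn_start_p` to `learn_end_p` across the session.  A window without a press — and
not covered by a deferral — emits one attack at the window's end; a press defers the
next scheduled attack by 3 s (at most one press per window counts).  Degenerate agents
bracket the behavior exactly: an always-pressing agent suffers 0 attacks, a
never-pressing agent exactly one attack per second.  Any monotone learning curve
reproduces the first-vs-last-bin decline the learning check measures; linear
interpolation is the simplest such curve.

**Pavlovian phase.** 45 trials (5 stimulus-outcome pairings × 9), each a 4-s stimulus,
1-s outcome, and an inter-trial interval drawn uniformly from {7, 9, 11} s; trial order
is a seeded permutation, so marginal counts are exact for every seed.

**Transfer phase.** 60 extinction trials (5 stimuli × 12): pre-stimulus fixation, 4-s
stimulus, then a recharge screen drawn uniformly from [2, 12] s during which responding
is disallowed.  The fixation duration is not dictated by the task timing; it defaults
to 4 s — equal to the stimulus window — so pre/stim response rates are directly
comparable.  The transfer agent is an inhomogeneous Poisson process per response
channel: baseline rate everywhere, × `specific_gain` for the congruent response under
CS1/CS2, × `general_gain` for both responses under CS3.  Multiplicative gains keep the
null agent exactly exchangeable across stimuli and intervals, which the type-I
calibration tests exploit.

**BOLD generation.** Subject *i*'s 5-ROI series follows the euSEM exactly: at each scan
`y_t = (I − A − Σ_k u_{tk} Τ_k)^{-1}(Φ y_{t−1} + Γ u_t + ζ_t)` with
`ζ_t ~ N(0, diag(σ²))`.  Stimulus onsets are placed as impulses on a 16×-upsampled
microtime grid, convolved with the subject's canonical two-gamma HRF (the gamma shape
is `delay/dispersion + 1`, so `peak_delay_s` is the exact mode), and decimated to the
TR grid — this avoids ±1-TR onset aliasing.  Fifty burn-in scans with `u = 0` are
discarded so the series starts at stationarity; with `u ≡ 0` the sample covariance
matches the closed-form VAR stationary covariance (verified at T = 5000).  Subject
matrices carry the *binary* onset columns; the analysis side must re-estimate the HRF,
which is exactly the estimation problem the method is built for.

**Random streams.** Every draw comes from a named `SeedSequence` substream
(`seed, purpose, subject`), so adding subjects or stages never perturbs existing data,
and identical configurations are byte-identical end to end.

## Behavioral statistics

Attacks are binned in 30-s bins (partial trailing bins dropped with a warning; an
attack at exactly the covered span's end belongs to the last bin, since the generator
emits window-end onsets).  The learning check is a classical paired t on
first-minus-last bin counts; constant nonzero differences are surfaced as a distinct
degenerate-variance condition instead of ±∞.

The three-way fully within-subject ANOVA (stimulus × interval × response) is computed
from orthonormal within-subject contrasts: each effect's per-subject cell means are
projected onto Kronecker products of centered orthonormal bases, giving the classical
univariate F with its effect-specific error term (cross-checked against statsmodels
`AnovaRM` and an independent mean-based sums-of-squares oracle), the Greenhouse-Geisser
epsilon `tr(S)²/(df₁·tr(S²))` from the contrast covariance (the fractional corrected
dfs commonly reported imply such a correction; GG is the usual default), and exact sums
of squares for generalized eta squared
`η²g = SS_effect / (SS_effect + SS_subjects + ΣSS_error)`.

Pairwise probes are paired t tests over a configurable family; the default family is,
per conditioned stimulus, the four contrasts {R1 pre-vs-stim, R2 pre-vs-stim, R1-vs-R2
within pre, R1-vs-R2 within stim}, Bonferroni-corrected over all 20 — covering every
contrast the transfer analysis reports.

## ROI extraction

Spheres are 5 mm radius ("10 mm diameter"; some sphere tools read such numbers as
radii, so the radius is a parameter).  A voxel belongs to the sphere iff its center is
within the radius of the sphere center, boundary ties included — deterministic and
matching common mask tools.  An onset at time *t* belongs to TR bin ⌊t/TR⌋.  The
pipeline consumes any externally produced (e.g. residualized) series; synthetic data
need no nuisance regression by construction.  Only the transfer-phase series enters the
connectivity analysis by default.

## sFIR HRF estimation

The smoothed FIR solves `min_h ‖y − Xh‖² + λ‖Dh‖²` with X the lagged-onset Toeplitz
design (16 TR = 32 s window by default), D the second-difference operator, and an
unpenalized intercept absorbing the baseline.  λ is chosen by generalized
cross-validation over a 25-point log grid (10⁻²–10⁴) by default; λ = 0 reduces to plain
FIR, λ → ∞ to a straight line (‖Dh‖ is non-increasing in λ).  Noiseless data are
recovered exactly as λ → 0.  One HRF per subject per input is estimated once — from
the average of the five ROI series by default, since a per-target-ROI choice is
circular before the model search has selected any direct effects — and held fixed
through the search (a `per_roi:<name>` mode is available).

A scale indeterminacy is inherent: only the product of HRF amplitude and the direct
effect γ is identified, so γ estimates are on the scale of the *estimated* impulse
response.  Path presence, significance, and the A/Φ weights are unaffected; recovery
benchmarks therefore score the input-driven paths by presence, not by β error.

## euSEM estimation

On the lagged data representation, lagged series and convolved inputs are
predetermined; bilinear terms are products of the centered convolved input with the
centered source series, treated as fixed regressors (centering reduces collinearity
with the direct effect).  Recursive (acyclic) contemporaneous structures are estimated
equation by equation — exactly ML under diagonal noise.  Cyclic structures go through
full-information ML with the `log|det(I − A)|` Jacobian, after an explicit
identification check: every equation inside a contemporaneous cycle must exclude at
least as many predetermined system variables (instruments) as it includes endogenous
predictors, otherwise an identification error names the cycle.  Degrees-of-freedom
bookkeeping treats input columns as fixed regressors, not modeled variables.

**Fit indices** come from the covariance structure over
[lagged ROIs, convolved inputs, in-model bilinear terms, ROIs] with the exogenous block
saturated: `χ² = (N−1)·F_ML` against the saturated model, and an independence baseline
with free variances for CFI/NNFI (chosen deliberately: the search's AR-only "null
model" is a different object).  Constant columns are dropped from the observed vector.
The 2-of-4 excellent-fit rule uses CFI > .95, NNFI > .95, RMSEA < .05, SRMR < .05.

**Modification indices** are proper SEM score tests on the conditional likelihood
`y|x ~ N(Πx, Ω)` with `Π = (I−A)⁻¹C` and `Ω = (I−A)⁻¹Ψ(I−A)⁻ᵀ`:
`MI = U² / (I_nn − I_no I_oo⁻¹ I_on)` from analytic derivatives and the expected
information.  This matters: a naive equation-wise regression score would flag the
mirror of an already-included contemporaneous path (its partial correlation with the
equation residual stays large), whereas the model-implied covariance already reproduces
that element, so the proper score is ≈ 0.  Candidates referencing constant columns get
MI = 0.

## Model search

Group stage: starting from the 5 AR paths, the candidate (over all absent
contemporaneous, lagged, direct, and bilinear edges — classes toggleable, since
bilinear candidates inflate the space) significant for the most subjects is added,
provided the count reaches ⌈0.75·n⌉; ties break on summed MI, then a lexicographic edge
key, making the search fully deterministic and auditable.  Selection continues until no
candidate reaches the cutoff; group paths are then pruned (same count rule on Wald
tests, worst first) to a fixed point, bounded at 50 iterations with a flagged audit
entry.  Individual stage: per subject, the largest family-wise-significant MI is added
until none remain or the cap hits; individual (never group) paths are then pruned at
α = 0.05.

MI significance during selection uses a Bonferroni threshold over the candidate set by
default.  The calibration targets of this package are stated family-wise (e.g. a
group-truth subject should gain zero individual paths in ≈ 95% of replicates), and
with ~90 candidates a raw per-candidate α would admit several spurious individual paths
per subject on otherwise well-fitted data; `mi_correction="none"` restores raw-α
behavior.  "75% of the sample" is implemented as ⌈0.75·n⌉ (9 of 11; 8 of 10); lowering
the cutoff toward 51% raises power for weak task effects at the cost of specificity,
and both are exposed in `SearchConfig`.

**Recovery scoring** pools counts over the per-subject final maps (group ∪ individual
paths each) against the shared generating network; presence is judged up to direction
for contemporaneous/lagged pairs, with directed agreement reported separately, and
precision is 1 by convention when nothing is claimed.

## Benchmarks and problem sizes

The recovery benchmark simulates 10 subjects × 200 scans from a 5-node truth with
5 AR paths (0.5) and 4 cross paths (0.5–0.6; three contemporaneous, one lagged —
the path classes of the group map in the motivating task) at unit noise, runs the full
search, and averages pooled presence precision/recall over 20 replicates; the
study-scale preset (`paper_like`) uses 11 subjects × 540 scans and adds a direct
specific-input → left-putamen effect, which the group search recovers.  Null
calibration uses 50 AR-only replicates; HRF peak recovery uses 100 replicates at SNR 1
with true peaks 4–8 s; behavioral calibration uses 500 simulated 11-subject
experiments.  These sizes keep each check to seconds-to-minutes while leaving the
binomial error of every calibration far from its acceptance margin.

## What the synthetic tests do not show

The generator produces exactly euSEM dynamics with white diagonal noise, canonical-
family HRFs, and no scanner drift, motion, physiological noise, or spatial correlation;
passing recovery benchmarks therefore demonstrates correctness of the estimator and
search under the model's own assumptions, not robustness to preprocessing failures or
model misspecification on real BOLD data.  Lag-1 dynamics only (no higher-order lags),
no latent variables, no non-diagonal noise covariance, and no subgrouping of
participants.  The per-stimulus response ranges reported for real participants are not
used to constrain the synthetic agent.

## Numerical notes

* OLS standard errors use the n−k denominator; z = β/SE with normal two-sided p
  (SEM convention); likelihoods use ML variance estimates.
* FIML accepts a BFGS stop with an essentially zero gradient as converged; standard
  errors come from a central-difference Hessian of the concentrated likelihood.
* Ties at a sphere boundary (distance exactly = radius) are included; ANOVA sums of
  squares below a relative tolerance of ~1e-10 are treated as exact zeros (constant
  tables give F = 0, not 0/0).
* An attack at exactly the session end is binned into the last bin.
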