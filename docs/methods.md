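# Methods

This note records the modelling conventions, defaults, and numerical
choices the package makes, and what its synthetic-data tests do and do not
establish about real data.

## Stimulus design

A roving oddball session is a concatenation of trains of identical
stimuli. Train lengths are i.i.d. uniform on {3, …, 7} presentations;
stimulus intensity alternates between consecutive trains; all events sit
exactly one inter-stimulus interval (default 2.0 s) apart, across train
boundaries included. The first presentation of each train is the deviant
and the third the designated standard, so a standard exists in every
train; with 158 trains the expected number of repeated (non-deviant)
stimuli is 4 × 158 = 632 with SD √(158 × 2) ≈ 17.8. "3 to 7 repetitions"
is read as total presentations per train including the deviant — the only
reading under which every train contains a third repetition and the
session totals come out near the published figures.

Design regressors sample a canonical double-gamma HRF (delay parameters
6 s and 16 s, unit dispersions, undershoot ratio 6, 32 s support,
normalised to peak 1; the gamma with delay parameter 6 has its mode near
5 s) at volume-onset times. The all-conditions regressor weights every
deviant and standard +1; the parametric modulator weights deviants +1 and
standards −1; fillers enter neither. Events beyond the run end are dropped
with a logged warning. No slice-timing offsets are modelled.

The detection-threshold staircase is one-up/three-down: intensity rises
after any miss and falls after three consecutive hits. The step halves
after every second reversal (the reduction factor is a package choice; the
procedure description leaves it open), the default starting step is 20% of
the starting intensity, intensities are floored at 0.1 mA (clipping
logged), and the run ends at the 8th reversal with the threshold the mean
of the reversal intensities. The rule's asymptotic convergence point is
the intensity detected with probability (1/2)^{1/3} ≈ 0.794; with 8
reversals and a halving schedule the mean threshold lands within a few
percent of that point (tested against a logistic observer).

## Generative model

Neuronal dynamics are the bilinear equation dx/dt = (A + Σ u_k B_k)x + Cu
in plain additive Hz. The A diagonal is strictly negative, and stability
of A + Σ u_k B_k is required (and checked) for every attained input value;
violations raise an error naming the offending eigenvalue. The log-scaled
self-connection convention used by some DCM implementations is *not*
adopted: couplings here are plain rates, matching how the modulations are
reported in Hz.

Haemodynamics are the standard four-state balloon–windkessel cascade per
region: signal decay κ = 0.64 s⁻¹, autoregulation γ = 0.32 s⁻¹, transit
time τ = 2.0 s, stiffness α = 0.32, resting extraction E₀ = 0.4, resting
volume fraction V₀ = 0.04, with classic observation coefficients
k₁ = 7E₀, k₂ = 2, k₃ = 2E₀ − 0.2 (1.5 T lineage), reported in percent
signal change. Flow, volume and deoxyhaemoglobin are integrated in log
space, which guarantees their positivity and tames stiffness; the
integrator is fixed-step classical Runge–Kutta at TR/16 by default.

Experimental inputs are short boxcars of fixed duration TR/16 s whose
onsets are binned to a TR/16 microtime grid (the binning SPM uses). Tying
stick width to the integration step instead would make the response scale
with the step and defeat step-size convergence checks; with microtime
binning, halving the step changes simulated BOLD by well under 1e-4 %
signal. The all-conditions stream drives the first region (TH in the
study network); the ±1 modulator acts through the B matrices. Observation
noise is i.i.d. Gaussian added at volume samples; autocorrelated noise is
out of scope.

Multi-voxel regions are summarised by the principal eigenvariate: the
first left singular vector scaled by its singular value over √(n voxels),
sign-aligned with the mean voxel series.

## Inversion

`laplace_fit` maximises the Laplace free energy of y = g(θ) + ε with
Gaussian parameter priors and one log noise precision λ per region
(noise covariance exp(−λ)·I within a region; hyperprior N(0, 16) by
default, variance 0 fixes the noise). The free energy uses the standard
cancelled form with Σ_q = H⁻¹, which is exact for linear g with known
noise — the conjugate linear-Gaussian tests exploit this, matching the
closed-form posterior to 1e-6 and the analytic evidence to 1e-3 nats.

F is treated as a function of the evaluation point: the Jacobian (forward
finite differences, relative step 1e-4, batched through the integrator),
the optimised λ, and the Laplace covariance are all recomputed at every
candidate, so accepted Gauss–Newton steps can never decrease F and the
accepted-step trace is monotone by construction. Levenberg–Marquardt
damping scales the identity by the mean Hessian diagonal, multiplying by 8
on rejection (capped) and relaxing on acceptance; a candidate whose
integration diverges counts as a rejection. λ is updated by coordinate
Newton with backtracking on its exact objective (including the ln|H(λ)|
term; the posterior-entropy term for λ uses the residual power without the
Jacobian trace — a small, documented approximation). Convergence is
declared after four consecutive accepted steps with |ΔF| < 0.01 nats, or
when no ascent direction survives heavy damping; 128 iterations is the
default cap, and non-convergence is flagged on the returned posterior.

Parameters with zero prior variance are projected out (eigendecomposition
of the prior covariance) and returned with zero posterior variance at
their prior means. Timeseries are mean-centred per region before
inversion, and so is the model prediction — the stand-in for nuisance
regression of confounds. Default priors: A diagonal N(−0.5, 1/16),
off-diagonal A and all B entries N(0, 1/16), C entries N(0, 1); the prior
mean system is stable by construction. These are conventional shrinkage
choices, not reconstructions of any particular SPM version's priors.

## Model reduction and comparison

Evidence and posterior of any model with a shrunk prior follow from
Gaussian algebra on the full posterior/prior. Removal (prior mean and
variance zero) is handled as the exact analytic limit: the quadratic form
is restricted to the affine subspace with removed parameters pinned, never
via a small-ε variance, avoiding conditioning artifacts. Reduction to the
identity prior gives Δ = 0; widening raises an error. On linear-Gaussian
problems the computed Δ log evidence matches direct conjugate evidence
differences to 1e-6 nats, including chains of nested reductions.

Model spaces are built from named families of parameters switched on/off
together; model ids are the binary encoding of family states (bit i =
family i), so 8 families give models 0–255 with 255 the full model. The
shipped default family structure for the 5-region network (thalamocortical
/ forward / backward A, the same split of B, self-B, and driving C) is
illustrative — the encoding pins the indexing, not the grouping — and
fully configurable. A self-connections are never switchable (every model
keeps self-decay).

Fixed-effects pooling sums log evidence over subjects; posterior model
probabilities are the max-subtracted softmax, and the Bayes factor is the
probability ratio of the two best models. Random-effects model selection
is out of scope.

## Group statistics

One-sample t-tests (two-sided, n − 1 d.f.) run over all modulatory
parameters with Benjamini–Hochberg FDR at q = 0.05 within that family of
25; Tukey-biweight regressions (c = 4.685 for 95% Gaussian efficiency,
MAD-based scale re-estimated each IRLS iteration, coefficient tolerance
1e-10) relate each of the 20 extrinsic modulations to difficulty ratings,
FDR-corrected within the 20, with the same battery repeated against
intensity-difference ratings as the null control. The slope's t uses
n − 2 d.f. Exactly collinear data short-circuit to the least-squares line
with unit weights (the MAD scale is zero there).

R² is reported as the squared correlation between fitted and observed
responses, *unweighted*. An R² weighted by the final biweight weights was
considered and rejected: the weights are by construction largest where the
fit is best, so a weighted R² systematically overstates the variance
explained (by ~5 percentage points in the cohort simulations) and no
longer estimates the population coupling the rating generator is
calibrated to. The robust weights are returned as outlier diagnostics.

## Synthetic cohorts

A cohort draws each subject's couplings from independent Gaussians about
configurable group means (default between-subject SD 0.1 Hz); draws
violating stability are rejected and redrawn (up to 100 attempts, logged),
and A self-connections are kept negative. The shipped 5-region group-mean
pattern — positive forward modulations up the TH→S1→AIC→MCC→MFG hierarchy,
a positive AIC→S1 backward modulation, positive (disinhibitory) TH/S1/AIC
self-modulations — reproduces the reported sign pattern only; magnitudes
are illustrative defaults. Observation noise is set per subject as the
noise-free signal SD divided by the configured SNR (default 2).

Difficulty ratings follow intercept + slope·(MFG→AIC modulation) + ε,
clipped to the 0–100 visual-analogue scale (clipping logged). The default
slope is −60 VAS/Hz around an intercept of 35 (the study's mean difficulty
level), and the residual SD is derived from the slope, the predictor's
population SD and a target population R² of 0.3804, so the coupling
strength is set by one interpretable number. Intensity-difference ratings
(mean 11, SD 19 VAS) are independent of connectivity — the null control.
At n = 25 the sample R² of the robust fit recovers the population value in
expectation to within Monte-Carlo error (the small-sample inflation of a
squared correlation at n = 25 is a few tenths of a percentage point).

Subject-level seeds derive deterministically from the master seed, making
the entire pipeline bit-reproducible.

## Problem sizes in the shipped tests

The heavy property suites run at desk scale by design. Parameter recovery
uses 2-region models with two independently driven regions plus an
independent ±1 modulator — a design chosen because a single driving stream
leaves the modulations of the second region's outgoing connections nearly
unidentifiable at any feasible run length — at 300 volumes, SNR 2, 10
seeds (pooled recovery correlation ≥ 0.9). End-to-end model recovery uses
2-region cohorts of 3 subjects, 300 volumes at SNR 8: shortening runs and
shrinking the cohort from the study's 1109 volumes × 25 subjects removes
most of the pooled evidence, and the higher SNR restores the per-subject
information so that family-level selection operates in a comparable
regime. Both suites use integration at TR/8 (convergence at this step is
verified separately against TR/16 and TR/32).

## What the synthetic tests do not show

The generator emulates the design's statistical skeleton: event timing,
train statistics, Gaussian between-subject variation, Gaussian observation
noise, and a linear rating–connectivity coupling. It does not emulate head
motion, physiological (cardiac/respiratory) noise, autocorrelated scanner
noise, susceptibility distortion, regional haemodynamic variability,
subject exclusion, or model mismatch between generator and fitter (the
inversion uses the same forward model that generated the data). Passing
recovery tests therefore demonstrate internal consistency of the
estimators under the assumed model, not robustness to the many ways real
fMRI violates it. The published real-data quantities that depend on the
raw recordings (the winning-model posterior probability, specific
parameter magnitudes, activation tables) are not reproduction targets.
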