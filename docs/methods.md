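# Methods

## Scope

`gnrhinfo` quantifies information transfer through GnRH receptor
signaling at single-cell resolution.  It combines:

1. **NSB Bayesian entropy estimation** and the mutual-information (MI)
   quantities built on it — marginal, conditional, joint (2-D),
   trajectory (3-time-point) MI and the chain-rule "additional
   information" of a second response;
2. a **hybrid deterministic/stochastic model** of GnRH → Ca²⁺ →
   calmodulin/calcineurin → NFAT nuclear translocation, in which the two
   effector totals (GnRHR and calmodulin) fluctuate as exponentiated
   Ornstein–Uhlenbeck (OU) processes with a controllable fluctuation
   lifetime (FL);
3. **pulse-sensing analyses** (during/after a 15-min pulse; two pulses
   separated by 135 min);
4. **synthetic single-cell data generators** emulating fixed-cell
   snapshot cohorts, tracked live-cell cohorts and nuclei-centroid frame
   stacks; and
5. an **MCMC nucleus tracker** pairing centroids between frames with an
   exponential-distance likelihood.

## Entropy and mutual information

Continuous readouts are discretized into 30 equal-width bins spanning
the pooled observed range (pooled across stimulus levels, so H(Z) and
H(Z|S) share one alphabet).  Ties on a bin edge go to the upper bin; the
global maximum joins the top bin; a zero-range (constant) readout
collapses to one bin and zero entropy rather than erroring.

Entropies are estimated with the Nemenman–Shafee–Bialek (NSB) estimator:
a mixture of symmetric Dirichlet priors weighted so the induced prior on
the entropy is nearly flat.  The hyperparameter integral is taken over
ξ = E[S|β] ∈ (0, ln K) on a 1000-point midpoint grid (a convergence test
doubles the grid); β(ξ) is recovered by monotone interpolation plus
vectorised Newton steps; log-evidence weights are stabilised by
max-subtraction; posterior entropy moments use the Wolpert–Wolf closed
forms.  Entropies are reported in bits with the posterior standard
deviation.  A brute-force adaptive-quadrature implementation, coded
independently in the test suite, agrees to ≤ 1e-3 bits on randomized
count tables (K ≤ 30, n ≤ 200).

Derived quantities:

* I(Z;S) = H(Z) − H(Z|S), with H(Z|S) the level-weighted NSB entropy;
* joint/trajectory MI discretize each response dimension separately
  (default 30 bins per dimension; note 30³ cells are very sparse at
  n ≈ 10³, so trajectory analyses default to 8 bins per dimension);
* I(Z₁;Z₂) = H(Z₁) + H(Z₂) − H(Z₁,Z₂) on the product alphabet;
* I(Z₂;S|Z₁) = I(Z₂;S) − I(Z₁;Z₂) + I(Z₁;Z₂|S) (chain rule).

Standard deviations of derived quantities combine the constituent
posterior sds in quadrature, ignoring their covariance — an
approximation, stated as such.  Estimates are reported unclamped;
slightly negative values are legitimate estimator noise and clamping
would bias sweep averages.  A plug-in (maximum-likelihood) estimator is
available via `method="plugin"`; the exact chain-rule identity and the
data-processing inequality hold exactly only for plug-in estimates and
are tested in that mode.

## The deterministic cascade

Six states: receptor occupancy ρ, cytoplasmic Ca²⁺ C, active
calcineurin P, and three NFAT pools (cytoplasmic phosphorylated NF_cp,
cytoplasmic dephosphorylated NF_cd, nuclear NF_n).  Rate laws are
mass-action with one Hill nonlinearity for Ca²⁺/calmodulin activation of
calcineurin (see `gnrhinfo.model` for the equations).  The readout is
the NFAT nuclear fraction NF_n/(NF_cp+NF_cd+NF_n), matching the
NFAT1c-EFP translocation reporter.  Receptor desensitization,
internalization, the ERK arm and transcription are deliberately outside
the model.

At zero ligand the system is linear given the basal Hill activity, so
the unstimulated steady state is computed in closed form and used as the
initial condition (a long zero-ligand relaxation reproduces it; tested).

**Integration.** Classical RK4 on sub-steps bounded by 0.5 / (fastest
linearised rate), vectorised across cells, with breakpoints at every
protocol boundary and effector-path update so piecewise-constant inputs
are honoured exactly.  RK4 preserves the linear NFAT conservation law to
machine precision; step-halving convergence (≤ 1e-4 on the nuclear
fraction) and agreement with an adaptive LSODA reference are asserted in
tests.  The vectorised fixed-step core is what makes 1000-cell × 4-dose
× multi-FL sweeps run in minutes on one CPU; the sweep sizes used in the
acceptance analyses (1000 cells per concentration, the full
{10,100,1000,10000}-min FL grid) are the study's own design points.

**Calibration.** The source model's rate constants are not published, so
the defaults here were fixed by numerical search against the observable
constraints the data impose, and then frozen:

* unstimulated nuclear fraction 0.475 (inside the live-cell 0.40–0.55
  baseline gate);
* a 1e-7 M step reaches 90% of its maximum at ≈16 min (within the
  15–60-min window the live-cell population traces show);
* after washout of a 15-min pulse the nuclear fraction returns to within
  10% of baseline well inside 120 min;
* peak and AUC responses strictly increase over 0 < 1e-11 < 1e-9 <
  1e-7 M;
* during/after window symmetry: the receptor off-rate (0.085/min) is
  matched to the on-rate at 1e-7 M (ρ rise time ≈10 min) so the AUC of
  the response in the 15 min after the pulse approximately equals the
  AUC during it — the regime in which sensing after the pulse is as
  informative as sensing during it;
* fast downstream kinetics (Ca²⁺, calcineurin and NFAT exchange
  relaxation times ≈1–3 min), so that effector fluctuations pass to the
  readout with little low-pass filtering and the population
  nuclear-fraction mean and variance at any time are nearly independent
  of FL at matched cv — the study's central control.

The slow step is receptor occupancy itself (k_on·L + k_off ≈ 0.1/min at
saturating ligand), which is *not* modulated by either fluctuating
effector; this is what reconciles the slow macroscopic rise with
FL-invariant population variance.

## Stochastic effector layer

GnRHR and calmodulin totals follow exponentiated OU processes: OU in log
space with autocorrelation time FL, exact discretization at 0.5-min
updates, stationary lognormal marginals with mean equal to the
deterministic totals and coefficient of variation cv.  Identifying FL
with the log-process autocorrelation time is the natural reading of
"fluctuation lifetime"; paths are piecewise-constant between updates so
the integrator sees exactly the sampled values.  Per-cell RNG substreams
are spawned from the run seed keyed by cell index, making populations
reproducible and order-independent.

The stationary variance is a calibration: `calibrate_cv` tunes a common
cv to a target coefficient of variation of the baseline-subtracted
pulse-1 maximum nuclear fraction at 1e-7 M (the spread live-cell
experiments constrain).  cv = 0.4 yields response CV ≈ 0.28 and is the
default for the pulse analyses; the OU layer itself defaults to
cv = 0.3, and the tracked-cohort generator uses 0.3, which keeps >90% of
cells inside the time-0 QC gate.

## Pulse analyses and response conventions

Windowed AUC responses are computed on the baseline-anchored trace —
NF(t) minus the cell's own pre-stimulus mean over the 10 min before
stimulation — mirroring how live-cell translocation responses are
referenced to pre-stimulus frames.  This matters quantitatively: raw
AUCs of adjacent windows share a common-mode static-baseline component
whose difference is an artificially clean dose channel, inflating the
additional information at high FL; anchoring removes it.  Two-pulse
responses Z₁/Z₂ are the raw maximum nuclear fraction per pulse window
(an anchored AUC variant over the first 15 min of each pulse is also
reported).

The two-pulse table reports the per-concentration MI between Z₁ and Z₂
pooled (n-weighted) over the four concentrations, I(Z₁;Z₂|S), as the
pulse-to-pulse predictability measure: it starts near 0 bits for
unstable effectors and rises monotonically with FL.  The pooled
unconditional I(Z₁;Z₂) is also emitted; note it has a dose-driven floor
(~0.5 bits) even at FL = 10 because both responses carry information
about the dose.

At FL = 10⁴ min our pulse-to-pulse MI plateaus near 2.2 bits.  In a pure
ODE + OU model the only within-cell scatter between the two pulses is
the OU decorrelation over the ≈195-min protocol span
(√(2(1−e^(−195/10⁴))) ≈ 0.20 of the cell-to-cell spread), which pins the
per-dose resolvability near 2.2 bits essentially independently of cv,
because MI is invariant under monotone response transformations.  A
model with additional intrinsic (molecular-number) noise — out of scope
here — would sit lower.

The protocol is 15-min pulse / 135-min interval / 60-min second pulse at
the same concentration (the Methods-text design; the figure-legend
variant with a 120-min interval and 30-min second pulse is expressible
through `PulseDesign`).  The transient translocation bump that washing
itself causes in wet experiments is not modeled.

## Synthetic data

The snapshot-cohort generator is a 4-parameter log-logistic population
dose-response (default log₁₀ EC₅₀ −8.24, Hill 1, basal 130 AFU ≈ the
assay background, amplitude 870 AFU) with per-cell lognormal basal and
amplitude factors (CV 0.3) and additive Gaussian readout noise, over 8
concentrations (0 and 1e-12…1e-6 M) — the regime in which MI lands well
below the 3-bit input entropy.  MI is invariant to the arbitrary
fluorescence scale (asserted).  The paired NFAT-NF-like channel shares
each cell's heterogeneity factors so joint-MI analyses see correlated
readouts.  The tracked-cohort generator wraps the hybrid model plus
additive measurement noise (default sd 0.01) and applies the time-0 QC
gate, removing cells with time-0 NF < 0.4 or > 0.55 — boundary values
are kept, per the strict inequalities of the stated rule.  The frame
generator provides Gaussian random-walk centroids with ground-truth
identities and optional births/deaths.

What the generators do *not* emulate: imaging artifacts, segmentation
errors, spatial context, phototoxicity/bleaching trends, and the
wash-induced Ca²⁺ transient.  Passing tests therefore demonstrate
correctness of the estimators and pipelines on data with the designed
statistical structure, not robustness to microscopy pathology.

## Tracker

Matching maximises Σ(−d/λ) − penalty·(#unmatched) over injective partial
matchings by Metropolis sampling (40% add / 20% remove / 40% rewire-or-
swap; 10⁴ iterations; greedy nearest-neighbour initialisation; best
state kept — MAP, not marginal assignment).  λ defaults to twice the
median nearest-neighbour displacement between consecutive frames
(self-scaling to frame rate); the per-unmatched penalty of 3 makes an
unmatched centroid as costly as a match at 3λ, allowing births and
deaths.  Exact agreement with brute-force enumeration on ≤6+6-point
instances and ≥99% correct links on ground-truth stacks are asserted.

## Numerical conventions and edge cases

* Time in minutes, ligand in molar, effector totals dimensionless
  (nominal 1); entropies/MI in bits.
* K = 1 alphabets: entropy exactly (0, 0).  Empty samples: error.
* Stimulus labels are canonically formatted strings; 0 and 0.0 are the
  same level.
* Seeds: every stochastic entry point takes an integer seed; derived
  seeds stay below 2³¹.

## Known limitations

* No receptor desensitization; no ERK arm; no intrinsic molecular
  noise (extrinsic effector fluctuations only, sampled independently
  for the two effectors).
* sd propagation ignores covariance between entropy posteriors.
* The NSB conditional quantities at K = 900 with n = 1000 per level are
  strongly shrunk; comparisons across conditions (the use made of them
  here) are more reliable than absolute values.
* The calibration reproduces the published simulation values for
  during/after-pulse sensing to within ±0.1 bit; the pulse-to-pulse MI
  at FL = 10⁴ plateaus ~0.3–0.4 bits above the published value for the
  structural reason given above.
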