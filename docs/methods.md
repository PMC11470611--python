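# Methods

This note documents the models, the numerical choices, and the limits of
what the synthetic experiments can show.  All quantities below are computed
by the package's tests or examples; none are copied in from elsewhere.

## Constitutive model

The strain energy is an isotropic neo-Hookean matrix term plus one
exponential fiber family,

    W = c/2 (I1 - 3) + k1/k2 [exp(k2 (I4 - 1)^2) - 1],

with c, k1 stress-like (kPa), k2 a dimensionless stiffening exponent, and
theta the fiber angle from the circumferential axis.  Incompressibility
fixes the radial stretch, and the plane-stress condition sigma_rr = 0
eliminates the hydrostatic pressure, leaving the two in-plane Cauchy
stresses as functions of (lambda_theta, lambda_z) alone.  Two deliberate
conventions:

- The axial fiber-stress term carries the chain-rule factor
  `lambda_z^2 sin^2(theta)`.  A published variant with `lambda_theta^2` in
  that slot is reachable via `cauchy_stresses(..., zz_fiber_factor="theta")`
  but breaks the identity between the analytic stresses and the stretch
  derivatives of W (the property suite verifies the identity to 1e-5
  relative over 200 random parameter/state draws, against central finite
  differences of W with the radial stretch eliminated).
- The fiber prefactor is `k1/k2`; the more common `k1/(2 k2)` is available
  via `split_prefactor=True`.  A fitted k1 absorbs the factor of two, so
  the choice does not affect predictions, only the reported k1.
- The fiber term is active only in tension (I4 >= 1).  On equibiaxial
  loading paths with stretch >= 1 the switch is moot.

### Identifiability on equibiaxial paths

On a strictly equibiaxial path I4 = lambda^2 regardless of theta; the angle
enters each stress only through the constant weights cos^2(theta) /
sin^2(theta).  Hence a single direction's curve identifies c, k2 and the
*product* of k1 with its angular weight — not k1 and theta separately.
Consequences:

- Joint fitting (both directions, one parameter set) identifies all four
  parameters; the recovery experiment (noiseless curves from known
  parameters, starting point perturbed by +/-20%) recovers them to machine
  precision, and with 2% multiplicative noise the median recovered c over
  10 replicates stays within 1% of truth.
- Per-direction fitting (two independent parameter sets, the convention
  behind direction-specific published parameter tables) converges onto the
  (k1, theta) ridge: the fitted curve is exact but the split between k1 and
  theta depends on the starting point.  `fit_holzapfel(..., fix_theta=True)`
  freezes theta and fits the identified triple (c, k1, k2).

### Fitting machinery

Residual minimisation uses trust-region Levenberg–Marquardt
(`scipy.optimize.least_squares`, method `trf`) with bounds c > 0, k1 >= 0,
k2 in (0, 1e3], theta in [0, pi]; inside the optimizer the fiber exponent
is clipped at 60 so wild intermediate iterates produce large finite
residuals instead of overflow (the public energy/stress functions raise
beyond exponent 700).  The default start is scale-aware: c = half the
toe-region secant modulus (stretch 1..1.4), k1 = c, k2 = 1, theta = 45 deg.
Non-convergence is reported as a flag on the result, not an exception.

## NARX surrogate and Bayesian-regularized training

Architecture: one exogenous input (strain), 5 tansig hidden neurons, linear
output, tapped delays {1,2} on both input and feedback — 5*(2+2)+5+5+1 = 31
adjustable parameters.  A literal undelayed-input variant (input delays
{0}, 26 parameters) is configurable but is not the default because only the
{1,2}/{1,2} configuration matches the stated parameter count.

Training is open-loop (series-parallel): the feedback taps read the
*measured* targets, making the residual differentiable and the Jacobian
exact (verified against central finite differences at 1e-6 on 50 random
instances).  The published epoch-wise update rule with the logistic
derivative `y(1-y)` in place of the tansig derivative `1-y^2` is kept
behind `jacobian(..., printed_derivative=True)` for study; it is not a
consistent gradient and is not used by the trainer.  Evaluation and all
reported predictions run closed-loop (the network feeds back its own
outputs), primed with the record's first two measured values.

The trainer minimizes F(w) = beta E_D + alpha E_w by damped Gauss–Newton
steps, solve((2 beta J'J + 2 alpha I) + mu I) with mu multiplied by 10 on
rejection and 0.1 on acceptance (start 0.005, stop above 5e5).  After each
accepted step the Foresee–Hagan evidence update re-estimates

    gamma = k - 2 alpha tr(H^-1),  alpha = gamma/(2 E_w),
    beta = (N - gamma)/(2 E_D),

starting from alpha = 0, beta = 1 (so gamma = k = 31 at the first epoch).
gamma is evaluated through the eigenvalues of J'J,
gamma = sum_i 2 beta s_i/(2 beta s_i + 2 alpha), which remains finite when
alpha -> 0 or J'J is rank-deficient; explicitly inverting the near-singular
Hessian returns nonsense here.  E_D, the mse and N refer to the training
subset only; validation/test subsets are monitored but never drive weight
selection — regularization replaces early stopping.

Data division is random over the usable indices (everything past the delay
priming), 50/25/25 by default, reshuffled every cycle.  Cyclic training
runs five cycles with Gaussian target noise annealed coarse-to-fine
(log-spaced from 1 kPa on the normalized scale down to 1/16 of that); the
descending order matters — finishing on the noisiest targets leaves the
final weights two orders of magnitude worse on the clean curve.  Both the
division and the noise derive from one seed, so identical configurations
reproduce training bit for bit.

Normalisation by the global maximum stress is not cosmetic: trained on raw
kPa targets (max ~200), the feedback taps drive the tansig layer deep into
saturation, its gradients vanish, and the closed-loop prediction plateaus
two orders of magnitude below the data maximum; on normalized targets the
same pipeline reaches within 0.1% of the maximum.  The saturation test
reproduces exactly this contrast.

## Curation

A direction-curve is "poor" training material when its flatness ratio
(stress at stretch 1.4 over its own maximum) falls below 0.15 or its
toe-region secant slope is not positive.  The two features come from the
documented data description; the cutoffs are this package's calibration,
chosen so the generator's good archetype (flatness ~0.21) and poor
archetype (~0.06) separate with margin on both sides.  Both features are
ratios/slopes, so labels are invariant to uniform stress rescaling.  The
three training-target kinds (raw curve, straight-line fit y = p1*lambda +
p2, constitutive fit) share the record's own strain grid and the ensemble's
normalisation constant.

## Evaluation

Predictions are scored per direction by the normalized error eps (with
q = 0 for a network simulated on fresh data, q = 4 for a direct
constitutive fit scored on the record it was fitted to) and by Pearson
correlation (R reported; R^2 available).  The one-way ANOVA computes the
full SS decomposition; p-values and critical values come from the exact F
distribution, and the implementation is cross-checked against
`scipy.stats.f_oneway` and against the squared pooled t statistic in the
two-group case.

## Synthetic data generator

Each specimen is a forward simulation of the constitutive model along the
equibiaxial ramp (strain rate decaying linearly ~7.8 -> ~3.9 %/s, rescaled
so terminal strain is exactly 50% over 8.5 s, 100 samples).  One log-normal
jitter draw (relative sd 0.10) perturbs all four parameters and applies to
*both* directions — one specimen, one material — so the
axial/circumferential ratio set by the fiber angle (sin^2/cos^2 of
57.3 deg: ratio ~2.4) is preserved per specimen.  Additive Gaussian
measurement noise (1 kPa) is applied and negative stresses clipped.

Base parameters anchor to the published axial-direction estimates with the
stress-like parameters scaled by 0.03 and the 57.3 deg fiber family shared
by both directions.  The scaling is forced by the data envelope itself:
the published parameters taken verbatim produce terminal stresses ~30x the
measured ones and a circumferential response with no toe region (the 91 deg
angle zeroes the hoop fiber term).  With the anchor scaling, good-archetype
curves have terminal axial stress ~40 kPa, [1.4, 1.5] secant moduli of
~320 kPa axial / ~130 kPa circumferential (inside the documented 267–2671
and 47–1170 kPa ranges), and toe regions below 25% of maximum at 40%
strain.  The poor archetype scales c, k1 by 0.05 and doubles k2: the curve
stays below 10% of its own maximum up to stretch 1.4, yet still rises at
the end of the ramp.  Ensembles default to 13 specimens (7 good, 6 poor)
plus the pointwise-mean record "T14"; a master seed spawns one substream
per specimen so dropping trailing specimens does not change the others.

What the generator does *not* emulate: hysteresis and preconditioning
cycles, rate dependence, shear, layer-specific behavior, and — importantly —
the tight cross-specimen agreement implied by the published per-test score
table.  The documented inter-specimen dispersion (standard deviations up
to ~27 kPa on ~40 kPa stresses; 10x spread in linear-region moduli) is
reproduced, and under that dispersion a network trained on one specimen
scores eps ~0.2–1.2 on its neighbours.  Passing property tests therefore
demonstrate correctness of the machinery (exact Jacobians, stable
closed-loop recurrences, recoverable parameters, reproduced saturation),
not that any single surrogate transfers across specimens at the few-percent
level on data this dispersed.

## Problem sizes and determinism

Test-suite experiments use the generator defaults (13 specimens, 100
samples per record) and the default training budget (5 cycles x <=1000 LM
epochs on 31 parameters); the full pipeline — six networks, closed-loop
simulation on all specimens, score table, ANOVA — runs in a few seconds on
one CPU.  Every random operation (weight init, data division, noise,
jitter) descends from explicit seeds; reruns are bit-identical.

## Known limitations

- Per-direction estimates of k1 and theta are reported as fitted but are
  ridge-degenerate on equibiaxial data (see identifiability above); only
  their product is data-determined.
- The flatness/slope cutoffs are calibration choices; on real data they
  should be re-examined against the observed flatness distribution.
- The trainer is dense and single-sequence by design (31 parameters,
  ~100-sample records); it is not meant for large networks or minibatched
  data.
- Closed-loop stability is empirical, not guaranteed: the recurrence is
  trained only in teacher-forced mode, and for some initialisations the
  free-running trajectory can drift near the top of the ramp.
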