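# Methods

This note documents the models, estimators and numerical choices behind
`mfrel`, and what the synthetic-data generators do and do not emulate.

## Scope and data model

The package covers the desk-side computations of a layer-by-layer (LbL)
ophthalmic particle formulation study: dynamic-light-scattering (DLS)
and zeta-potential post-processing with rule-based formulation
screening; cumulative drug-release modelling; a closed-form Riccati
release-dynamics kernel; fractal-dimension ("fractality degree")
estimation of release curves; and HET-CAM irritation scoring.  The
central container is `ReleaseCurve`: a replicate-averaged cumulative
release series (minutes; fraction or concentration units flagged
explicitly) with per-point SDs and a replicate count.

## Colloid characterization and screening

Hydrodynamic diameter follows Stokes–Einstein, `DH = kB*T/(3*pi*eta*D)`,
and zeta potential follows Smoluchowski in the form `zeta = eta*mu/eps`
with `eps` the *absolute* dielectric constant of the medium (F/m).
Some texts write `mu*eta/(eps0*epsr)` with a relative permittivity;
callers here always supply the absolute value.  Instrument temperature
and viscosity are rarely reported, so the defaults (298.15 K,
8.9e-4 Pa·s, 6.95e-10 F/m — water-like at 25 °C) are configuration, not
assertions.

Screening rules mirror accepted colloidal-stability practice for
ophthalmic emulsions: mean size strictly below 500 nm, PDI strictly
below 0.3, and refractive index at most 1.476 (inclusive; skipped when
unmeasured).  Selection takes the smallest mean size among formulations
with PDI < 0.3, breaking ties by lower PDI, then lower CTAB fraction.

## HET-CAM scoring

The continuous irritation score is
`IS = 5*(301-h)/300 + 7*(301-l)/300 + 9*(301-c)/300` for onset times
(s) of hemorrhage `h`, lysis/hyperemia `l` and coagulation `c` within a
300 s window; an unobserved effect is encoded as 301 s so its term is
exactly zero, making "no reaction → 0" an identity.  The scale runs 0
to 21.  Categories (non / less / moderate / severe irritant) use the
printed breakpoints 1.0, 5.0, 9.0 as left-closed interval endpoints;
the printed gaps (e.g. scores in (0.9, 1.0)) are closed by the
half-open convention so classification is total.  A discrete
window-score variant (points per effect for onset within 0.5/2/5 min)
is provided for completeness; the continuous score is authoritative for
classification.

## Riccati release dynamics

In the multifractal description of release, structural-unit dynamics
reduce to a constant-coefficient Riccati equation whose oscillatory
branch has the closed-form solution

    z(t) = B + A*Omega*[2 r sin(phi) + i(1-r^2)]/(1 + r^2 + 2 r cos(phi)),
    phi = 2*Omega*(t - t0),  0 <= r < 1,

with period pi/Omega.  Two typographic ambiguities in the source
derivation were resolved as package design choices:

* both the real and the imaginary part are scaled by `A*Omega` (the
  symmetric reading); the choice is isolated in `z_solution`;
* the root bookkeeping of the characteristic polynomial is
  inconsistent in the derivation; the closed form above is normative,
  and the Möbius-oracle roots `z1,2 = B ± i*A*Omega` are defined to be
  consistent with it.  Algebraically `w = (z - z1)/(z - z2) =
  -r*exp(2i*Omega*(t - t0))`, an exact phasor, so `dw/dt = 2i*Omega*w`
  holds identically and the finite-difference residual measures only
  truncation error (second order, verified by grid refinement).

Closed-form invariants used as oracles: time-averages `<Re z> = B` and
`<Im z> = A*Omega` (Poisson-kernel integral), extrema
`B ± 2*A*Omega*r/(1 - r^2)` (calculus on the kernel), and exact
periodicity.  Regime labels are operational: the published regimes are
defined only pictorially, so classification uses the duty cycle (the
fraction of a period with `|Re z - B|` above half its maximum): a pure
sinusoid has duty 2/3, spikes shrink it.  Thresholds (0.45 and 0.25)
are config-exposed; labels carry no claim beyond peak shape.  Sweeps
are deterministic and seed-free.

## Release models and fitting

The Kink law `M(t) = B + a*tanh(a*(t - t0)/A)` is the bounded solution
of the Riccati-type rate equation; `tau` is identified with `t - t0`
(the lag is the "convenient choice of variables"), and the implicit
constant `C` is not fitted independently (recoverable as
`(a^2 - B^2)/A`).  Baselines: Korsmeyer–Peppas `k*t^n`, Higuchi
`k*sqrt(t)`, Hixson–Crowell in cumulative form `M0*(1-(1-k*t)^3)`
clipped at complete dissolution, and Weibull
`Minf*(1-exp(-(t/lambda)^b))`.

Fitting is weighted least squares through `scipy.optimize.curve_fit`
with per-model bounds and data-driven initial guesses (for the Kink
law: B = first observation, a = total rise, t0 = half-rise time, A from
the maximal slope).  Replicate SDs enter as `1/sd^2` weights after
shrinking per-point variances 50% toward the pooled variance: SD
estimates from n = 3 replicates are so noisy that raw weights
measurably degrade parameter recovery (the shrinkage is an
empirical-Bayes-style moderation; with homoscedastic truth it roughly
halves the excess error while preserving genuine heteroscedasticity).
Higuchi has a closed-form weighted solution and never fails; nonlinear
models report a convergence flag instead of raising.  Models are
compared by AICc (small-sample corrected; release curves have ~20
points), computed from the weighted RSS.

### Identifiability of the Kink parameters

A tanh observed only on its upper branch has nearly degenerate
(B, t0): the demo default (lag 30 min, plateau 0.9 at fraction scale,
95% of plateau at 280 min) leaves the lower asymptote outside the
sampling window, and the Cramér–Rao bound at 2%-of-plateau noise is
~28% relative on B and ~41% on t0 — no fitter can do better.
Parameter-recovery studies therefore use `recovery_kink_params()`: a
symmetric S-curve (B = a = 0.45, lag 150 min, same 280 min plateau
approach) whose lag phase, rise and plateau are all observed; its CRLB
is ≤ ~5% per parameter and measured median errors are 1–3.5%.  The
plateau `B + a` is well determined in both designs (≤ 0.5%).

### Model-comparison limits

Self-consistency ("data generated from model X ranks X first by AICc")
cannot exceed ~90% for generators nested inside richer competitors:
Higuchi *is* Korsmeyer–Peppas at n = 0.5, and the power law is the
small-t boundary limit of Weibull.  By Wilks' theorem the richer model
improves the fit by more than the AICc penalty gap (≈2.5 at 20 points)
with probability ≈ P(chi2_1 > 2.5) ≈ 11%, independent of noise level
or seed.  Measured win rates over 100 trials: kink 100,
hixson-crowell 95, weibull 96, korsmeyer-peppas 91, higuchi 81.  This
is a property of information-criterion selection, not of the fitter.

### Preprocessing and plateau detection

Absorbance series convert to concentration through a calibration line
(`(A - intercept)/slope`, clipped at zero with a logged count) and to
cumulative mass with the standard withdrawn-and-replaced sampling
correction `m_i = V_bath*C_i + V_sample*sum_{j<i} C_j`.

`plateau_time` declares a plateau when the last three points agree with
the curve maximum within 2% of the maximum, widened by three pooled
standard errors of the mean when replicate SDs are present — without
the widening, the rule rejects ~45% of curves at the generator's own
default 2% replicate noise, because the maximum is a noisy order
statistic.  The 95%-of-plateau crossing time is linearly interpolated
between samples (so a sampled step returns the in-segment crossing,
converging to the step time with denser sampling).

## Fractality degree

No estimator is canonical for the "fractality degree" of a release
curve, so two standard, independent ones are reported: box counting on
the min-max-normalised curve (primary; geometric ladder of box sizes
1/4 … 1/64 of the unit square, polyline densely resampled so segment
interiors are counted, log-log slope with its R²) and a Higuchi-type
curve-length estimator (cross-check; k_max = 8 by default).  Both clip
to [1, 2], are bit-for-bit reproducible, and are invariant to affine
axis rescaling.  Reporting both exposes estimator sensitivity: they
agree on smooth curves (≈1) and rank rough panels identically, but
their absolute values differ on band-limited noise.  The qualitative
drug ordering (bevacizumab > dexamethasone > pilocarpine) is treated as
an emulation target of the synthetic panel, not a numeric claim.

## Synthetic data: what it emulates, what it does not

Generators are pure functions of (spec, seed):

* `gen_release_curve` — replicated sigmoidal release over a
  dissolution-style grid (dense to 600 min, sparse to 72 h, 20 points)
  with i.i.d. Gaussian replicate noise, default 2% of plateau (no
  magnitude is reported for the real error bars; this is a config
  default).  The demo Kink default (plateau 0.9, lag 30 min, 95% at
  280 min) lands the plateau inside the observed 200–360 min window.
* `gen_drug_panel` — three drugs sharing the Kink backbone with
  high-frequency roughness amplitudes in ratio 1:2:4 (base 1% of
  plateau, chosen so the finest box scale resolves the roughness),
  making the downstream complexity ordering decidable.
* `gen_dls_sizes` — log-normal sizes with exact theoretical mean and
  PDI (= variance/mean², the cumulant convention; the sources never
  define PDI, and this matches DLS-instrument magnitudes).
* `gen_lbl_series` — nondecreasing sizes and alternating zeta signs
  (polyanion −, chitosan +) with magnitudes in [5, 50] mV.
* `gen_hetcam_observation` — onsets drawn from per-category windows
  constructed so any combination scores inside the category; the
  classification is re-checked at generation time.

Not emulated: real DLS correlograms, drift/autocorrelation in release
noise (i.i.d. only), burst release beyond the tanh shape, UV–Vis
spectra, and inter-egg variability in HET-CAM.  A green test on this
stated world certifies the estimators and plumbing, not the chemistry.

## Determinism

All randomness flows from a single seed; the pipeline derives
per-stage seeds via `numpy.random.SeedSequence(seed, spawn_key)`.
Reports are byte-identical across reruns with the same config, and the
provenance block (config hash, seed, version) suffices to reproduce a
run.
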