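# Methods

This note documents the models, the study conditions, the numerical choices
and the known limitations of `dcmv0`. It is the package's own account of its
science; every empirical statement here is something the test-suite or
`scripts/acceptance.py` computes.

## 1. Generative model

### Neuronal level

Latent activity `z ∈ R^n` (one state per region) follows the bilinear state
equation

    dz/dt = (A + Σ_j u_j B_j) z + C u

with `A` the fixed effective connectivity (1/s), `B_j` the input-dependent
modulation of that connectivity and `C` the direct efficacy of the exogenous
inputs `u(t)`. The synthetic study uses a single binary input and no
modulatory `B` terms, so the neuronal level is a linear time-invariant system
during any one condition. Self-connections `A_ii` are fixed (not estimated)
and carry the stability convention discussed in §4.

### Hemodynamic level

Each region converts `z` into BOLD through the four-state Balloon model

    ds/dt = ε z − s/τ_s − (f − 1)/τ_f
    df/dt = s
    τ_0 dv/dt = f − v^{1/α}
    τ_0 dq/dt = f · E(f, E_0)/E_0 − v^{1/α} q / v,     E(f, E_0) = 1 − (1 − E_0)^{1/f}

and the observation equation

    y = V_0 [ k_1 (1 − q) + k_2 (1 − q/v) + k_3 (1 − v) ],
    k_1 = 7 E_0,  k_2 = 2,  k_3 = 2 E_0 − 0.2   (1.5 T convention, configurable).

`V_0`, the resting venous blood volume fraction, multiplies the output
exactly: doubling `V_0` doubles `y` for a fixed state trajectory. This exact
linearity is asserted at machine precision in the tests and is the reason a
misspecified `V_0` behaves like a per-region gain error during inversion.

A nomenclature caveat: part of the literature calls `τ_s` the signal-decay
constant and `τ_f` the flow-feedback (autoregulation) constant; other
sources swap the two labels. In this package the roles are fixed by the
equations above — `τ_s` always divides `s`, `τ_f` always divides `(f − 1)` —
and the names follow those roles.

### Default parameters

| parameter | meaning | default | units |
|---|---|---|---|
| ε | neuronal efficacy | 1.0 | – |
| τ_s | vasodilatory signal decay | 1/0.64 ≈ 1.5625 | s |
| τ_f | flow feedback (autoregulation) | 1/0.32 = 3.125 | s |
| τ_0 | mean transit time | 2.0 | s |
| α | balloon stiffness (outflow exponent) | 0.32 | – |
| E_0 | resting O₂ extraction fraction | 0.32 | – |
| V_0 | resting venous blood volume fraction | 0.04 | – |

These mirror the conventional software defaults for event-related BOLD
modelling and are configurable per region.

## 2. Study conditions (synthetic data)

Three regions A1, A2, A3. The stimulus drives A1 (`C = [1, 0, 0]ᵀ`); A1 is
reciprocally coupled to A2 and to A3; every inter-regional coupling and the
input efficacy equal 1 1/s. The design is 120 scans at TR = 2 s in 12
alternating 20-s blocks (10 scans each) starting with task. (The design's
printed description is internally inconsistent — 120 points in "blocks of 6"
cannot give twelve 20-s blocks at TR 2 s — so the package follows the two
mutually consistent numbers: 120 scans and twelve 20-s blocks.)

Per-region `V_0` triplets:

* set 1 (generating): (0.02, 0.04, 0.06)
* set 2: (0.04, 0.04, 0.04) — the "arbitrary physiologically plausible value"
* set 3: (0.06, 0.04, 0.02) — the reversed assignment

Observation noise is white Gaussian, i.i.d. per region, with standard
deviation `std(clean signal)/SNR` and SNR = 3. White noise slightly violates
the serial-correlation assumptions a full fMRI noise model would make; the
generator exposes this deliberately simple choice and the inversion matches
it with an i.i.d. Gaussian likelihood. The generator does not emulate
physiological (cardiac/respiratory) noise, scanner drift, or motion — so
passing tests demonstrate recovery under the stated idealised conditions,
not robustness to real-data artefacts.

## 3. Model space

Thirteen candidate architectures over the three regions, all with the input
on A1: feedforward-only, single-branch, pruned-feedback, lateral-link and
fully connected variants. The generating architecture (reciprocal A1↔A2,
A1↔A3) sits at index 3. The exact distractor composition is a canonical
reconstruction — the selection result ("truth wins under correct priors") is
about the generating model beating structurally wrong alternatives and does
not hinge on any particular distractor.

## 4. Why the self-connection is −1.5 1/s

With unit reciprocal couplings on two branches, the symmetric part of `A`
has top eigenvalue `a_self + √2`: the network is only dissipative for
`a_self < −√2 ≈ −1.414`. The package fixes `a_self = −1.5` 1/s, just inside
that bound, for a substantive reason beyond stability. The slowest network
mode then has time constant ≈ 1/0.086 ≈ 12 s, inside the band a 20-s block
design actually probes. A strongly self-inhibited network (e.g. −2.5 1/s)
relaxes within a fraction of a scan; in that regime the block design sees
only the static gain pattern of the network, any architecture with three
effective gain degrees of freedom reproduces the generating output to
~10⁻⁶ relative residual, and architecture selection degenerates into a
coin flip regardless of SNR. Keeping a slow collective mode makes the
feedback links express themselves in the measurable dynamics — the regime in
which effective-connectivity inference is informative at all. The price is
notional signal amplitudes (clean fractional signal change up to ~0.1–0.2
with the unit couplings), which is immaterial here because the noise is
defined relative to the signal.

## 5. Variational-Laplace inversion

Free parameters: the mask-allowed couplings and input efficacies (Gaussian
prior, mean 0, variance 1.0), and per region the log scaling factors of
{ε, τ_s, τ_0} around their defaults (mean 0, variance 0.015 — tight, as
befits biophysical constants). `V_0` is clamped per region to the prior-set
value under scrutiny; it is never estimated by default (a config flag can
free other hemodynamic parameters, but `V_0` clamping is the phenomenon the
study isolates).

The posterior is a fixed-form Gaussian found by Levenberg–Marquardt damped
Gauss–Newton ascent on the free energy

    F = Σ_r [ N/2 (ln λ_r − ln 2π) − λ_r/2 (RSS_r + tr(J_r Σ J_rᵀ)) ]
        − ½ [ tr(Π₀Σ) + (μ−μ₀)ᵀΠ₀(μ−μ₀) − p + ln|Σ₀| − ln|Σ| ]

with `J` the forward-model Jacobian (central differences, step 1e-4 on the
working scale, batched through the integrator), `Σ = (JᵀΠ_y J + Π₀)⁻¹` the
Laplace posterior covariance, and one noise precision `λ_r` per region
maximised in closed form (`λ_r = N/(RSS_r + tr(J_r Σ J_rᵀ))`) between
parameter steps; there is no hyperprior on the precisions. Steps are
accepted only when they increase F, so the accepted-step trace is
non-decreasing by construction; damping grows by 8× on rejection and decays
by 4× on acceptance. Iteration stops when an iteration gains less than
`tol` (default 1e-3 nats in the study configuration) or at `max_iter`
(128). The optimiser contains no randomness: repeated fits are
bit-identical.

On linear-Gaussian problems with fixed noise precision this scheme is exact;
the test-suite checks the posterior moments against the conjugate closed
form and F against the analytic log evidence to 1e-6 nats.

Numerical details: predictions for inversion are integrated with classical
RK4 at dt = 0.25 s (the generator uses 0.125 s; the discretisation gap is
orders of magnitude below the noise floor). Trial parameter vectors that
drive the integration out of the physical domain (f, v, q ≤ 0, overflow)
yield F = −∞ and are rejected by the damping loop rather than raising.

## 6. Model comparison

Fixed-effects Bayesian model selection on a single synthetic subject:
posterior model probabilities are the softmax of free energies under uniform
model priors. The combined comparison ranks all 13 × 3 = 39
(architecture, V_0 set) pairs at once; per-set log evidences relative to the
worst model of the set are also reported. Family-wise comparison over the
three V_0 sets uses uniform-across-family and uniform-within-family priors,
which corrects for unequal family sizes. Random-effects (group) BMS is out
of scope.

## 7. Sensitivity analysis

Single region, 2-s stimulus entering the signal equation directly
(`z = u`), noise-free output on a 0.125-s grid over 32 s. Parameters are
drawn from the priors of §1: lognormal for ε, τ_s, τ_f, τ_0 and
logit-normal for α, E_0, V_0, each with scale-spread √0.015 ≈ 0.122 —
matching the inversion's tight hemodynamic priors — except `V_0`, which the
inversion clamps and therefore has no estimation prior; its sampling spread
is set to 0.5 on the logit scale, reflecting the across-region physiological
range the study itself manipulates (0.02–0.06, with venous-dominated voxels
far higher). Total-effect indices use the Jansen estimator on a Saltelli
design built from scrambled Sobol' sequences (`scipy.stats.qmc`), N = 1024
base samples by default ((7+2)·1024 = 9216 model runs). Time points whose
total variance is numerically zero report the index as missing (NaN), never
as 0. The estimator is validated against an additive-quadratic test function
with closed-form Sobol indices (agreement within 0.02 at N = 4096) and the
single-uncertain-factor limit (S_T = 1).

## 8. Problem sizes and determinism

The acceptance pipeline runs 10 noise seeds × 39 fits (each fit typically
converges in 10–40 Gauss–Newton iterations) plus one N = 1024 sensitivity
analysis; the sizes are chosen so a full reproduction completes in minutes
on a single CPU while leaving the selection margins (hundreds of nats
between V_0 sets, fractions of a nat between neighbouring architectures)
clearly resolved at convergence tolerance 1e-3 nats. All randomness flows
through explicit integer seeds (dataset noise, Sobol' scrambling); reruns
are byte-identical, and every run directory carries a manifest with the
config hash and seeds.

## 9. Known limitations

* The inversion's noise model is i.i.d. Gaussian per region; AR(1) or
  physiological noise structure is not modelled (matching the generator's
  white noise, but not real data).
* Architecture selection margins between the generating model and its close
  structural neighbours (supersets, single-feedback prunings) are a few
  tenths of a nat at SNR 3 — the winner is stable across seeds in the
  majority sense, not per-seed deterministic.
* Nonlinear (two-state) neuronal models, stochastic DCM, slice timing and
  any real-data preprocessing are out of scope; the ROI CSV reader is a
  convenience entry point, not a preprocessing pipeline.
* The hemodynamic sampling distributions for the sensitivity analysis are a
  documented choice, recorded in each result's metadata; conclusions about
  which parameter "leads" hold under those priors.
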