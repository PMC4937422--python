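# dcmv0

Dynamic causal modeling (DCM) of fMRI with explicit priors on the resting
venous blood volume fraction **V₀**.

In DCM, directed ("effective") connectivity between brain regions is
inferred by inverting a generative model: a bilinear neuronal state equation

> dz/dt = (A + Σⱼ uⱼ Bⱼ) z + C u

coupled, per region, to the Balloon hemodynamic model (states *s, f, v, q*)
whose output is

> y = V₀ · [k₁(1−q) + k₂(1−q/v) + k₃(1−v)].

V₀ multiplies the observation equation, so the BOLD signal scales *exactly
linearly* in it — yet in practice V₀ is clamped to an arbitrary
"physiologically plausible" value (typically 0.04) because it cannot be
estimated jointly with the other parameters. This package quantifies the
consequences: it simulates a three-region network with region-specific V₀,
inverts it under competing V₀ beliefs with a variational-Laplace scheme,
ranks 13 candidate architectures × 3 V₀ prior sets by their free energies
(a 39-way Bayesian model comparison, plus family-wise comparison of the V₀
beliefs), and measures — via Sobol total-effect indices over peristimulus
time — how dominantly V₀ uncertainty drives the measurable BOLD output.

It is intended for methods researchers in effective-connectivity /
neuroimaging statistics who want a self-contained, reproducible testbed for
prior-misspecification effects in DCM.

## Worked example

```python
from dcmv0 import (SyntheticDatasetSpec, generate_study_dataset,
                   enumerate_architectures, default_priors,
                   variational_laplace, V0_SETS)

ds = generate_study_dataset(SyntheticDatasetSpec(seed=1))   # SNR 3, V0 = (0.02, 0.04, 0.06)
mask = enumerate_architectures("study13")[2]                # generating architecture (index 3)
post = variational_laplace(ds.noisy, ds.design, mask,
                           default_priors(mask, V0_SETS["set1"]))
print(f"F = {post.free_energy:.1f} nats, converged = {post.converged}")
for name in ("A:A1->A2", "A:A2->A1", "A:A1->A3", "A:A3->A1"):
    print(f"  {name}: {post[name]:.2f}")
```

prints

```
F = 1451.8 nats, converged = True
  A:A1->A2: 0.98
  A:A2->A1: 1.06
  A:A1->A3: 0.92
  A:A3->A1: 1.04
```

i.e. with the *correct* V₀ priors all four generating couplings (true value
1 s⁻¹) are recovered to within a few percent, and F is the log-evidence
bound that the model comparison ranks. The sensitivity side:

```python
from dcmv0 import sample_parameters, total_effect_indices, timing_summary

res = total_effect_indices(sample_parameters(n_base=1024, seed=0))
print(timing_summary(res.times, res.variance))
print({n: round(res.time_averaged_index(n, 2, 10), 3) for n in res.names})
```

```
{'t_peak': 4.75, 't_depart': 1.75, 't_return_after_offset': 11.25, 'threshold_fraction': 0.05}
{'epsilon': 0.024, 'tau_s': 0.024, 'tau_f': 0.098, 'tau_0': 0.032, 'alpha': 0.004, 'E_0': 0.002, 'V_0': 0.849}
```

The output variance of the hemodynamic response to a 2-s stimulus departs
from baseline just before 2 s, peaks near 5 s and returns to baseline about
11 s after stimulus offset — and V₀ carries ~85 % of that variance over the
positive-response window, dwarfing every kinetic parameter. That is the
quantitative case for treating V₀ as something worth knowing, not assuming.

A command line mirrors the library (`dcmv0 simulate|invert|compare|
sensitivity|study`); see `dcmv0 --help`.

## Layout

- `dcmv0.forward_model` — bilinear + Balloon generative model, RK4 engine
- `dcmv0.synthetic_data` — block design, ground-truth network, calibrated noise
- `dcmv0.model_space` — the 13-architecture candidate space
- `dcmv0.inversion` — variational Laplace (Gauss–Newton on the free energy)
- `dcmv0.model_comparison` — fixed-effects and family-wise BMS
- `dcmv0.sensitivity` — Saltelli/Jansen total-effect indices over time
- `dcmv0.pipeline`, `dcmv0.cli` — orchestration, config, CLI
- `docs/methods.md` — modelling assumptions, parameter tables, design choices
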