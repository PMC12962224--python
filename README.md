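# mdinvert

Voxel-wise inversion of multidimensional diffusion-relaxation MRI
(MD-MRI): estimation of the joint distribution of frequency-dependent
diffusion tensors and relaxation rates from sparse acquisitions that
vary b-tensor magnitude, shape, orientation, encoding frequency
content, TE and TR.

## The problem

A voxel's signal is modelled as a nonnegative mixture of
diffusion-relaxation components,

    s_m = Σ_n w_n · exp(−b_m : D_n(ω_cent,m)) · (1 − e^(−TR_m R1,n)) · e^(−TE_m R2,n),

where each component is an axisymmetric tensor with Lorentzian
frequency dispersion, `D_n(ω) = (D∥, D⊥, θ, φ, D0, Γ∥, Γ⊥)`, plus
relaxation rates `R1, R2`. Recovering the discrete distribution
`P(D(ω), R1, R2)` from ~10² measurements is ill-posed; this package
implements and compares three bootstrap-based inversion strategies:

- **MC** — Monte Carlo inversion: stochastic proliferation of random
  candidate components followed by local mutation, with NNLS weights
  and pruning, per bootstrap resampling.
- **DM** — dictionary matching: each bootstrap signal is matched (by
  cosine similarity) against an *informed dictionary* of precomputed
  signal/kernel/parameter triplets built from training data, then
  projected onto the matched kernels by NNLS.
- **ID-MC** — dictionary-guided MC: DM followed by a small number of
  local Gaussian mutation rounds (`Nm = 1` by default, `R = 200`
  perturbed sets per round). The matched kernels are always part of
  the expanded set, so the ID-MC residual never exceeds DM's, while
  mutation restores the flexibility that pure matching lacks.

Voxel distributions are summarized by means/variances/covariances of
Diso(ω), D∆²(ω), R1, R2; white-matter / gray-matter / CSF-like bin
fractions over the Diso–D∆² plane; and finite-difference frequency
derivatives across 6.6–21 Hz. A synthetic evaluation harness provides
the four-component reference voxel, Rician noise, bias-controlled
training dictionaries, exact Earth Mover's Distance scoring, and
test-retest reliability statistics (ICC(3,1), within-subject CV).

The intended users are MR physicists and image-analysis researchers
prototyping MD-MRI processing at desk scale; everything is driven by
seeded configuration objects and reruns are bit-identical.

## Worked example

```python
import numpy as np
import mdinvert as mi

protocol = mi.make_protocol(seed=0)          # 139 synthetic measurements
phantom  = mi.default_phantom()              # soma + crossing fibers + CSF
signal   = phantom.signal(protocol)          # noise-free ground truth

plan = mi.draw_bootstrap_plan(protocol.M, 20, seed=0)
sols = mi.mc_invert_voxel(signal, protocol, plan, mi.McConfig(nb=20, seed=0))

dist = mi.aggregate(sols)
labels, f1, f2, f3 = mi.assign_bins(dist)
diso, _ = dist.scalars(6.6)
print(f"bin fractions: {f1:.3f} {f2:.3f} {f3:.3f}")
print(f"E[Diso] at 6.6 Hz: {mi.weighted_stats(diso, dist.weights)[0]:.3f}")
```

prints

```
bin fractions: 0.524 0.369 0.108
E[Diso] at 6.6 Hz: 1.063
```

against ground-truth fractions (0.50, 0.35, 0.15) and E[Diso] = 1.088
μm²/ms — the MC estimate concentrates the mixture correctly into the
three tissue-like bins and recovers the mean isotropic diffusivity to
within a few percent from a single noise-free voxel at 20 bootstraps.

The same pipeline through the model interface:

```python
model = mi.DiffusionRelaxationInversion(signal, protocol)
res = model.fit("mc", nb=20, seed=0)
print(res.summary())
```

A command-line surface wraps the library
(`mdinvert make-protocol | simulate | build-dict | invert | maps |
evaluate | study`); every subcommand takes `--seed` and writes
provenance alongside its outputs.

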