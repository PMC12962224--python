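# Methods

## Signal model

A voxel is modelled as a discrete mixture of `N_c` diffusion-relaxation
components. Component `n` is the 9-parameter set

    (D∥, D⊥, θ, φ, D0, Γ∥, Γ⊥, R1, R2)

— an axisymmetric diffusion tensor whose axial and radial diffusivities
disperse with the angular frequency ω of the encoding waveform, plus
longitudinal and transverse relaxation rates. Each axis follows a
Lorentzian spectrum

    λi(ω) = Di + (D0 − Di) · ω² / (ω² + Γi²),   i ∈ {∥, ⊥},

which interpolates monotonically between the zero-frequency diffusivity
`Di` and the high-frequency isotropic plateau `D0`, with transition
frequency `Γi` (rad/s). The exact dispersion form is a modelling choice
of this package: it reproduces the intended limits (restricted
diffusion at low ω, free-like diffusion at high ω) with a single
transition parameter per axis.

A measurement is described by its b-tensor — trace `b` (ms/μm²),
normalized anisotropy `b∆` (1 linear, 0 spherical, −0.5 planar),
symmetry axis — the centroid angular frequency `ω_cent` of the
waveform, and TE/TR. The full spectral coupling ∫ b(ω):D(ω) dω is
approximated by evaluating the tensor contraction at the centroid
frequency, `b : D(ω_cent)`; true per-waveform encoding spectra are out
of scope, and the centroid surrogate is exact for spectra concentrated
at one frequency. The kernel of component `n` under measurement `m` is

    k_mn = exp(−b:D(ω_cent)) · (1 − exp(−TR·R1)) · exp(−TE·R2),

and the signal is `s = K w` with nonnegative weights `w` (signal
units; proton density is absorbed by the weights, no normalization is
applied before inversion).

Units: `b` in ms/μm² against diffusivities in μm²/ms; TE/TR in s
against R1/R2 in 1/s; ω and Γ in rad/s, with user-facing frequency
columns in Hz (ω = 2π f).

## Inversion strategies

All three inversions share a fixed bootstrap plan: `Nb` index vectors
of length M drawn uniformly with replacement. A least-squares fit on a
resampled signal is solved on the *unique* rows with √(multiplicity)
row weighting — algebraically identical to fitting the repeated rows,
but cheaper.

**MC (baseline Monte Carlo).** Per bootstrap: `Np = 20` proliferation
rounds each draw `batch = 20` i.i.d. candidates within the sampling
bounds (log-uniform for diffusivities and transition frequencies whose
bounds span orders of magnitude, uniform for relaxation rates, uniform
on the sphere for orientation), merge them with the retained set, fit
by NNLS and keep nonzero-weight candidates; then `Nm = 20` mutation
rounds perturb the retained set (`mutation_reps = 5` perturbed copies
per round) and refit. A round is accepted only if the residual does
not increase, so the residual is monotone within each stage.

During the search the retained set is allowed to grow to
`working_cap = 30` components; only the final solution is projected
down to `Nc = 10` (largest weights, refit). Capping to `Nc` every
round was tried first and discards minor mixture fractions (a 15 %
free-water pool) before mutation can refine them, visibly biasing the
recovered bin fractions; the working cap removes that bias at modest
cost while every returned solution still has ≤ `Nc` components.

Sampling bounds (human brain): D ∈ [0.05, 5] μm²/ms, θ ∈ [0, π],
φ ∈ [0, 2π], R1 ∈ [0.2, 2] s⁻¹, R2 ∈ [1, 30] s⁻¹, Γ ∈ [0.01, 10⁴] s⁻¹.

**DM (dictionary matching).** The informed dictionary stores, per
bootstrap index `b`, entries derived from training signals: the
resampled synthesized signal, its kernel columns, and the generating
parameter sets. Training signals are reduced to `n_reps`
representatives by k-means on unit-normalized signals (centroids
snapped to the nearest actual member); each representative's plan-row-b
resampling is MC-inverted to create the entry. Inversion resamples the
query with the *same* plan, picks the entry with maximal cosine
similarity (exact exhaustive search, ties to the lowest index) and
projects the signal onto the matched kernels by NNLS. No mutation.

**ID-MC.** Starts from the DM solution and runs `Nm` rounds (default
1) of local refinement: the retained parameter sets are perturbed into
`R = 200` replicate sets by zero-mean Gaussian offsets — multiplicative
in log-space (σ = 0.1) for the positive parameters, additive (σ = 0.1
rad) for the angles, clipped to bounds — the matched kernels are
expanded with the perturbed ones, and a second NNLS fit redistributes
the weights (cap `Nc`, accept only non-increasing residuals). Because
the matched kernels are always part of the expanded set, the ID-MC
residual can never exceed the DM residual on the same bootstrap
sample; with `Nm = 0` ID-MC reduces exactly to DM. One mutation round
is the default: more rounds progressively refit noise, which is
visible in the simulation study as growing distribution spread.

Every inversion is a pure function of (signal, protocol, plan, config):
per-bootstrap and per-voxel RNG streams are spawned from
`SeedSequence((seed, index))`, so parallel and serial execution agree
and reruns are bit-identical.

## Descriptors

Bootstrap solutions are pooled with equal per-bootstrap mass (weights
normalized to 1, then scaled by 1/Nb). Scalar projections at frequency
ω: `Diso = (λ∥ + 2λ⊥)/3` and `D∆² = ((λ∥ − λ⊥)/(3 Diso))²`. Voxel
summaries are weighted means/variances/covariances of {Diso(ω), D∆²(ω),
R1, R2}, three bin fractions over the Diso–D∆² plane

    bin 1: Diso ≤ 2.5 μm²/ms and D∆² > 0.25   (white-matter-like)
    bin 2: Diso ≤ 2.5 μm²/ms and D∆² ≤ 0.25   (gray-matter-like)
    bin 3: Diso > 2.5 μm²/ms                   (CSF-like)

evaluated at the lowest sampled frequency (6.6 Hz, configurable; the
inequalities for bins 1/3 are strict), and finite-difference rates of
change of E/V of the diffusion statistics across 6.6–21 Hz, per Hz.
Orientation angles enter the kernel only; they are excluded from the
scalar summaries and from the distribution distance below.

## Synthetic data

The reference voxel is a four-component mixture: soma-like water
(isotropic, slow, strongly dispersive), two crossing-fiber populations
(identical tensor shape, azimuths 55° apart) and free water (fast,
isotropic, frequency-flat), with weights (0.35, 0.25, 0.25, 0.15).
The synthetic protocol mimics a sparse multidimensional acquisition:
139 measurements minus one b = 0 volume, b ∈ [0.1, 3] ms/μm², shapes
drawn from {linear, spherical, planar}, centroid frequencies 6.6–21 Hz,
TE ∈ [40, 150] ms, TR ∈ [0.62, 7.6] s, quasi-uniform orientations.

Noise is Rician, `S = √((S_gt + v/SNR)² + (v′/SNR)²)` with standard
normal v, v′, at SNR ∈ {130, 90, 60, 30}; the noise scale 1/SNR is
referenced to a unit-amplitude signal and is not renormalized per
draw. Biased training sets multiply every positive parameter by
(1 + ε), ε ~ N(0, σ_bias²), perturb angles additively by σ_bias rad,
clip to bounds, and perturb-and-renormalize the weights
(σ_bias ∈ {0.2, 0.3, 0.4, 0.5}; a switch disables weight
perturbation).

What the generator does *not* emulate: spatial structure and partial
voluming across voxels, physiological noise and motion, eddy/Gibbs
artifacts, true gradient-waveform encoding spectra, exchange between
pools, and scanner-to-scanner variation. Passing the synthetic checks
therefore demonstrates correctness of the inversion machinery and its
comparative behaviour under noise and prior mismatch, not in-vivo
validity.

## Evaluation

**EMD.** Accuracy against the known ground truth is the exact optimal
transport cost between the two discrete weighted distributions
(transportation LP solved with HiGHS; supports pruned at weight 10⁻⁶
and renormalized). Ground metric: Euclidean distance after mapping
each component to log10 of its positive parameters, each rescaled to
[0, 1] by its sampling bounds; orientation is excluded by default
(configurable weight on the axis unit vector). The log/rescale choice
makes μm²/ms-scale diffusivities and 10³-scale transition frequencies
commensurable.

**Signal-domain metrics.** Cosine similarity between reconstructed and
reference signals, and NRMSE = ‖ŝ − s‖₂ / (√M · range(s)). Per-voxel
counts of bootstrap fits above/below similarity thresholds (defaults
0.999/0.997, or 80th/20th percentiles of a training sample) summarize
fit stability.

**Reliability.** ICC(3,1) — two-way mixed, single measurement,
consistency — computed from the ANOVA mean squares; chosen because the
two sessions of a test-retest design are fixed rather than sampled
raters (the absolute-agreement variant ICC(2,1) is a one-line change
and is cross-checked against an independent implementation in the
tests). CVws = √(mean within-subject variance) / grand mean.

## Numerical choices

- NNLS: Lawson–Hanson active-set iteration on the normal equations,
  gradient tolerance 10⁻¹² (absolute, on the projected gradient), ties
  broken by lowest column index; Gram columns are computed lazily and
  active-set systems are solved by a hand-rolled Cholesky with a 10⁻¹³
  diagonal regularizer (the expanded ID-MC systems contain
  near-duplicate columns). Wide systems (139 × ~2000) stay cheap
  because at most ~M columns can ever be active. Warm-starting from
  the previous round's retained columns accelerates the per-round
  refits without changing the optimum.
- Degenerate inputs: an all-zero bootstrap signal yields an empty
  solution; empty bootstraps are skipped in aggregation; an all-empty
  voxel yields an empty-distribution sentinel that refuses summaries.
- Bin boundary: components exactly at Diso = 2.5 or D∆² = 0.25 fall in
  bin 2 (strict inequalities for bins 3 and 1).
- Per-voxel seeds are derived by `SeedSequence((seed, voxel))` reduced
  below 2³¹.

## Problem sizes

The test suite and the acceptance script run the full pipeline at
reduced scale, chosen as the package's desk-scale defaults: bootstrap
rounds Nb = 20 (instead of the in-vivo 100); one dictionary per
(bias, SNR) condition, trained on 200 signals noised at that SNR and
clustered to 128 representatives; and accuracy studies of 80 test
voxels per (seed, SNR) condition over 5 seeds at SNR ∈ {130, 30} and
σ_bias = 0.2 (the acceptance script uses 40 voxels and one seed).
Orderings between methods (median EMD, mean similarity) are
sample-size-free properties; the reduced scale widens their sampling
error, and the dictionary-guided methods are sensitive to dictionary
density — their accuracy improves monotonically with the number of
representatives, so desk-scale results bound the full-scale advantage
from below, most visibly at high SNR where the matching error rather
than noise limits accuracy. The full in-vivo scale (10 000 voxels per
SNR, Nb = 100, dictionaries of ~10⁶ patterns) is reachable through
the same configuration objects.

## Known limitations

- The centroid-frequency surrogate under-represents broad encoding
  spectra; protocols whose waveforms have multimodal spectra would
  need the full b(ω) integral.
- The Lorentzian dispersion form is assumed, not fitted; non-Lorentzian
  or exchange-driven dispersion is out of scope.
- Dictionary quality bounds DM/ID-MC accuracy: pathologies absent from
  the training distribution are only reachable through the mutation
  step's local exploration radius.
- The EMD ground metric ignores orientation by default, so two
  distributions differing only in fiber orientation have distance 0
  under the default settings.
- MC recovery of minor mixture fractions remains biased at desk scale
  (e.g. free-water fraction recovered at ~0.11 against a true 0.15
  noise-free); this is inherent to the ill-posedness of the inversion,
  not a convergence failure, and is shared by the published baselines.
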