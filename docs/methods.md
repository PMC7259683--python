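# Methods

## The two-compartment model

A diffusion-weighted voxel is modeled as a mixture of anisotropic tissue
and isotropic free water:

```
Aᵢ(D, f) = f · exp(−b qᵢᵀ D qᵢ) + (1 − f) · exp(−b d)
```

* `Aᵢ` — attenuation (weighted signal / mean unweighted signal) along unit
  direction `qᵢ`;
* `D` — symmetric positive-definite tissue tensor (mm²/s), stored
  throughout as the 6 lower-triangular components `(Dxx, Dxy, Dyy, Dxz,
  Dyz, Dzz)`;
* `f ∈ [0, 1]` — tissue volume fraction; the free-water map is `1 − f`;
* `d = 3.0×10⁻³ mm²/s` — free-water diffusivity at body temperature,
  fixed.

With a single nonzero b-value the data constrain only the product
structure of the mixture: for every tensor there is a family of
`(f, D)` pairs with nearly identical predicted attenuations. The package
therefore treats the fit as a local refinement of a carefully built
starting point, which carries most of the estimate. This is a property of
the single-shell problem, not of the optimizer (see "Optimizer behavior").

## Initialization

Two per-voxel fraction estimates are combined:

* **T2-scaling estimate** `f_b0 = 1 − log(S0/S_t)/log(S_w/S_t)`. The
  references are `S_t` = 5th percentile of S0 inside a white-matter
  region and `S_w` = 95th percentile inside a CSF region (percentiles are
  deliberately asymmetric: a low WM reference and a high CSF reference
  bracket the intensity range). The pipeline assumes the S0 image is
  bias-field corrected upstream; the CLI warns when that is not asserted,
  because a multiplicative intensity bias translates directly into a
  spatially varying fraction bias.
* **Diffusivity estimate**
  `f_MD = (e^(−b·MD) − e^(−b·d)) / (e^(−b·MD_tissue) − e^(−b·d))`, where
  MD is the mean diffusivity of the standard (single-tensor) fit and
  `MD_tissue = 0.60×10⁻³ mm²/s` is the expected MD of clean white matter.
  Free-water partial volume inflates the apparent MD toward `d`; this map
  inverts that inflation under an isotropic mono-exponential assumption.

The blend is geometric, `f_init = f_b0^(1−α) · f_MD^α`, with `α` equal to
the raw `f_b0` value clipped to `[0, 1]`. Voxels whose S0 resembles the WM
reference (`α ≈ 1`) trust the diffusivity route; CSF-like voxels
(`α ≈ 0`) trust the T2 route; intermediate voxels — edema, infiltration,
partial volume — sit near the geometric mean. The interpolation therefore
needs no tissue segmentation beyond the two reference regions.

Per-voxel feasibility bounds come from the extreme attenuations:

```
f_min = (min Â − e^(−bd)) / (e^(−b λmax) − e^(−bd))
f_max = (max Â − e^(−bd)) / (e^(−b λmin) − e^(−bd))
```

with `λmin = 0.1×10⁻³`, `λmax = 2.5×10⁻³ mm²/s` (a putative range of
radial/axial WM diffusivity). Values are clamped to `[10⁻⁴, 1]` and
ordered; `f_b0` is clamped to the nearest bound, and the final `f_init`
is clamped into `[f_min, f_max]` as well, because that interval is the
optimizer's feasible region (whether the original formulation re-clamps
after interpolation is not documented; this package does, and records the
choice here).

The initial corrected tensor removes the free-water term at `f_init`
(`Â_t = (Â − (1−f_init) e^(−bd)) / f_init`, clipped to (10⁻⁸, 1]) and
refits a single tensor to the result.

A **b0 baseline mode** reproduces the prior initialization for
head-to-head comparisons: `f_init = f_b0` with out-of-range values
replaced by the bound midpoint `(f_min + f_max)/2` instead of the nearest
bound.

## Optimizer

Per voxel, the objective is the sum of squared attenuation residuals
(attenuation space, matching the model statement, rather than
log-signals). Descent is projected gradient with a backtracking (halving,
≤ 20) line search from a fixed initial step of 0.1 along the normalized
negative gradient; the accepted-objective sequence is therefore
non-increasing by construction. The tensor is parameterized by its matrix
logarithm `L = log D` (log-Euclidean coordinates), so `D = exp L` is
symmetric positive definite with no explicit constraint; the chain rule
through the matrix exponential uses the Daleckii–Krein divided-difference
form, which is exact for symmetric matrices (verified against finite
differences). `f` is re-projected into `[f_min, f_max]` after every step.
Convergence is declared when the relative objective decrease falls below
1e-8 or after 100 iterations; voxels that hit the iteration cap are
flagged, not discarded. Eigenvalues are floored at 10⁻⁶ mm²/s before the
matrix logarithm (noisy corrected-tensor initializations can be
indefinite). Fitting contains no randomness: identical inputs give
identical outputs.

### Optimizer behavior (and why the initialization dominates)

On noise-free data the model is technically identifiable, but the
objective landscape is a long, curved, nearly flat valley in `(f, D)`:
profiling the valley floor `J*(f) = J(f, D_corr(f))` around a noise-free
voxel shows residuals of order 10⁻⁷ across a ±0.1 band of `f`, with
genuine local minima along the way. Plain gradient descent converges onto
the floor and stops; it does not slide along it (a Barzilai–Borwein
variant was evaluated and does not either — the floor has real barriers,
not just slow curvature). At any realistic SNR the valley structure lies
far below the noise floor, so the data cannot arbitrate along it and the
final estimate inherits the initialization's bias. This is the premise of
the method — single-shell free-water elimination is an
initialization-dominated problem — and it is why the phantom experiments
measure initialization quality rather than optimizer quality. A practical
consequence: at moderate free-water levels the FERNET estimate carries a
positive bias of roughly +0.1 under this package's phantom conditions
(reported per level by the acceptance script), while the b0 baseline's
errors are bimodal with a much larger spread.

## Spatial regularization

The optional penalty is `ω · Σ (f_a − f_b)²` over 6-connected in-mask
neighbor pairs — a discrete Dirichlet/Laplacian energy on the fraction
map (the original work used an undisclosed in-house tool; only the
qualitative behavior is targeted). Minimization alternates block-coordinate
sweeps (default 5): each voxel is refit against its neighbors' current
values, which adds a quadratic prior `ω Σ_n (f − f_n)²` to that voxel's
objective. `ω = 0` disables the extra term and runs the identical
unregularized path. The weight's absolute scale is only meaningful
relative to this package's summed-attenuation data term; `ω = 0.1` is the
documented demonstration value. The regularization-sensitivity experiment
compares FW histograms (50 bins on [0, 1], total-variation distance)
between `ω = 0` and `ω = 0.1` fits of a smooth phantom; note that this
metric counts every bin-edge crossing, so coherent sub-bin drifts
(mean |ΔFW| ≈ 0.005, a quarter of one bin, per the acceptance script's
`reg_mean_abs_fw_shift`) can still produce TV values above 0.1 even when
the histograms visually coincide.

## Standard tensor fit

Weighted linear least squares on the log-signal: an ordinary LS fit on
`log S` provides predicted signals, and one reweighting pass with weights
equal to those predicted signals squared yields the final estimate (the
standard correction for the heteroscedasticity introduced by the log
transform). Signals are floored at 10⁻⁸ before the logarithm — Rician
noise can drive normalized signals to zero — and multiple b0 volumes are
averaged into a single S0 before attenuations are formed. The design
matrix requires at least one b0 volume and six distinct weighted
directions; the gradient-table container enforces this, along with unit
direction norms (renormalizing within ±5%) and the single-shell contract
(all nonzero b equal within 1%).

## Synthetic data

The simulator emulates single-shell DWI of a voxel containing a
ground-truth tissue tensor plus free water:

* unweighted signal `S0 = f·S0_WM + (1−f)·S0_CSF` — the linear form a
  spin-echo magnetization model reduces to when proton density and
  relaxation times are held fixed while only the volume fraction varies;
* weighted signals `Sᵢ = S0 (f·A_tissue + (1−f)·A_water)`, consistent
  with the fitting model to machine precision (asserted in the suite);
* Rician noise: `out = √((S+n₁)² + n₂²)`, `n₁,n₂ ~ N(0, σ²)`,
  `σ = S0_WM / SNR` (SNR referenced to the tissue b0 intensity, the
  conventional DWI definition).

Three scenarios define the ground-truth tensors:

| scenario | construction | FA | MD (mm²/s) |
|---|---|---|---|
| A | prolate tensor, healthy-WM averages | 0.5 | 7.7×10⁻⁴ |
| B | A's eigenvalues assigned to free-water VF 0.15 and extrapolated per eigenvalue to VF 0 | 0.6 | 6.0×10⁻⁴ |
| C | prolate tensor, restricted-diffusion tumor region | 0.1 | 5.5×10⁻⁴ |

Scenarios given only as (FA, MD) pairs are realized as axially symmetric
(prolate) tensors — `λ₁ = MD(1+2δ)`, `λ₂ = λ₃ = MD(1−δ)` with
`δ = FA·√(3/(9−6FA²))` — the disambiguation that reproduces scenario B's
printed values. The B extrapolation solves, per eigenvalue,
`λ_tissue = −ln[(e^(−bλ) − 0.15·e^(−bd))/0.85]/b`; mixing back at VF 0.15
recovers the inputs to 10⁻¹⁰ (asserted).

The default grid is 10 free-water volume fractions (0–0.9) × 10 SNR
levels (10–100) × 100 noise realizations × 100 random tensor rotations
(uniform over SO(3) via normalized quaternions) = 1,000,000 records per
scenario. Tests and the acceptance script run reduced subsets; per-cell
seeding (`SeedSequence((seed, i_vf, i_snr, i_rep, i_rot))`) makes any
sub-grid reproduce the corresponding cells of the full grid exactly.

What the simulator does **not** emulate: spatial anatomy and partial
volume between more than two compartments, eddy/motion/susceptibility
artifacts, bias fields (phantom S0 images are bias-free by construction,
so the bias-correction input contract is untested by simulation), tissue
heterogeneity within a voxel, and multi-shell acquisitions. Passing the
simulation suite therefore demonstrates correctness of the model,
initialization and optimizer under the stated noise model — not
performance on real scanner data.

## Parameters (defaults and rationale)

| parameter | default | units | rationale |
|---|---|---|---|
| `d` | 3.0×10⁻³ | mm²/s | free-water diffusivity at 37 °C, fixed by the model |
| `λmin`, `λmax` | 0.1×10⁻³, 2.5×10⁻³ | mm²/s | putative radial/axial WM diffusivity range (bounds) |
| `MD_tissue` | 0.60×10⁻³ | mm²/s | expected MD of clean WM (f_MD anchor) |
| simulation `b` | 800 | s/mm² | the single value that reproduces scenario B's printed MD of 6.0×10⁻⁴ (b=1000 gives ≈6.2×10⁻⁴); configurable |
| directions | 30 (+3 b0) | — | clinical single-shell layout; deterministic electrostatic-repulsion set |
| `S0_WM`, `S0_CSF` | 400, 1200 | scanner units | representative tissue/CSF b0 intensities; in simulations they double as the S_t/S_w references since records carry no spatial context |
| fraction floor `ε_f` | 10⁻⁴ | — | keeps the geometric interpolation and the 1/f correction finite |
| signal floor `ε` | 10⁻⁸ | — | guards logarithms against non-positive noisy signals |
| `max_iters`, step, tol | 100, 0.1, 10⁻⁸ | — | see "Optimizer" |
| `ω`, sweeps | 0 (off), 5 | — | see "Spatial regularization" |
| implausible-MD threshold | 0.40×10⁻³ | mm²/s | corrected-tensor MD below this flags an artifactual fit |

## Evaluation conventions

Signed error is **estimate − truth** (positive = free water
overestimated). Standard deviations are sample (n−1). Grouped summaries
report mean, std, skewness, the 5/25/50/75/95% quantiles and counts.
Voxelwise agreement between co-registered map stacks is the Pearson
correlation across subjects per voxel (NaN where either stack has zero
variance) plus the mean squared difference; at least three subjects are
required. The implausible-fit diagnostic reports the percentage of
subjects (or in-mask voxels) whose corrected-tensor MD falls below the
threshold.

## Known limitations

* The initialization's fraction estimates are heuristics; at moderate
  free-water levels they bias the estimate upward (see "Optimizer
  behavior"), and because the optimizer cannot traverse the flat valley,
  the bias survives fitting. The method's advantage is its *stability* —
  unimodal, low-variance errors — rather than unbiasedness.
* `f_b0`'s logarithmic S0 scaling is only exact when the voxel S0 equals a
  geometric mixture of the references; real voxels mix linearly, so the
  two routes disagree by construction and the interpolation inherits a
  residual bias that depends on the S_w/S_t ratio.
* The prolate realization of (FA, MD) scenarios is an assumption; real
  WM voxels are not exactly axially symmetric.
* The spatial regularizer is a generic Dirichlet energy, not a
  reimplementation of any specific prior tool, and its weight is
  implementation-scale-dependent.
* No preprocessing is performed or validated here: denoising, eddy/motion
  correction, skull stripping, bias-field correction and co-registration
  are upstream input contracts. Masks must already sit on the DWI grid —
  the I/O layer rejects, and never resamples, mismatched affines.
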