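# fernet-fw

Free-water elimination for **single-shell** diffusion MRI.

Diffusion tensor indices such as fractional anisotropy (FA) and mean
diffusivity (MD) are confounded wherever a voxel contains free
(unrestricted) water — most prominently in peritumoral edema, where the
extracellular water both masks and mimics tissue change. Multi-shell
free-water elimination resolves the ambiguity with extra acquisitions, but
most clinical diffusion protocols are single-shell, where the
two-compartment fit has infinitely many solutions and the result is decided
by the starting point of the optimization.

This package implements **FERNET** (Freewater EstimatoR using iNtErpolated
iniTialization): a bi-tensor model fit driven by an initialization that
interpolates between a T2-based and a diffusivity-based estimate of the
tissue volume fraction, designed to behave sensibly in both healthy tissue
and edema. It also ships the bi-compartment phantom simulator and the
evaluation metrics used to characterize the method.

## Model

Each voxel's attenuation along gradient direction *qᵢ* at b-value *b* is

```
Aᵢ(D, f) = f · exp(−b qᵢᵀ D qᵢ) + (1 − f) · exp(−b d)
```

with tissue tensor *D*, tissue volume fraction *f* (free water = 1 − f) and
fixed free-water diffusivity *d* = 3.0×10⁻³ mm²/s. The initialization
blends two fraction estimates geometrically,

```
f_init = f_b0^(1−α) · f_MD^α ,
f_b0  = 1 − log(S0/S_t) / log(S_w/S_t) ,
f_MD  = (e^(−b·MD) − e^(−b·d)) / (e^(−b·MD_tissue) − e^(−b·d)) ,
```

where S_t / S_w are reference unweighted signals (5th percentile of S0 in a
white-matter region, 95th percentile in a CSF region), MD comes from the
standard weighted-linear-least-squares tensor fit, MD_tissue = 0.60×10⁻³
mm²/s, and α is f_b0 restricted to [0, 1]: voxels that look like normal WM
on T2 trust f_MD, CSF-like voxels trust f_b0, intermediate voxels (edema,
partial volume) land near the geometric mean. Per-voxel feasibility bounds
[f_min, f_max] derived from the extreme attenuations constrain the fraction
throughout. The model is then fit per voxel by projected gradient descent
with the tensor in log-Euclidean coordinates (symmetric positive definite by
construction) and an optional 6-neighbor smoothness penalty on *f*.

## Worked example

Simulate noisy single-shell data from the healthy-WM scenario (prolate
tensor, FA 0.5, MD 7.7×10⁻⁴ mm²/s) with a known free-water fraction of 0.6
at SNR 20, then estimate free water with both initializations:

```python
import numpy as np
import fernet as fn

scheme = fn.make_scheme(b=800.0, n_dirs=30, n_b0=3)
scenario = fn.build_scenario("A").subset(
    vf_grid=[0.6], snr_grid=[20.0], n_realizations=10, n_rotations=5
)
records = fn.run_simulation(scenario, scheme, seed=42)

fw_fernet = fn.fit_records(records, init_mode="fernet")
fw_b0 = fn.fit_records(records, init_mode="b0")

print(f"true FW: {records.vf[0]:.2f}, records: {records.n_records}")
print(f"FERNET:  mean FW {fw_fernet.mean():.3f}  "
      f"mean error {np.mean(fw_fernet - records.vf):+.3f}")
print(f"b0 init: mean FW {fw_b0.mean():.3f}  "
      f"mean error {np.mean(fw_b0 - records.vf):+.3f}")
```

prints

```
true FW: 0.60, records: 50
FERNET:  mean FW 0.681  mean error +0.081
b0 init: mean FW 0.351  mean error -0.249
```

FERNET overestimates this edema-like free-water level slightly; the older
b0-scaling initialization collapses a large subpopulation of voxels to far
too little free water (its error distribution is bimodal — the mean hides a
−0.25 body of mass).

On real data the same fit runs from the command line and writes NIfTI maps
(FW, tissue fraction, corrected tensor/FA/MD, per-voxel diagnostics):

```
fernet fit --dwi dwi.nii.gz --bval dwi.bval --bvec dwi.bvec \
  --mask brain.nii.gz --wm-mask wm.nii.gz --csf-mask csf.nii.gz \
  --init fernet --out out/ --bias-corrected
```

`fernet simulate`, `fernet evaluate` and `fernet agree` expose the phantom
generator, the grouped error summaries and the voxelwise agreement maps.

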