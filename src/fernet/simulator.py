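"""Synthetic bi-compartment DWI with ground truth.

Each simulated voxel mixes a ground-truth tissue tensor with an isotropic
free-water compartment (diffusivity 3.0e-3 mm^2/s). The unweighted signal is
a linear mix of tissue and CSF reference intensities,

    S0 = f * S0_WM + (1 - f) * S0_CSF,

which is what a spin-echo magnetization model reduces to when proton density
and relaxation constants are held fixed while the volume fraction varies.
The weighted signal along direction i is ``S_i = S0 (f A_tissue + (1-f)
A_water)`` and Rician noise is applied as the magnitude of a
complex-Gaussian-perturbed signal with sigma = S0_WM / SNR.

Three named scenarios cover the study conditions:

* ``A`` — healthy white matter: prolate tensor with FA 0.5, MD 7.7e-4 mm^2/s
  (WM averages of healthy controls), free water added on top.
* ``B`` — healthy WM assumed to already carry free water: the scenario-A
  eigenvalues are assigned to a free-water volume fraction of 0.15 and
  extrapolated per eigenvalue to VF 0, giving FA 0.6, MD 6.0e-4 mm^2/s.
* ``C`` — restricted diffusion in tumor: FA 0.1, MD 5.5e-4 mm^2/s.

The default grid is 10 free-water volume fractions (0 to 0.9) x 10 SNR
levels (10 to 100) x 100 noise realizations x 100 random tensor rotations =
1,000,000 records per scenario; tests and the acceptance script run reduced
subsets of the same design.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .gradients import GradientScheme, make_scheme
from .initialization import InitParams
from .tensor import (
    FREE_WATER_DIFFUSIVITY,
    from_lower_tri,
    prolate_tensor,
    signal_attenuation,
    tensor_eigensystem,
    tensor_from_eigensystem,
)

#: Default reference unweighted intensities (scanner units).
DEFAULT_S0_WM = 400.0
DEFAULT_S0_CSF = 1200.0

#: Default simulated shell.
DEFAULT_B = 800.0
DEFAULT_N_DIRS = 30


@dataclass(frozen=True)
class SimulationScenario:
    """Ground truth and grid definition for one simulation design.

    ``vf_grid`` holds free-water volume fractions (VF, the edema axis of
    the design); the tissue fraction of a record is ``1 - vf``.
    """

    name: str
    evals: np.ndarray                      # ground-truth eigenvalues, mm^2/s
    s0_wm: float = DEFAULT_S0_WM
    s0_csf: float = DEFAULT_S0_CSF
    vf_grid: np.ndarray = field(default_factory=lambda: np.round(np.arange(10) * 0.1, 10))
    snr_grid: np.ndarray = field(default_factory=lambda: np.arange(10, 101, 10.0))
    n_realizations: int = 100
    n_rotations: int = 100
    seed: int = 0

    @property
    def n_records(self) -> int:
        return (
            len(self.vf_grid) * len(self.snr_grid)
            * self.n_realizations * self.n_rotations
        )

    def subset(self, vf_grid=None, snr_grid=None, n_realizations=None,
               n_rotations=None) -> "SimulationScenario":
        """Same ground truth on a reduced grid (seeding stays per-cell)."""
        return SimulationScenario(
            name=self.name, evals=self.evals, s0_wm=self.s0_wm,
            s0_csf=self.s0_csf,
            vf_grid=np.atleast_1d(vf_grid if vf_grid is not None else self.vf_grid),
            snr_grid=np.atleast_1d(snr_grid if snr_grid is not None else self.snr_grid),
            n_realizations=n_realizations or self.n_realizations,
            n_rotations=n_rotations or self.n_rotations,
            seed=self.seed,
        )


def simulate_s0(f, s0_wm: float, s0_csf: float):
    """Unweighted signal of a voxel with tissue fraction ``f``."""
    f = np.asarray(f, dtype=float)
    return f * s0_wm + (1.0 - f) * s0_csf


def simulate_dwi(D, f: float, s0: float, scheme: GradientScheme) -> np.ndarray:
    """Noise-free signals for every volume of ``scheme`` (b0 slots = S0)."""
    out = np.empty(scheme.n_volumes)
    out[scheme.b0_mask] = s0
    out[scheme.dwi_mask] = s0 * signal_attenuation(D, f, scheme)
    return out


def add_rician_noise(signals, snr: float, s0_ref: float, rng: np.random.Generator):
    """Magnitude of the complex-Gaussian-perturbed signal.

    ``out_i = sqrt((S_i + n1)^2 + n2^2)`` with n1, n2 ~ N(0, sigma^2) and
    ``sigma = s0_ref / snr``.
    """
    if snr <= 0:
        raise ValueError("SNR must be positive")
    signals = np.asarray(signals, dtype=float)
    sigma = s0_ref / snr
    n1 = rng.normal(0.0, sigma, signals.shape)
    n2 = rng.normal(0.0, sigma, signals.shape)
    return np.sqrt((signals + n1) ** 2 + n2**2)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Rotation matrix uniform over SO(3), via a normalized random quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def extrapolate_tissue_tensor(evals_measured, vf_assumed: float, b: float,
                              params: InitParams | None = None) -> np.ndarray:
    """Remove an assumed free-water share from measured eigenvalues.

    Treats each measured eigenvalue as the apparent diffusivity of a
    two-compartment mono-exponential mixture at tissue fraction
    ``f = 1 - vf_assumed`` and solves for the tissue diffusivity:

        lambda_tissue = -ln[(e^(-b lambda) - (1-f) e^(-b d)) / f] / b

    Returns the extrapolated eigenvalues (the tensor at VF 0).
    """
    if not 0.0 < vf_assumed < 1.0:
        raise ValueError("assumed VF must be in (0, 1)")
    d = (params or InitParams()).d
    evals = np.asarray(evals_measured, dtype=float)
    f = 1.0 - vf_assumed
    corrected = (np.exp(-b * evals) - (1.0 - f) * np.exp(-b * d)) / f
    if np.any(corrected <= 0):
        raise ValueError(
            "corrected attenuation non-positive; assumed VF too large for "
            "these eigenvalues at this b-value"
        )
    return -np.log(corrected) / b


#: Printed scenario parameters: (FA, MD mm^2/s).
_SCENARIO_FA_MD = {"A": (0.5, 7.7e-4), "C": (0.1, 5.5e-4)}
_SCENARIO_B_ASSUMED_VF = 0.15


def build_scenario(name: str, b: float = DEFAULT_B, **overrides) -> SimulationScenario:
    """Construct a named simulation scenario (A, B or C).

    Scenario B is derived from A by per-eigenvalue free-water extrapolation
    at the simulation b-value (assumed VF 0.15). Keyword overrides pass
    through to :class:`SimulationScenario` (grids, S0 references, seed).
    """
    name = name.upper()
    if name in _SCENARIO_FA_MD:
        fa, md = _SCENARIO_FA_MD[name]
        evals = tensor_eigensystem(prolate_tensor(fa, md))[0]
    elif name == "B":
        evals_a = tensor_eigensystem(prolate_tensor(*_SCENARIO_FA_MD["A"]))[0]
        evals = extrapolate_tissue_tensor(evals_a, _SCENARIO_B_ASSUMED_VF, b)
    else:
        raise ValueError(f"unknown scenario {name!r}; expected A, B or C")
    return SimulationScenario(name=name, evals=evals, **overrides)


def enumerate_grid(scenario: SimulationScenario):
    """Iterate the (vf_index, snr_index, realization, rotation) grid lazily."""
    return itertools.product(
        range(len(scenario.vf_grid)), range(len(scenario.snr_grid)),
        range(scenario.n_realizations), range(scenario.n_rotations),
    )


@dataclass
class SimulatedRecords:
    """Flat arrays of simulated records with their ground truth."""

    vf: np.ndarray           # true free-water volume fraction
    snr: np.ndarray
    realization: np.ndarray
    rotation: np.ndarray
    signals: np.ndarray      # (n_records, n_volumes), noisy
    scheme: GradientScheme
    scenario: SimulationScenario

    @property
    def f(self) -> np.ndarray:
        """True tissue fraction."""
        return 1.0 - self.vf

    @property
    def n_records(self) -> int:
        return self.signals.shape[0]


def _cell_rng(seed: int, ivf: int, isnr: int, irep: int, irot: int):
    """Independent, reproducible stream per grid cell."""
    return np.random.default_rng(
        np.random.SeedSequence((int(seed), ivf, isnr, irep, irot))
    )


def run_simulation(scenario: SimulationScenario, scheme: GradientScheme | None = None,
                   seed: int | None = None) -> SimulatedRecords:
    """Generate noisy signals for every cell of the scenario grid.

    Each (VF, SNR, realization, rotation) cell draws its rotation and noise
    from an independent seeded stream, so any sub-grid reproduces the same
    records as the full grid. Noise sigma is ``S0_WM / SNR``.
    """
    scheme = scheme or make_scheme(DEFAULT_B, DEFAULT_N_DIRS)
    seed = scenario.seed if seed is None else seed
    D0 = tensor_from_eigensystem(scenario.evals)
    n = scenario.n_records
    vf_arr = np.empty(n)
    snr_arr = np.empty(n)
    rep_arr = np.empty(n, dtype=np.int32)
    rot_arr = np.empty(n, dtype=np.int32)
    signals = np.empty((n, scheme.n_volumes))
    for k, (ivf, isnr, irep, irot) in enumerate(enumerate_grid(scenario)):
        vf = float(scenario.vf_grid[ivf])
        snr = float(scenario.snr_grid[isnr])
        rng = _cell_rng(seed, ivf, isnr, irep, irot)
        R = random_rotation(rng)
        D = R @ D0 @ R.T
        f = 1.0 - vf
        s0 = simulate_s0(f, scenario.s0_wm, scenario.s0_csf)
        clean = simulate_dwi(D, f, s0, scheme)
        vf_arr[k], snr_arr[k] = vf, snr
        rep_arr[k], rot_arr[k] = irep, irot
        signals[k] = add_rician_noise(clean, snr, scenario.s0_wm, rng)
    return SimulatedRecords(
        vf=vf_arr, snr=snr_arr, realization=rep_arr, rotation=rot_arr,
        signals=signals, scheme=scheme, scenario=scenario,
    )


def make_phantom(vf_volume, evals, scheme: GradientScheme,
                 snr: float | None = None, s0_wm: float = DEFAULT_S0_WM,
                 s0_csf: float = DEFAULT_S0_CSF, seed: int = 0):
    """Pack a ground-truth VF field into a 4-D DWI volume.

    Every voxel shares the tissue tensor built from ``evals`` (principal
    axis x); ``vf_volume`` gives the per-voxel free-water volume fraction.
    ``snr=None`` produces noise-free data.

    Returns ``(dwi, truth)`` where truth maps hold the true FW and tissue
    fraction.
    """
    vf = np.asarray(vf_volume, dtype=float)
    if np.any((vf < 0) | (vf > 1)):
        raise ValueError("VF field must lie in [0, 1]")
    D = tensor_from_eigensystem(np.asarray(evals, dtype=float))
    f = 1.0 - vf
    s0 = simulate_s0(f, s0_wm, s0_csf)
    att = np.empty(vf.shape + (scheme.n_directions,))
    # attenuation is affine in f: one evaluation at f=0 and f=1 suffices
    a1 = signal_attenuation(D, 1.0, scheme)
    a0 = signal_attenuation(D, 0.0, scheme)
    att = f[..., None] * a1 + (1.0 - f[..., None]) * a0
    dwi = np.empty(vf.shape + (scheme.n_volumes,))
    dwi[..., scheme.b0_mask] = s0[..., None]
    dwi[..., scheme.dwi_mask] = s0[..., None] * att
    if snr is not None:
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0)))
        dwi = add_rician_noise(dwi, snr, s0_wm, rng)
    truth = {"fw": vf, "f": f, "s0": s0}
    return dwi, truth
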