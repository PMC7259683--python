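"""Interpolated initialization of the tissue volume fraction (FERNET).

Fitting the two-compartment model to single-shell data has infinitely many
solutions, so the gradient-descent fit inherits most of its behavior from its
starting point. This module computes that starting point two ways and blends
them:

``f_b0``
    scales the unweighted signal S0 between a white-matter reference ``S_t``
    (5th percentile of S0 in a WM region) and a CSF reference ``S_w``
    (95th percentile in a CSF region):
    ``f_b0 = 1 - log(S0/S_t) / log(S_w/S_t)``.

``f_MD``
    maps the mean diffusivity of the standard single-tensor fit onto a
    fraction via the mono-exponential mixture at the shell b-value:
    ``f_MD = (exp(-b MD) - exp(-b d)) / (exp(-b MD_tissue) - exp(-b d))``.

``f_init``
    the geometric (logarithmic) interpolation ``f_b0^(1-alpha) * f_MD^alpha``
    where ``alpha`` is the unclamped ``f_b0`` value restricted to [0, 1]: a
    voxel whose S0 looks like normal WM (S0 ~ S_t) trusts ``f_MD``; a voxel
    that looks like CSF (S0 ~ S_w) trusts ``f_b0``; intermediate T2 signal
    (edema, partial volume) lands near the geometric mean.

Per-voxel feasibility bounds ``[f_min, f_max]`` are derived from the extreme
attenuations and a putative diffusivity range of brain tissue; all fraction
maps are clamped into these bounds (out-of-range values move to the nearest
bound). The prior "b0 initialization" (``f_init = f_b0`` with out-of-range
values replaced by the bound midpoint) is kept as a comparison baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .tensor import (
    FREE_WATER_DIFFUSIVITY,
    SIGNAL_EPS,
    compute_attenuation,
    fa_md,
    fit_standard_tensor,
    fit_tensor_from_attenuations,
    tensor_eigensystem,
)

#: Lower clamp on fraction maps; keeps the geometric interpolation and the
#: 1/f attenuation correction finite (the formulas are undefined at 0).
EPS_F = 1e-4


@dataclass(frozen=True)
class InitParams:
    """Fixed model constants and reference signals of the initialization.

    Attributes
    ----------
    d : free-water diffusivity, mm^2/s.
    lambda_min, lambda_max : putative range of tissue diffusivities
        (radial/axial WM diffusivity), mm^2/s; define the per-voxel
        feasibility bounds on the tissue fraction.
    md_tissue : expected MD of a WM voxel free of partial volume or
        pathology, mm^2/s.
    s_t, s_w : reference unweighted signals of tissue and free water
        (scanner units); set from WM/CSF regions via
        :func:`reference_signals`.
    """

    d: float = FREE_WATER_DIFFUSIVITY
    lambda_min: float = 0.1e-3
    lambda_max: float = 2.5e-3
    md_tissue: float = 0.60e-3
    s_t: float | None = None
    s_w: float | None = None

    def __post_init__(self):
        if not 0 < self.lambda_min < self.lambda_max < self.d:
            raise ValueError("need 0 < lambda_min < lambda_max < d")
        if self.s_t is not None and self.s_w is not None and not (
            0 < self.s_t < self.s_w
        ):
            raise ValueError("need 0 < S_t < S_w (check WM/CSF reference masks)")

    def with_references(self, s_t: float, s_w: float) -> "InitParams":
        return replace(self, s_t=float(s_t), s_w=float(s_w))


@dataclass
class FractionMaps:
    """Per-voxel fraction maps produced by the initialization (audit output)."""

    f_b0: np.ndarray        # bounds-clamped S0-scaling fraction
    f_md: np.ndarray        # MD-derived fraction, clamped to [EPS_F, 1]
    alpha: np.ndarray       # interpolation weight in [0, 1]
    f_min: np.ndarray
    f_max: np.ndarray
    f_init: np.ndarray      # final initialization, in [f_min, f_max]
    md: np.ndarray = field(default=None)  # standard-fit MD used for f_md


def reference_signals(s0_map, wm_mask, csf_mask) -> tuple[float, float]:
    """Reference unweighted signals from WM and CSF regions.

    ``S_t`` is the 5th percentile of S0 over the WM mask, ``S_w`` the 95th
    percentile over the CSF mask. Rejects empty masks and ``S_t >= S_w``
    (a symptom of badly placed reference regions).
    """
    s0_map = np.asarray(s0_map, dtype=float)
    wm = np.asarray(wm_mask, dtype=bool)
    csf = np.asarray(csf_mask, dtype=bool)
    if not wm.any():
        raise ValueError("WM reference mask is empty")
    if not csf.any():
        raise ValueError("CSF reference mask is empty")
    s_t = float(np.percentile(s0_map[wm], 5))
    s_w = float(np.percentile(s0_map[csf], 95))
    if s_t >= s_w:
        raise ValueError(
            f"S_t ({s_t:g}) >= S_w ({s_w:g}); WM/CSF reference regions look "
            "misplaced or the S0 image is not intensity-consistent"
        )
    return s_t, s_w


def f_b0_raw(s0_map, s_t: float, s_w: float) -> np.ndarray:
    """Unclamped S0-scaling fraction ``1 - log(S0/S_t)/log(S_w/S_t)``."""
    s0 = np.clip(np.asarray(s0_map, dtype=float), SIGNAL_EPS, None)
    return 1.0 - np.log(s0 / s_t) / np.log(s_w / s_t)


def f_b0_map(s0_map, s_t, s_w, f_min_map, f_max_map) -> np.ndarray:
    """S0-scaling fraction clamped to the per-voxel bounds (nearest bound)."""
    return np.clip(f_b0_raw(s0_map, s_t, s_w), f_min_map, f_max_map)


def f_bounds(att: np.ndarray, b: float, params: InitParams) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel tissue-fraction bounds from the extreme attenuations.

    The smallest attenuation bounds the fraction from below assuming the
    largest plausible tissue diffusivity, and vice versa:

        f_min = (min(A) - e^(-bd)) / (e^(-b lambda_max) - e^(-bd))
        f_max = (max(A) - e^(-bd)) / (e^(-b lambda_min) - e^(-bd))

    Both are clamped to [EPS_F, 1] and ordered so f_min <= f_max.
    ``att`` is (..., n_directions).
    """
    att = np.asarray(att, dtype=float)
    e_d = np.exp(-b * params.d)
    lo = (att.min(axis=-1) - e_d) / (np.exp(-b * params.lambda_max) - e_d)
    hi = (att.max(axis=-1) - e_d) / (np.exp(-b * params.lambda_min) - e_d)
    lo = np.clip(lo, EPS_F, 1.0)
    hi = np.clip(hi, EPS_F, 1.0)
    return np.minimum(lo, hi), np.maximum(lo, hi)


def f_md_map(md_map, b: float, params: InitParams) -> np.ndarray:
    """MD-derived fraction, clamped to [EPS_F, 1].

    MD is the mean diffusivity of the standard single-tensor fit; partial
    free-water volume inflates it toward ``d``, which this map inverts under
    an isotropic mono-exponential mixture assumption.
    """
    md = np.asarray(md_map, dtype=float)
    e_d = np.exp(-b * params.d)
    f = (np.exp(-b * md) - e_d) / (np.exp(-b * params.md_tissue) - e_d)
    return np.clip(f, EPS_F, 1.0)


def interpolated_init(f_b0, f_md, alpha, f_min=None, f_max=None) -> np.ndarray:
    """Geometric interpolation ``f_b0^(1-alpha) * f_md^alpha``.

    If bounds are given, the result is clamped into [f_min, f_max].
    """
    f_init = np.asarray(f_b0, float) ** (1.0 - np.asarray(alpha, float)) * (
        np.asarray(f_md, float) ** np.asarray(alpha, float)
    )
    if f_min is not None:
        f_init = np.clip(f_init, f_min, f_max)
    return f_init


def corrected_tensor_init(att, f_init, scheme, params: InitParams | None = None) -> np.ndarray:
    """Initial free-water-corrected tissue tensor.

    Removes the free-water term from the attenuations at the initial
    fraction, ``A_t = (A - (1 - f) e^(-bd)) / f`` clipped to (eps, 1], and
    fits a single tensor to the result.

    Returns (..., 6) lower-triangular tensor components.
    """
    params = params or InitParams()
    att = np.asarray(att, dtype=float)
    f = np.asarray(f_init, dtype=float)[..., None]
    b = scheme.shell_b
    att_tissue = (att - (1.0 - f) * np.exp(-b * params.d)) / f
    att_tissue = np.clip(att_tissue, SIGNAL_EPS, 1.0)
    return fit_tensor_from_attenuations(att_tissue, scheme)


def compute_initialization(
    signals, scheme, s_t: float, s_w: float,
    params: InitParams | None = None, mode: str = "fernet",
) -> tuple[FractionMaps, np.ndarray]:
    """Full initialization pipeline for an array of voxels.

    Parameters
    ----------
    signals : (..., n_volumes) array
        Raw signals including b0 volumes (bias-corrected S0 assumed).
    s_t, s_w : reference unweighted signals from :func:`reference_signals`.
    mode : 'fernet' (interpolated) or 'b0' (baseline: ``f_init = f_b0`` with
        out-of-range values replaced by the bound midpoint).

    Returns
    -------
    maps : FractionMaps
    d_init : (..., 6) initial corrected tissue tensors
    """
    if mode not in ("fernet", "b0"):
        raise ValueError(f"unknown init mode {mode!r}")
    params = (params or InitParams()).with_references(s_t, s_w)
    signals = np.asarray(signals, dtype=float)
    b = scheme.shell_b
    s0 = signals[..., scheme.b0_mask].mean(axis=-1)
    att = compute_attenuation(signals, scheme)

    f_min, f_max = f_bounds(att, b, params)
    raw = f_b0_raw(s0, s_t, s_w)
    alpha = np.clip(raw, 0.0, 1.0)
    fb0 = np.clip(raw, f_min, f_max)

    dtensor, _ = fit_standard_tensor(signals, scheme)
    md = tensor_eigensystem(dtensor)[0].mean(axis=-1)
    fmd = f_md_map(md, b, params)

    if mode == "fernet":
        f_init = interpolated_init(fb0, fmd, alpha, f_min, f_max)
    else:
        mid = 0.5 * (f_min + f_max)
        f_init = np.where((raw < f_min) | (raw > f_max), mid, raw)

    maps = FractionMaps(
        f_b0=fb0, f_md=fmd, alpha=alpha,
        f_min=f_min, f_max=f_max, f_init=f_init, md=md,
    )
    d_init = corrected_tensor_init(att, f_init, scheme, params)
    return maps, d_init
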