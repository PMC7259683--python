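"""Diffusion-tensor algebra and the bi-compartment signal model.

Conventions used throughout the package:

* diffusivities in mm^2/s, b-values in s/mm^2 (so ``b * lambda`` is O(1));
* symmetric tensors stored as 6 lower-triangular components in the fixed
  order ``(Dxx, Dxy, Dyy, Dxz, Dyz, Dzz)`` — also the order used for
  6-volume NIfTI tensor maps;
* the free-water compartment is isotropic with diffusivity
  :data:`FREE_WATER_DIFFUSIVITY`, and ``f`` always denotes the *tissue*
  volume fraction (free-water fraction = ``1 - f``).

The two-compartment attenuation model for the i-th weighted direction is

    A_i(D, f) = f * exp(-b q_i^T D q_i) + (1 - f) * exp(-b d)

with ``D`` the tissue tensor and ``d`` the free-water diffusivity.
"""

from __future__ import annotations

import numpy as np

#: Diffusivity of free water in tissue at body temperature, mm^2/s.
FREE_WATER_DIFFUSIVITY = 3.0e-3

#: Floor applied to normalized signals before any logarithm.
SIGNAL_EPS = 1e-8

#: (row, col) index pairs of the lower-triangular storage order.
LOWER_TRI_INDICES = [(0, 0), (1, 0), (1, 1), (2, 0), (2, 1), (2, 2)]

_ROWS = np.array([ij[0] for ij in LOWER_TRI_INDICES])
_COLS = np.array([ij[1] for ij in LOWER_TRI_INDICES])


def from_lower_tri(comps: np.ndarray) -> np.ndarray:
    """(..., 6) lower-triangular components -> (..., 3, 3) symmetric matrices."""
    comps = np.asarray(comps, dtype=float)
    out = np.zeros(comps.shape[:-1] + (3, 3))
    out[..., _ROWS, _COLS] = comps
    out[..., _COLS, _ROWS] = comps
    return out


def to_lower_tri(mats: np.ndarray) -> np.ndarray:
    """(..., 3, 3) symmetric matrices -> (..., 6) lower-triangular components."""
    mats = np.asarray(mats, dtype=float)
    return mats[..., _ROWS, _COLS]


def tensor_eigensystem(D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (descending) and matching eigenvectors of symmetric D.

    Parameters
    ----------
    D : (..., 3, 3) or (..., 6) array
        Symmetric tensor(s); the 6-vector form uses the package's
        lower-triangular order.

    Returns
    -------
    evals : (..., 3) array, sorted ``lambda1 >= lambda2 >= lambda3``
    evecs : (..., 3, 3) array, ``evecs[..., :, k]`` pairs with ``evals[..., k]``
    """
    D = np.asarray(D, dtype=float)
    if D.shape[-1] == 6 and (D.ndim == 1 or D.shape[-2:] != (3, 3)):
        D = from_lower_tri(D)
    evals, evecs = np.linalg.eigh(D)
    return evals[..., ::-1], evecs[..., :, ::-1]


def fa_md(evals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fractional anisotropy and mean diffusivity from eigenvalues.

    MD = (l1 + l2 + l3) / 3;  FA = sqrt(3/2) * ||l - MD|| / ||l||.
    An all-zero eigenvalue triple yields FA = 0 by convention.
    """
    evals = np.asarray(evals, dtype=float)
    md = evals.mean(axis=-1)
    num = np.linalg.norm(evals - md[..., None], axis=-1)
    den = np.linalg.norm(evals, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den > 0, fa, 0.0)
    return fa, md


def prolate_tensor(fa_target: float, md_target: float, axis=(1.0, 0.0, 0.0)) -> np.ndarray:
    """Axially symmetric (prolate) tensor with prescribed FA and MD.

    Eigenvalues are ``l1 = MD (1 + 2 delta)``, ``l2 = l3 = MD (1 - delta)``
    with ``delta >= 0`` solving ``FA(delta) = 3 delta / sqrt(3 + 6 delta^2)``,
    i.e. ``delta = FA * sqrt(3 / (9 - 6 FA^2))``. The principal axis is
    aligned with ``axis``.

    Returns the (3, 3) tensor.
    """
    fa_target = float(fa_target)
    md_target = float(md_target)
    if not 0.0 <= fa_target < 1.0:
        raise ValueError(f"FA target must be in [0, 1), got {fa_target}")
    if md_target <= 0:
        raise ValueError("MD target must be positive")
    delta = fa_target * np.sqrt(3.0 / (9.0 - 6.0 * fa_target**2))
    evals = md_target * np.array([1 + 2 * delta, 1 - delta, 1 - delta])
    return tensor_from_eigensystem(evals, principal_axis=axis)


def tensor_from_eigensystem(evals, principal_axis=(1.0, 0.0, 0.0)) -> np.ndarray:
    """Build a symmetric tensor from eigenvalues and a principal axis.

    The first eigenvalue is attached to ``principal_axis``; the remaining two
    to an arbitrary orthonormal completion (unique only for prolate/oblate
    spectra up to rotation about the axis, which leaves the tensor invariant
    when the two minor eigenvalues are equal).
    """
    evals = np.asarray(evals, dtype=float)
    e1 = np.asarray(principal_axis, dtype=float)
    n = np.linalg.norm(e1)
    if not np.isclose(n, 1.0, atol=1e-6):
        raise ValueError("principal axis must be a unit vector")
    e1 = e1 / n
    helper = np.array([0.0, 0.0, 1.0]) if abs(e1[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e2 = np.cross(e1, helper)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    V = np.column_stack([e1, e2, e3])
    return V @ np.diag(evals) @ V.T


def signal_attenuation(D, f, scheme) -> np.ndarray:
    """Two-compartment attenuation for each weighted direction of ``scheme``.

    ``A_i = f exp(-b q_i^T D q_i) + (1 - f) exp(-b d)`` with ``d`` the
    free-water diffusivity. ``f`` is the tissue fraction in [0, 1].
    """
    f = float(f)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"tissue fraction must be in [0, 1], got {f}")
    D = np.asarray(D, dtype=float)
    if D.shape == (6,):
        D = from_lower_tri(D)
    q = scheme.directions
    b = scheme.bvals[scheme.dwi_mask]
    proj = np.einsum("ij,jk,ik->i", q, D, q)
    return f * np.exp(-b * proj) + (1 - f) * np.exp(-b * FREE_WATER_DIFFUSIVITY)


def design_matrix(scheme) -> np.ndarray:
    """Log-linear DTI design matrix, one row per volume (b0 rows included).

    Columns: ``[ln S0, Dxx, Dxy, Dyy, Dxz, Dyz, Dzz]`` so that
    ``ln S = X @ [ln S0, D_lower_tri]``.
    """
    b = scheme.bvals
    q = scheme.bvecs
    X = np.empty((scheme.n_volumes, 7))
    X[:, 0] = 1.0
    X[:, 1] = -b * q[:, 0] ** 2
    X[:, 2] = -2 * b * q[:, 0] * q[:, 1]
    X[:, 3] = -b * q[:, 1] ** 2
    X[:, 4] = -2 * b * q[:, 0] * q[:, 2]
    X[:, 5] = -2 * b * q[:, 1] * q[:, 2]
    X[:, 6] = -b * q[:, 2] ** 2
    return X


def fit_standard_tensor(signals: np.ndarray, scheme) -> tuple[np.ndarray, np.ndarray]:
    """Weighted linear least-squares single-tensor fit.

    Ordinary least squares on the log-signal provides an initial estimate;
    one reweighting iteration with weights equal to the squared signals
    predicted by that estimate gives the WLLS solution (standard practice for
    log-linearized DTI, where the log transform makes the noise
    heteroscedastic with variance ~ 1/S^2).

    Parameters
    ----------
    signals : (..., n_volumes) array
        Raw signals including the b0 volumes, any leading voxel shape.
        Values are floored at :data:`SIGNAL_EPS` before the logarithm.

    Returns
    -------
    dtensor : (..., 6) lower-triangular tensor components (mm^2/s)
    s0 : (...) fitted unweighted signal
    """
    signals = np.asarray(signals, dtype=float)
    if signals.shape[-1] != scheme.n_volumes:
        raise ValueError(
            f"signal count {signals.shape[-1]} != scheme volumes {scheme.n_volumes}"
        )
    X = design_matrix(scheme)
    y = np.log(np.clip(signals, SIGNAL_EPS, None))
    beta_ols = np.linalg.lstsq(X, y.reshape(-1, scheme.n_volumes).T, rcond=None)[0].T
    # one reweighting pass: w_i = predicted signal squared
    w = np.exp(2.0 * (beta_ols @ X.T))
    XtW = X.T[None, :, :] * w[:, None, :]
    A = XtW @ X
    rhs = np.einsum("vij,vj->vi", XtW, y.reshape(-1, scheme.n_volumes))
    beta = np.linalg.solve(A, rhs[..., None])[..., 0]
    beta = beta.reshape(signals.shape[:-1] + (7,))
    return beta[..., 1:], np.exp(beta[..., 0])


def fit_tensor_from_attenuations(att: np.ndarray, scheme) -> np.ndarray:
    """Single-tensor WLLS fit on attenuations (normalized signals).

    ``att`` has one entry per weighted volume; unit signals are substituted
    for the b0 slots so :func:`fit_standard_tensor` applies unchanged.

    Returns the (..., 6) lower-triangular tensor components.
    """
    att = np.asarray(att, dtype=float)
    signals = np.ones(att.shape[:-1] + (scheme.n_volumes,))
    signals[..., scheme.dwi_mask] = att
    dtensor, _ = fit_standard_tensor(signals, scheme)
    return dtensor


def compute_attenuation(signals: np.ndarray, scheme) -> np.ndarray:
    """Normalized weighted signals: S_i / mean(S_b0), clipped to (eps, 1].

    Multiple b0 volumes are averaged into a single S0 before division.
    """
    signals = np.asarray(signals, dtype=float)
    s0 = signals[..., scheme.b0_mask].mean(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        att = signals[..., scheme.dwi_mask] / s0[..., None]
    return np.clip(att, SIGNAL_EPS, 1.0)
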