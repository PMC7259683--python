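"""Constrained gradient-descent fit of the two-compartment model.

Each voxel minimizes the sum of squared attenuation residuals

    J(f, D) = sum_i (A_i_obs - f e^(-b q_i^T D q_i) - (1 - f) e^(-b d))^2

over the tissue fraction ``f`` (projected into its per-voxel feasibility
interval ``[f_min, f_max]``) and the tissue tensor ``D``. The tensor is
parameterized by its matrix logarithm (log-Euclidean coordinates), which
keeps ``D = expm(L)`` symmetric positive definite without explicit
constraints; the chain rule through the matrix exponential uses the
Daleckii-Krein divided-difference form, exact for symmetric matrices.

Descent is plain projected gradient with a backtracking (halving) line
search, so the recorded objective sequence is non-increasing by
construction. An optional spatial regularizer penalizes squared differences
of ``f`` between 6-connected neighbors and is handled by block-coordinate
sweeps: voxels are refit in turn against their neighbors' current values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .initialization import (
    EPS_F,
    FractionMaps,
    InitParams,
    compute_initialization,
    reference_signals,
)
from .tensor import (
    FREE_WATER_DIFFUSIVITY,
    compute_attenuation,
    fa_md,
    from_lower_tri,
    to_lower_tri,
    tensor_eigensystem,
)

#: Eigenvalue floor (mm^2/s) applied before the matrix logarithm; noisy
#: corrected-tensor initializations can be indefinite.
EVAL_FLOOR = 1e-6


@dataclass(frozen=True)
class FitOptions:
    """Optimizer settings.

    Attributes
    ----------
    max_iters : gradient-descent iterations per voxel.
    init_step : initial step along the normalized negative gradient.
    max_halvings : backtracking line-search halvings before giving up.
    tol : relative objective decrease declaring convergence.
    reg_weight : spatial regularization weight (0 disables it).
    outer_sweeps : block-coordinate sweeps when ``reg_weight > 0``.
    """

    max_iters: int = 100
    init_step: float = 0.1
    max_halvings: int = 20
    tol: float = 1e-8
    reg_weight: float = 0.0
    outer_sweeps: int = 5

    def __post_init__(self):
        if self.reg_weight < 0:
            raise ValueError("reg_weight must be >= 0")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")


@dataclass
class FreeWaterFit:
    """Volume-level result of the free-water elimination fit."""

    f: np.ndarray             # tissue fraction
    fw: np.ndarray            # free-water fraction = 1 - f
    tensor: np.ndarray        # corrected tissue tensor, (..., 6) lower-tri
    fa: np.ndarray            # corrected FA
    md: np.ndarray            # corrected MD (mm^2/s)
    residual: np.ndarray      # final per-voxel data objective
    converged: np.ndarray     # bool per voxel
    mask: np.ndarray
    init: FractionMaps = field(default=None)


def voxel_objective(att, scheme, f, D, params: InitParams | None = None) -> float:
    """Sum of squared attenuation residuals of the two-compartment model."""
    d = (params or InitParams()).d
    att = np.asarray(att, dtype=float)
    D = np.asarray(D, dtype=float)
    if D.shape == (6,):
        D = from_lower_tri(D)
    q = scheme.directions
    b = scheme.bvals[scheme.dwi_mask]
    proj = np.einsum("ij,jk,ik->i", q, D, q)
    r = att - f * np.exp(-b * proj) - (1 - f) * np.exp(-b * d)
    return float(r @ r)


def _log_of_spd(D: np.ndarray) -> np.ndarray:
    """Matrix logarithm of a symmetric tensor, eigenvalues floored first."""
    w, V = np.linalg.eigh(D)
    w = np.clip(w, EVAL_FLOOR, None)
    return (V * np.log(w)) @ V.T


def _expm_frechet_factor(lw: np.ndarray) -> np.ndarray:
    """Daleckii-Krein divided-difference matrix for expm at eigenvalues lw."""
    diff = lw[:, None] - lw[None, :]
    ew = np.exp(lw)
    with np.errstate(invalid="ignore", divide="ignore"):
        K = (ew[:, None] - ew[None, :]) / diff
    near = np.abs(diff) < 1e-12
    K[near] = np.exp(0.5 * (lw[:, None] + lw[None, :]))[near]
    return K


# lower-tri order (xx, xy, yy, xz, yz, zz); off-diagonals appear twice in L
_OFFDIAG = np.array([1.0, 2.0, 1.0, 2.0, 2.0, 1.0])


def fit_voxel(
    att,
    scheme,
    f_init: float,
    D_init,
    bounds: tuple[float, float],
    options: FitOptions | None = None,
    params: InitParams | None = None,
    f_prior: tuple[float, np.ndarray] | None = None,
    trace: list | None = None,
):
    """Projected gradient descent on one voxel.

    Parameters
    ----------
    att : (n_directions,) observed attenuations.
    f_init, D_init : starting point (D as (3,3) or 6-vector).
    bounds : (f_min, f_max) feasibility interval for f.
    f_prior : optional ``(weight, neighbor_values)`` adding
        ``weight * sum((f - v)^2)`` to the objective — the voxel's share of
        the spatial penalty with neighbors held fixed.
    trace : optional list; accepted objective values are appended to it
        (the line search makes this sequence non-increasing).

    Returns
    -------
    f, D6, residual, converged : final fraction, tensor (6-vector,
        lower-tri), final *data* objective, and convergence flag.
    """
    options = options or FitOptions()
    params = params or InitParams()
    att = np.asarray(att, dtype=float)
    q = scheme.directions
    b = scheme.bvals[scheme.dwi_mask]
    e_d = np.exp(-b * params.d)
    f_lo, f_hi = float(bounds[0]), float(bounds[1])

    D = np.asarray(D_init, dtype=float)
    if D.shape == (6,):
        D = from_lower_tri(D)
    L6 = to_lower_tri(_log_of_spd(D))
    f = float(np.clip(f_init, f_lo, f_hi))

    pw, pv = (0.0, None)
    if f_prior is not None:
        pw = float(f_prior[0])
        pv = np.asarray(f_prior[1], dtype=float)

    def evaluate(L6_, f_):
        L = from_lower_tri(L6_)
        lw, V = np.linalg.eigh(L)
        Dm = (V * np.exp(lw)) @ V.T
        proj = np.einsum("ij,jk,ik->i", q, Dm, q)
        et = np.exp(-b * proj)
        r = att - f_ * et - (1 - f_) * e_d
        data = float(r @ r)
        total = data if pw == 0.0 else data + pw * float(np.sum((f_ - pv) ** 2))
        return total, data, (r, et, lw, V)

    obj, data_obj, cache = evaluate(L6, f)
    if trace is not None:
        trace.append(obj)
    if not np.isfinite(obj):
        return f, to_lower_tri(D), data_obj, False

    converged = False
    for _ in range(options.max_iters):
        r, et, lw, V = cache
        # dJ/dD = 2 f sum_i b_i r_i et_i q_i q_i^T  (symmetric)
        wvec = 2.0 * f * b * r * et
        G = (q.T * wvec) @ q
        K = _expm_frechet_factor(lw)
        M = V.T @ G @ V
        gL = V @ (K * M) @ V.T
        grad_L = to_lower_tri(gL) * _OFFDIAG
        grad_f = float(-2.0 * np.sum(r * (et - e_d)))
        if pw > 0.0:
            grad_f += 2.0 * pw * float(np.sum(f - pv))

        g = np.concatenate([grad_L, [grad_f]])
        gnorm = np.linalg.norm(g)
        if not np.isfinite(gnorm):
            return f, to_lower_tri(from_lower_tri(L6)), data_obj, False
        if gnorm == 0.0:
            converged = True
            break
        direction = -g / gnorm

        t = options.init_step
        accepted = False
        for _ in range(options.max_halvings):
            L6_new = L6 + t * direction[:6]
            f_new = float(np.clip(f + t * direction[6], f_lo, f_hi))
            obj_new, data_new, cache_new = evaluate(L6_new, f_new)
            if np.isfinite(obj_new) and obj_new < obj:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            converged = True  # no descent direction left at line-search scale
            break
        rel = (obj - obj_new) / max(obj, 1e-300)
        L6, f, obj, data_obj, cache = L6_new, f_new, obj_new, data_new, cache_new
        if trace is not None:
            trace.append(obj)
        if rel < options.tol:
            converged = True
            break

    lw, V = np.linalg.eigh(from_lower_tri(L6))
    D_final = (V * np.exp(lw)) @ V.T
    return f, to_lower_tri(D_final), data_obj, converged


_SHIFTS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def _neighbor_lists(mask: np.ndarray) -> list[np.ndarray]:
    """Flat in-mask indices of the 6-neighbors of each in-mask voxel."""
    idx_vol = -np.ones(mask.shape, dtype=np.int64)
    coords = np.argwhere(mask)
    idx_vol[tuple(coords.T)] = np.arange(len(coords))
    out = []
    for c in coords:
        nbrs = []
        for s in _SHIFTS:
            p = c + s
            if np.all(p >= 0) and np.all(p < mask.shape) and mask[tuple(p)]:
                nbrs.append(idx_vol[tuple(p)])
        out.append(np.array(nbrs, dtype=np.int64))
    return out


def regularization_penalty(f_map, mask, omega: float):
    """Spatial smoothness penalty on the fraction map.

    ``omega * sum over 6-connected in-mask pairs of (f_a - f_b)^2`` and its
    gradient with respect to each in-mask voxel (zero elsewhere).
    """
    if omega < 0:
        raise ValueError("omega must be >= 0")
    f_map = np.asarray(f_map, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    penalty = 0.0
    grad = np.zeros_like(f_map)
    for axis in range(f_map.ndim):
        sl_a = [slice(None)] * f_map.ndim
        sl_b = [slice(None)] * f_map.ndim
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        sl_a, sl_b = tuple(sl_a), tuple(sl_b)
        pair = mask[sl_a] & mask[sl_b]
        diff = np.where(pair, f_map[sl_a] - f_map[sl_b], 0.0)
        penalty += float(np.sum(diff**2))
        grad[sl_a] += 2.0 * diff
        grad[sl_b] -= 2.0 * diff
    return omega * penalty, omega * grad


def fit_volume(
    dwi,
    scheme,
    brain_mask,
    wm_mask,
    csf_mask,
    init_mode: str = "fernet",
    options: FitOptions | None = None,
    params: InitParams | None = None,
) -> FreeWaterFit:
    """Fit the two-compartment model over a masked 4-D volume.

    Runs the selected initialization, then per-voxel projected gradient
    descent; with ``options.reg_weight > 0`` the voxels are refit in
    block-coordinate sweeps against the spatial smoothness penalty.

    Parameters
    ----------
    dwi : (X, Y, Z, n_volumes) array of raw signals.
    brain_mask, wm_mask, csf_mask : boolean volumes; the WM and CSF masks
        provide the reference unweighted signals.
    init_mode : 'fernet' or 'b0'.
    """
    options = options or FitOptions()
    params = params or InitParams()
    dwi = np.asarray(dwi, dtype=float)
    brain = np.asarray(brain_mask, dtype=bool)
    if dwi.shape[-1] != scheme.n_volumes:
        raise ValueError("DWI volume count does not match the gradient table")

    s0_map = dwi[..., scheme.b0_mask].mean(axis=-1)
    s_t, s_w = reference_signals(s0_map, wm_mask, csf_mask)

    vox_signals = dwi[brain]                      # (n_vox, n_volumes)
    maps, d_init = compute_initialization(
        vox_signals, scheme, s_t, s_w, params=params, mode=init_mode
    )
    att = compute_attenuation(vox_signals, scheme)
    n_vox = vox_signals.shape[0]

    f_cur = maps.f_init.copy()
    D_cur = d_init.copy()
    resid = np.zeros(n_vox)
    conv = np.zeros(n_vox, dtype=bool)

    unreg = FitOptions(
        max_iters=options.max_iters, init_step=options.init_step,
        max_halvings=options.max_halvings, tol=options.tol,
    )

    def sweep(prior_weight: float):
        nbrs = _neighbor_lists(brain) if prior_weight > 0 else None
        for v in range(n_vox):
            prior = None
            if prior_weight > 0 and nbrs[v].size:
                prior = (prior_weight, f_cur[nbrs[v]])
            f_cur[v], D_cur[v], resid[v], conv[v] = fit_voxel(
                att[v], scheme, f_cur[v], D_cur[v],
                (maps.f_min[v], maps.f_max[v]),
                options=unreg, params=params, f_prior=prior,
            )

    if options.reg_weight > 0:
        for _ in range(options.outer_sweeps):
            sweep(options.reg_weight)
    else:
        sweep(0.0)

    def unflatten(values, fill=0.0):
        out = np.full(brain.shape + values.shape[1:], fill, dtype=values.dtype)
        out[brain] = values
        return out

    evals = tensor_eigensystem(D_cur)[0]
    fa_v, md_v = fa_md(evals)
    return FreeWaterFit(
        f=unflatten(f_cur),
        fw=unflatten(1.0 - f_cur) * brain,
        tensor=unflatten(D_cur),
        fa=unflatten(fa_v),
        md=unflatten(md_v),
        residual=unflatten(resid),
        converged=unflatten(conv, fill=False),
        mask=brain,
        init=FractionMaps(
            f_b0=unflatten(maps.f_b0), f_md=unflatten(maps.f_md),
            alpha=unflatten(maps.alpha), f_min=unflatten(maps.f_min),
            f_max=unflatten(maps.f_max), f_init=unflatten(maps.f_init),
            md=unflatten(maps.md),
        ),
    )


def fit_records(records, init_mode: str = "fernet",
                options: FitOptions | None = None,
                params: InitParams | None = None) -> np.ndarray:
    """Estimate free water for simulated records, one isolated voxel each.

    The simulation's reference intensities stand in for the WM/CSF
    percentile references (``S_t = S0_WM``, ``S_w = S0_CSF``), since the
    records carry no spatial context to draw reference regions from.

    Returns the estimated free-water fraction ``1 - f`` per record.
    """
    options = options or FitOptions()
    params = params or InitParams()
    scheme = records.scheme
    scen = records.scenario
    maps, d_init = compute_initialization(
        records.signals, scheme, scen.s0_wm, scen.s0_csf,
        params=params, mode=init_mode,
    )
    att = compute_attenuation(records.signals, scheme)
    fw = np.empty(records.n_records)
    for v in range(records.n_records):
        f, _, _, _ = fit_voxel(
            att[v], scheme, maps.f_init[v], d_init[v],
            (maps.f_min[v], maps.f_max[v]), options=options, params=params,
        )
        fw[v] = 1.0 - f
    return fw
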