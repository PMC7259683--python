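"""Gradient tables for single-shell diffusion acquisitions.

A :class:`GradientScheme` holds the per-volume b-values and unit gradient
directions of a diffusion acquisition and enforces the single-shell contract
this package relies on: one nonzero shell, at least one unweighted (b=0)
volume, and at least six distinct weighted directions (a tensor fit is
otherwise underdetermined).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: b-values below this (s/mm^2) are treated as unweighted volumes.
B0_THRESHOLD = 50.0

#: bvec norms inside [0.95, 1.05] are renormalized; anything else is rejected.
_NORM_SLACK = 0.05


@dataclass(frozen=True)
class GradientScheme:
    """b-values and unit gradient directions of a single-shell acquisition.

    Parameters
    ----------
    bvals : (N,) array
        Diffusion weighting per volume, s/mm^2.
    bvecs : (N, 3) array
        Unit gradient directions, image coordinate frame (FSL dialect).
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    shell_b: float = field(init=False)

    def __post_init__(self):
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.atleast_2d(np.asarray(self.bvecs, dtype=float))
        if bvecs.shape == (3, bvals.size) and bvals.size != 3:
            bvecs = bvecs.T
        if bvecs.shape != (bvals.size, 3):
            raise ValueError(
                f"bvecs shape {bvecs.shape} does not match {bvals.size} bvals"
            )
        dwi = bvals > B0_THRESHOLD
        if not np.any(~dwi):
            raise ValueError("gradient table has no b=0 volume")
        norms = np.linalg.norm(bvecs[dwi], axis=1)
        bad = (norms < 1 - _NORM_SLACK) | (norms > 1 + _NORM_SLACK)
        if np.any(bad):
            raise ValueError(
                f"{bad.sum()} weighted directions have norm outside "
                f"[{1 - _NORM_SLACK}, {1 + _NORM_SLACK}]"
            )
        bvecs = bvecs.copy()
        bvecs[dwi] /= norms[:, None]
        # distinct up to sign (q and -q probe the same tensor projection)
        dirs = bvecs[dwi]
        canon = dirs * np.sign(dirs[:, [np.argmax(np.abs(dirs).max(0))]] + 1e-300)
        distinct = np.unique(np.round(canon, 6), axis=0).shape[0]
        if distinct < 6:
            raise ValueError(
                f"only {distinct} distinct weighted directions; need >= 6"
            )
        shells = np.unique(np.round(bvals[dwi], 6))
        shell_b = float(np.median(bvals[dwi]))
        if np.any(np.abs(bvals[dwi] - shell_b) > 0.01 * shell_b):
            raise ValueError(
                f"multiple shells detected (b values {sorted(shells)}); "
                "this package models single-shell data only"
            )
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)
        object.__setattr__(self, "shell_b", shell_b)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals <= B0_THRESHOLD

    @property
    def dwi_mask(self) -> np.ndarray:
        return self.bvals > B0_THRESHOLD

    @property
    def n_volumes(self) -> int:
        return self.bvals.size

    @property
    def n_directions(self) -> int:
        return int(self.dwi_mask.sum())

    @property
    def directions(self) -> np.ndarray:
        """Unit directions of the weighted volumes, (n_directions, 3)."""
        return self.bvecs[self.dwi_mask]


def read_gradient_table(bval_path, bvec_path) -> GradientScheme:
    """Read an FSL-style .bval/.bvec pair.

    bvals: whitespace-separated scalars; bvecs: 3 rows x N columns (the
    transposed N x 3 layout is also accepted). Directions with norm in
    [0.95, 1.05] are renormalized, anything else rejected.
    """
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.ndim != 2:
        raise ValueError(f"cannot parse bvec file {bvec_path!r}")
    if bvecs.shape[0] == 3 and bvecs.shape[1] == bvals.size:
        bvecs = bvecs.T
    if bvecs.shape != (bvals.size, 3):
        raise ValueError(
            f"bvec shape {bvecs.shape} inconsistent with {bvals.size} bvals"
        )
    return GradientScheme(bvals=bvals, bvecs=bvecs)


def write_gradient_table(scheme: GradientScheme, bval_path, bvec_path) -> None:
    """Write an FSL-style .bval/.bvec pair (bvecs as 3 rows x N columns)."""
    np.savetxt(bval_path, scheme.bvals[None, :], fmt="%.1f")
    np.savetxt(bvec_path, scheme.bvecs.T, fmt="%.8f")


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """Quasi-uniform points on the upper unit hemisphere."""
    i = np.arange(n) + 0.5
    z = i / n                       # upper hemisphere only
    phi = np.pi * (1 + 5**0.5) * i
    r = np.sqrt(1 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def dispersed_directions(n: int, n_iter: int = 200) -> np.ndarray:
    """Deterministic electrostatic-repulsion direction set.

    Starts from a Fibonacci hemisphere layout and relaxes the points under
    antipodally symmetric Coulomb repulsion (each point interacts with every
    other point and its antipode), projecting back to the sphere each step.
    """
    p = _fibonacci_hemisphere(n)
    step = 0.01
    for _ in range(n_iter):
        force = np.zeros_like(p)
        for sign in (1.0, -1.0):
            diff = p[:, None, :] - sign * p[None, :, :]
            dist2 = np.einsum("ijk,ijk->ij", diff, diff)
            np.fill_diagonal(dist2, np.inf)
            dist2[dist2 < 1e-12] = np.inf
            force += np.einsum("ij,ijk->ik", dist2**-1.5, diff)
        # tangential component only
        force -= np.einsum("ik,ik->i", force, p)[:, None] * p
        p = p + step * force / n
        p /= np.linalg.norm(p, axis=1, keepdims=True)
    return p


def make_scheme(b: float = 800.0, n_dirs: int = 30, n_b0: int = 1) -> GradientScheme:
    """Build a synthetic single-shell scheme with dispersed directions."""
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_dirs, float(b))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dispersed_directions(n_dirs)])
    return GradientScheme(bvals=bvals, bvecs=bvecs)
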