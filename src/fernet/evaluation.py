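"""Error summaries, agreement metrics, and fit-quality diagnostics.

Sign convention: the free-water estimation error is ``estimate - truth``
(positive = overestimated free water). Standard deviations are sample
(n-1) throughout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Corrected-tensor MD below this (mm^2/s) marks an implausible fit.
IMPLAUSIBLE_MD_THRESHOLD = 0.40e-3

_QUANTILES = (0.05, 0.25, 0.5, 0.75, 0.95)


def fw_error_summary(estimates, truths, groups=None) -> pd.DataFrame:
    """Grouped moments and quantiles of the signed free-water error.

    Parameters
    ----------
    estimates, truths : equal-length vectors of free-water fractions.
    groups : optional mapping of key name -> per-record values (e.g.
        ``{"vf": ..., "snr": ...}``); omitted -> one global row.

    Returns
    -------
    DataFrame with one row per group: mean, std (sample), skewness,
    quantiles, and count of the signed error ``estimate - truth``.
    """
    estimates = np.asarray(estimates, dtype=float).ravel()
    truths = np.asarray(truths, dtype=float).ravel()
    if estimates.shape != truths.shape:
        raise ValueError(
            f"length mismatch: {estimates.shape} estimates vs "
            f"{truths.shape} truths"
        )
    err = estimates - truths
    frame = pd.DataFrame({"error": err})
    keys = []
    if groups:
        for name, values in groups.items():
            values = np.asarray(values).ravel()
            if values.shape != err.shape:
                raise ValueError(f"group {name!r} length mismatch")
            frame[name] = values
            keys.append(name)
    else:
        frame["_all"] = 0
        keys = ["_all"]

    def summarize(s: pd.Series) -> pd.Series:
        out = {
            "mean": s.mean(),
            "std": s.std(ddof=1),
            "skew": s.skew(),
            "count": s.size,
        }
        for q in _QUANTILES:
            out[f"q{int(q * 100):02d}"] = s.quantile(q)
        return pd.Series(out)

    result = frame.groupby(keys)["error"].apply(summarize).unstack()
    result["count"] = result["count"].astype(int)
    if not groups:
        result.index = ["all"]
    return result.reset_index() if groups else result


def voxelwise_agreement(stack_a, stack_b):
    """Per-voxel Pearson correlation and MSE between two map stacks.

    Stacks are (n_subjects, ...) arrays of co-registered maps; correlation
    is computed across subjects independently at each voxel. Voxels where
    either stack has zero variance get NaN correlation.
    """
    a = np.asarray(stack_a, dtype=float)
    b = np.asarray(stack_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("stacks must have identical shapes")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 subjects for voxelwise correlation")
    n = a.shape[0]
    am = a - a.mean(axis=0)
    bm = b - b.mean(axis=0)
    cov = (am * bm).sum(axis=0)
    va = (am**2).sum(axis=0)
    vb = (bm**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / np.sqrt(va * vb)
    corr = np.where((va > 0) & (vb > 0), corr, np.nan)
    mse = ((a - b) ** 2).mean(axis=0)
    return corr, mse


def implausible_fraction(md_maps, mask, threshold: float = IMPLAUSIBLE_MD_THRESHOLD):
    """Share of implausible corrected-tensor fits (MD below threshold).

    With a (n_subjects, ...) stack, returns a percentage map: per voxel,
    100 x (subjects with MD < threshold) / n_subjects, restricted to the
    mask (NaN outside). With a single map, returns the scalar in-mask
    percentage.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    md = np.asarray(md_maps, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if md.shape == mask.shape:
        return 100.0 * float(np.mean(md[mask] < threshold))
    if md.shape[1:] != mask.shape:
        raise ValueError("MD stack shape does not match mask")
    pct = 100.0 * (md < threshold).mean(axis=0)
    return np.where(mask, pct, np.nan)


def histogram_tv_distance(values_a, values_b, bins: int = 50,
                          value_range=(0.0, 1.0)) -> float:
    """Total-variation distance between two value histograms.

    Used as the regularization-sensitivity metric: free-water maps fit with
    and without the spatial penalty are compared as normalized histograms
    (default 50 bins on [0, 1]); TV = 0.5 * sum |p - q| in [0, 1].
    """
    a = np.asarray(values_a, dtype=float).ravel()
    b = np.asarray(values_b, dtype=float).ravel()
    pa, _ = np.histogram(a, bins=bins, range=value_range)
    pb, _ = np.histogram(b, bins=bins, range=value_range)
    pa = pa / max(pa.sum(), 1)
    pb = pb / max(pb.sum(), 1)
    return 0.5 * float(np.abs(pa - pb).sum())


def plot_error_violins(summary_frame, ax=None):  # pragma: no cover - visual aid
    """Violin-style visualization of grouped FW errors (optional helper).

    Requires matplotlib; intended for human inspection of simulation runs,
    mirroring the grouped-by-VF violin layout used to present estimation
    error distributions.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = np.arange(len(summary_frame))
    ax.errorbar(x, summary_frame["mean"], yerr=summary_frame["std"], fmt="o")
    ax.axhline(0.0, color="green", ls=":")
    ax.set_xlabel("group")
    ax.set_ylabel("FW error (estimate - truth)")
    return ax
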