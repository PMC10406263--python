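"""Map-level utilities: ΔS ratio maps, threshold segmentation, regression.

These operate on 3D parameter maps (ΔS, ε_t, MTT, rCBV) such as those
produced by :func:`dscsim.analyze.analyze_volume`.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

__all__ = [
    "delta_s_ratio_maps",
    "threshold_segmentation",
    "map_regression",
    "average_maps",
]

#: separable 3x3 binomial (Gaussian) smoothing kernel
_K3 = np.array([1.0, 2.0, 1.0]) / 4.0


def delta_s_ratio_maps(
    delta_s_gd: np.ndarray,
    delta_s_dohb: np.ndarray,
    labels: np.ndarray | None = None,
    eps: float = 1e-9,
):
    """Voxel-wise ΔS_dOHb / ΔS_Gd map, masking voxels with no Gd response.

    If ``labels`` (integer region codes) is given, also return the mean
    ratio per region code.
    """
    if delta_s_gd.shape != delta_s_dohb.shape:
        raise ValueError("maps must share a grid")
    ratio = np.full(delta_s_gd.shape, np.nan)
    ok = np.isfinite(delta_s_gd) & np.isfinite(delta_s_dohb) & (delta_s_gd > eps)
    ratio[ok] = delta_s_dohb[ok] / delta_s_gd[ok]
    if labels is None:
        return ratio, {}
    summary = {}
    for code in np.unique(labels[labels > 0]):
        sel = (labels == code) & ok
        summary[int(code)] = float(np.nanmean(ratio[sel])) if sel.any() else np.nan
    return ratio, summary


def _range_threshold(values: np.ndarray, frac: float, side: str) -> np.ndarray:
    lo, hi = values.min(), values.max()
    span = hi - lo
    if side == "low":
        return values <= lo + frac * span
    return values >= lo + frac * span


def threshold_segmentation(
    delta_s_map: np.ndarray,
    noise_map: np.ndarray,
    mtt_map: np.ndarray,
    wm_low_frac: float = 0.20,
    gm_high_frac: float = 0.75,
    noise_low_frac: float = 0.10,
    mtt_low_frac: float = 0.70,
    robust_percentiles: tuple = (2.0, 98.0),
):
    """Range-threshold GM/WM segmentation with noise and MTT masking.

    WM voxels fall in the lowest ``wm_low_frac`` of the ΔS data range; GM
    voxels in the highest ``gm_high_frac`` (i.e. above the
    ``1 - gm_high_frac`` point of the range).  Voxels are first restricted
    to the lowest ``noise_low_frac`` of the ε_t range (removing noisy
    vessel and skull-base voxels) and the lowest ``mtt_low_frac`` of the
    robust MTT range (removing CSF); the ΔS range is computed over the
    surviving voxels.  Returns ``(gm_mask, wm_mask)``.
    """
    finite = np.isfinite(delta_s_map) & np.isfinite(noise_map) & np.isfinite(mtt_map)
    if not finite.any():
        warnings.warn("no finite voxels to segment", stacklevel=2)
        empty = np.zeros_like(delta_s_map, dtype=bool)
        return empty, empty.copy()

    keep = finite.copy()
    noise_vals = noise_map[finite]
    noise_ok = np.zeros_like(keep)
    noise_ok[finite] = _range_threshold(noise_vals, noise_low_frac, "low")
    keep &= noise_ok

    if keep.any():
        p_lo, p_hi = np.percentile(mtt_map[keep], robust_percentiles)
        mtt_cut = p_lo + mtt_low_frac * (p_hi - p_lo)
        keep &= mtt_map <= mtt_cut

    gm = np.zeros_like(keep)
    wm = np.zeros_like(keep)
    if not keep.any():
        warnings.warn("all voxels masked out before ΔS thresholding", stacklevel=2)
        return gm, wm
    ds = delta_s_map[keep]
    lo, hi = ds.min(), ds.max()
    span = hi - lo
    wm[keep] = delta_s_map[keep] <= lo + wm_low_frac * span
    gm[keep] = delta_s_map[keep] >= lo + (1.0 - gm_high_frac) * span
    if not gm.any() or not wm.any():
        warnings.warn("segmentation produced an empty GM or WM mask", stacklevel=2)
    return gm, wm


def _smooth_slices(volume: np.ndarray) -> np.ndarray:
    """Per-slice separable 3x3 Gaussian smoothing; NaNs propagate as-is."""
    out = volume.astype(float).copy()
    for axis in (0, 1):
        pad = [(0, 0)] * volume.ndim
        pad[axis] = (1, 1)
        padded = np.pad(out, pad, mode="edge")
        sl = [slice(None)] * volume.ndim
        acc = np.zeros_like(out)
        for offset, w in zip((0, 1, 2), _K3):
            sl[axis] = slice(offset, offset + volume.shape[axis])
            acc += w * padded[tuple(sl)]
        out = acc
    return out


def map_regression(
    map_a: np.ndarray,
    map_b: np.ndarray,
    mask: np.ndarray | None = None,
    smoothing: bool = False,
):
    """OLS regression of ``map_b`` on ``map_a`` over in-mask voxels.

    With ``smoothing=True`` both maps are first smoothed per axial slice
    with a 3x3 Gaussian kernel.  Returns ``(slope, r_squared)``.
    """
    if map_a.shape != map_b.shape:
        raise ValueError("maps must share a grid")
    a, b = map_a, map_b
    if smoothing:
        a, b = _smooth_slices(a), _smooth_slices(b)
    if mask is None:
        mask = np.ones(a.shape, dtype=bool)
    sel = mask & np.isfinite(a) & np.isfinite(b)
    if sel.sum() < 3:
        raise ValueError("need at least 3 in-mask voxels for regression")
    res = stats.linregress(a[sel], b[sel])
    return float(res.slope), float(res.rvalue**2)


def average_maps(maps: list[np.ndarray]) -> np.ndarray:
    """Voxel-wise mean of co-registered maps (NaN-aware)."""
    return np.nanmean(np.stack(maps), axis=0)
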