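"""Voxel-wise DSC analysis of a 4D dataset.

Given a 4D signal array plus the coordinates of a reference arterial
(AIF) and venous (VOF) voxel, compute per-voxel perfusion maps: percentage
signal change, baseline noise, rCBV (arterial or venous normalization),
rCBF and MTT from thresholded-SVD deconvolution, and the negative-rCBV
exclusion mask.  The AIF pseudo-inverse is factorized once and applied to
every voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .contrast_inputs import Agent
from .dsc_quant import (
    DeconvolutionConfig,
    RelaxationTimecourse,
    _onset_offset,
    convolution_matrix,
    kappa,
)
from .forward_signal import SignalTimecourse

__all__ = ["AnalysisResult", "analyze_volume"]


@dataclass
class AnalysisResult:
    """3D maps produced by :func:`analyze_volume`."""

    rcbv: np.ndarray
    rcbf: np.ndarray
    mtt: np.ndarray
    delta_s: np.ndarray
    noise: np.ndarray          # epsilon_t in percent of S0
    excluded: np.ndarray       # bool mask of negative/undefined rCBV
    meta: dict = field(default_factory=dict)

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "rcbv": self.rcbv, "rcbf": self.rcbf, "mtt": self.mtt,
            "delta_s": self.delta_s, "noise": self.noise,
            "excluded": self.excluded,
        }


def analyze_volume(
    data: np.ndarray,
    aif_index: tuple,
    vof_index: tuple,
    agent: Agent,
    tr: float,
    te: float,
    baseline_window: np.ndarray | None = None,
    svd_threshold: float = 0.20,
    normalization: str = "arterial",
    hct: float = 0.4,
    onset_frac: float = 0.10,
) -> AnalysisResult:
    """Run the standard DSC pipeline over every voxel of ``data``.

    ``data`` has shape (x, y, z, t) with signal in arbitrary units;
    ``normalization`` chooses the rCBV reference ('arterial' or 'venous');
    deconvolution always uses the AIF.
    """
    if normalization not in ("arterial", "venous"):
        raise ValueError(f"unknown normalization {normalization!r}")
    spatial = data.shape[:-1]
    n_t = data.shape[-1]
    if baseline_window is None:
        baseline_window = np.arange(min(10, n_t))
    baseline_window = np.asarray(baseline_window, dtype=int)

    flat = data.reshape(-1, n_t)
    s0 = flat[:, baseline_window].mean(axis=1)
    valid = (s0 > 0) & np.all(flat > 0, axis=1)
    dr2 = np.zeros_like(flat)
    dr2[valid] = -np.log(flat[valid] / s0[valid, None]) / te

    ds = np.full(flat.shape[0], np.nan)
    ds[valid] = 100.0 * (s0[valid] - flat[valid].min(axis=1)) / s0[valid]
    eps = np.full(flat.shape[0], np.nan)
    if baseline_window.size >= 2:
        sd = flat[:, baseline_window].std(axis=1, ddof=1)
        eps[valid] = 100.0 * sd[valid] / s0[valid]

    aif_flat = np.ravel_multi_index(aif_index, spatial)
    vof_flat = np.ravel_multi_index(vof_index, spatial)
    aif = dr2[aif_flat]
    vof = dr2[vof_flat]

    i0, _ = _onset_offset(aif, onset_frac)
    _, i1 = _onset_offset(vof, onset_frac)
    if i1 <= i0:
        raise ValueError("VOF bolus ends before the AIF bolus starts")
    window = slice(i0, i1 + 1)
    dr2_w = dr2[:, window]
    aif_w = aif[window]
    vof_w = vof[window]

    reference = aif_w if normalization == "arterial" else vof_w
    ref_area = np.trapezoid(reference, dx=tr)
    k = kappa(agent, hct)
    areas = np.trapezoid(dr2_w, dx=tr, axis=1)
    rcbv = k * areas / ref_area * 100.0
    rcbv[~valid] = np.nan

    # one SVD of the AIF matrix serves every voxel
    A = convolution_matrix(aif_w, tr)
    U, s, Vt = linalg.svd(A)
    keep = (s >= svd_threshold * s[0]) & (s > 0)
    if not np.any(keep):
        raise ValueError("all singular values removed by the threshold")
    s_inv = np.where(keep, 1.0 / np.where(keep, s, 1.0), 0.0)
    pinv = (Vt.T * s_inv) @ U.T
    residues = dr2_w @ pinv.T
    peaks = residues.max(axis=1)
    rcbf = np.where(peaks > 0, k * peaks * 100.0 * 60.0, np.nan)
    # arterial-normalized rCBV feeds the central volume principle
    rcbv_art = k * areas / np.trapezoid(aif_w, dx=tr) * 100.0
    mtt = np.where(rcbf > 0, rcbv_art / rcbf * 60.0, np.nan)
    rcbf[~valid] = np.nan
    mtt[~valid] = np.nan

    excluded = ~valid | np.isnan(rcbv) | (rcbv < 0)

    shape = spatial
    return AnalysisResult(
        rcbv=rcbv.reshape(shape),
        rcbf=rcbf.reshape(shape),
        mtt=mtt.reshape(shape),
        delta_s=ds.reshape(shape),
        noise=eps.reshape(shape),
        excluded=excluded.reshape(shape),
        meta={
            "agent": agent.value, "normalization": normalization,
            "svd_threshold": svd_threshold, "kappa": k,
            "bolus_window": (i0, i1), "tr": tr, "te": te,
        },
    )
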