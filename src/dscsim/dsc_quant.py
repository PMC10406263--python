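"""Standard DSC quantification: from signal time courses to rCBV/rCBF/MTT.

The pipeline follows the conventional analysis: log-ratio conversion of
signal to a relaxation-rate time course, truncation to the bolus window,
area-ratio rCBV with the hematocrit correction factor kappa, and
singular-value-decomposition deconvolution of the tissue curve by the
arterial input function (AIF) with fractional singular-value thresholding
for rCBF, with MTT from the central volume principle.

Normalization note: tissue may be normalized to an arterial or a venous
reference for rCBV only; deconvolution always uses the AIF, because the
venous curve is not rescaled to arterial area and deconvolving by it would
violate indicator-dilution theory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .contrast_inputs import Agent
from .forward_signal import SignalTimecourse

__all__ = [
    "RelaxationTimecourse",
    "DeconvolutionConfig",
    "PerfusionEstimate",
    "signal_to_relaxation",
    "delta_s",
    "snr",
    "temporal_gaussian_filter",
    "truncate_to_bolus_window",
    "kappa",
    "rcbv",
    "svd_deconvolve",
    "rcbf_mtt",
    "exclude_voxels",
]

#: assumed brain density (g/mL) converting per-100-mL to per-100-g units
BRAIN_DENSITY_G_PER_ML = 1.0


@dataclass
class RelaxationTimecourse:
    """ΔR2*(t) in 1/s at the acquisition TR."""

    samples: np.ndarray
    TR: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("relaxation samples must be finite")

    @property
    def times(self) -> np.ndarray:
        return self.TR * np.arange(self.samples.size)

    @property
    def area(self) -> float:
        return float(np.trapezoid(self.samples, dx=self.TR))


@dataclass(frozen=True)
class DeconvolutionConfig:
    """SVD deconvolution settings; threshold is a fraction of the largest
    singular value (clinical default 0.20)."""

    svd_threshold: float = 0.20
    discretization: str = "simple"
    allow_negative_residue: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.svd_threshold < 1.0:
            raise ValueError(
                f"svd_threshold must be in [0, 1), got {self.svd_threshold}"
            )
        if self.discretization != "simple":
            raise ValueError("only the simple discretization is implemented")


@dataclass
class PerfusionEstimate:
    """Per-voxel perfusion values plus provenance."""

    rCBV: float                  # mL/100g
    rCBF: float = np.nan         # mL/100g/min
    MTT: float = np.nan          # s
    normalization: str = "arterial"
    kappa: float = np.nan
    excluded: bool = False
    reason: str | None = None
    meta: dict = field(default_factory=dict)


def signal_to_relaxation(s: SignalTimecourse) -> RelaxationTimecourse:
    """ΔR2*(t) = -(1/TE) * ln(S(t)/S0), with S0 the baseline-window mean."""
    bad = np.flatnonzero(s.samples <= 0)
    if bad.size:
        raise ValueError(
            f"non-positive signal at sample index {bad[0]}; cannot take log"
        )
    dr2 = -(1.0 / s.TE) * np.log(s.samples / s.s0)
    return RelaxationTimecourse(dr2, TR=s.TR, meta=dict(s.meta))


def delta_s(s: SignalTimecourse) -> float:
    """Percentage maximal signal change: 100 * (S0 - min(S)) / S0."""
    return 100.0 * (s.s0 - float(s.samples.min())) / s.s0


def snr(s: SignalTimecourse) -> float:
    """Bolus SNR: ΔS divided by the baseline temporal noise ε_t (both in %).

    ε_t is the standard deviation of the baseline-window samples relative
    to S0.  A noiseless simulation has zero baseline variance and is
    flagged with an infinite SNR.
    """
    base = s.samples[s.baseline_window]
    if base.size < 2:
        raise ValueError("baseline_window must hold at least 2 samples")
    eps_t = 100.0 * float(base.std(ddof=1)) / s.s0
    ds = delta_s(s)
    if eps_t == 0.0:
        warnings.warn("zero baseline variance: noiseless series, SNR infinite",
                      stacklevel=2)
        return np.inf
    return ds / eps_t


#: 5-tap normalized Gaussian kernel (sigma = 1 sample)
_GAUSS5 = np.exp(-0.5 * np.arange(-2, 3) ** 2)
_GAUSS5 = _GAUSS5 / _GAUSS5.sum()


def temporal_gaussian_filter(s: SignalTimecourse) -> SignalTimecourse:
    """Smooth the series with a 1x5 Gaussian kernel (edges renormalized)."""
    x = s.samples
    if x.size < 5:
        raise ValueError("need at least 5 samples for the 1x5 kernel")
    num = np.convolve(x, _GAUSS5, mode="same")
    den = np.convolve(np.ones_like(x), _GAUSS5, mode="same")
    return SignalTimecourse(
        num / den, TR=s.TR, TE=s.TE,
        baseline_window=s.baseline_window.copy(), meta=dict(s.meta),
    )


def _onset_offset(x: np.ndarray, frac: float) -> tuple[int, int]:
    peak = np.abs(x).max()
    if peak <= 0:
        raise ValueError("no detectable bolus (flat series)")
    above = np.flatnonzero(np.abs(x) >= frac * peak)
    return int(above[0]), int(above[-1])


def truncate_to_bolus_window(
    tissue: RelaxationTimecourse,
    aif: RelaxationTimecourse,
    vof: RelaxationTimecourse,
    onset_frac: float = 0.10,
    end_frac: float = 0.02,
) -> tuple[RelaxationTimecourse, RelaxationTimecourse, RelaxationTimecourse]:
    """Crop all series to [start of the AIF bolus, end of the VOF bolus].

    The onset is the first AIF sample whose magnitude exceeds
    ``onset_frac`` of the AIF maximum; the end is the last VOF sample
    above ``end_frac`` of the VOF maximum.  The end criterion is looser so
    the slow venous (and tissue) washout is retained — cutting it biases
    the rCBV areas and the deconvolved residue low.
    """
    if not (tissue.TR == aif.TR == vof.TR):
        raise ValueError("series must share the same TR")
    i0, _ = _onset_offset(aif.samples, onset_frac)
    _, i1 = _onset_offset(vof.samples, end_frac)
    if i1 <= i0:
        raise ValueError("VOF bolus ends before the AIF bolus starts")
    sl = slice(i0, i1 + 1)
    crop = lambda r: RelaxationTimecourse(r.samples[sl], TR=r.TR, meta=dict(r.meta))
    return crop(tissue), crop(aif), crop(vof)


def kappa(agent: Agent, hct: float = 0.4) -> float:
    """Hematocrit correction factor for rCBV.

    Gd resides in plasma: kappa = (1 - Hct)/(1 - 0.69*Hct).  dOHb resides
    in the red cells: kappa = Hct/(0.69*Hct) = 1/0.69, independent of Hct.
    """
    if agent is Agent.GD:
        return (1.0 - hct) / (1.0 - 0.69 * hct)
    return 1.0 / 0.69


def rcbv(
    tissue: RelaxationTimecourse,
    reference: RelaxationTimecourse,
    agent: Agent,
    hct: float = 0.4,
    normalization: str = "arterial",
) -> PerfusionEstimate:
    """Area-ratio rCBV in mL/100g: kappa * (∫tissue / ∫reference) * 100.

    Unit brain density is assumed.  A non-positive reference area leaves
    the estimate undefined and flags the voxel.
    """
    k = kappa(agent, hct)
    ref_area = reference.area
    if ref_area <= 0:
        return PerfusionEstimate(
            np.nan, normalization=normalization, kappa=k,
            excluded=True, reason="non_positive_reference_area",
        )
    value = k * tissue.area / ref_area * 100.0 / BRAIN_DENSITY_G_PER_ML
    est = PerfusionEstimate(value, normalization=normalization, kappa=k)
    if value < 0:
        est.excluded, est.reason = True, "negative_rcbv"
    return est


def convolution_matrix(aif: np.ndarray, tr: float) -> np.ndarray:
    """Lower-triangular discrete convolution matrix A[j, k] = TR * aif[j-k]."""
    n = aif.size
    A = np.zeros((n, n))
    for j in range(n):
        A[j, : j + 1] = tr * aif[j::-1]
    return A


def svd_deconvolve(
    tissue: RelaxationTimecourse,
    aif: RelaxationTimecourse,
    cfg: DeconvolutionConfig = DeconvolutionConfig(),
) -> np.ndarray:
    """Estimate CBF*R(t) by thresholded-SVD inversion of the AIF matrix.

    Singular values below ``cfg.svd_threshold`` times the largest are
    zeroed before forming the pseudo-inverse; negative tail values of the
    estimate are kept (thresholding is the only regularization).
    """
    if tissue.samples.size != aif.samples.size:
        raise ValueError("tissue and AIF series must be aligned")
    if tissue.samples.size < 8:
        raise ValueError("need at least 8 samples for deconvolution")
    A = convolution_matrix(aif.samples, aif.TR)
    U, s, Vt = linalg.svd(A)
    keep = (s >= cfg.svd_threshold * s[0]) & (s > 0)
    if not np.any(keep):
        raise ValueError("all singular values removed by the threshold")
    s_inv = np.where(keep, 1.0 / np.where(keep, s, 1.0), 0.0)
    b = (Vt.T * s_inv) @ (U.T @ tissue.samples)
    return b


def rcbf_mtt(
    residue_series: np.ndarray,
    rCBV: float,
    agent: Agent,
    hct: float = 0.4,
) -> tuple[float, float]:
    """rCBF (mL/100g/min) and MTT (s) from the deconvolved residue.

    rCBF = kappa * max(b) * 100 * 60; MTT = rCBV/rCBF * 60 (central volume
    principle).  The same kappa is applied to rCBF as to rCBV so that the
    MTT ratio is hematocrit-free.
    """
    peak = float(np.max(residue_series))
    if peak <= 0:
        return np.nan, np.nan
    k = kappa(agent, hct)
    rcbf_val = k * peak * 100.0 * 60.0
    mtt = rCBV / rcbf_val * 60.0
    return rcbf_val, mtt


def residue_mtt_diagnostic(residue_series: np.ndarray, tr: float) -> float:
    """Area-over-max of the recovered residue: MTT without the kappa route."""
    peak = float(np.max(residue_series))
    if peak <= 0:
        return np.nan
    return float(np.trapezoid(residue_series, dx=tr)) / peak


def exclude_voxels(estimates: list[PerfusionEstimate]) -> tuple[list, dict]:
    """Flag negative-rCBV voxels; return the kept set and an exclusion report."""
    kept, report = [], {}
    for est in estimates:
        if not est.excluded and (np.isnan(est.rCBV) or est.rCBV < 0):
            est.excluded = True
            est.reason = "negative_rcbv"
        if est.excluded:
            report[est.reason] = report.get(est.reason, 0) + 1
        else:
            kept.append(est)
    report["n_excluded"] = sum(v for k_, v in report.items() if k_ != "n_excluded")
    return kept, report
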