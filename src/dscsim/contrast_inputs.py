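"""Arterial inlet functions for gadolinium and deoxyhemoglobin contrast.

Two bolus families are supported: the gamma-variate concentration profile
conventionally used for an injected Gd bolus, and a smoothed rectangular
drop in arterial oxygen saturation (SaO2) produced by a transient hypoxic
gas challenge.  Both are represented on a fine simulation time grid as an
:class:`AgentBolus`; Gd carries concentration in mM (non-negative) while the
dOHb bolus carries the signed saturation change ΔY (non-positive during
hypoxia).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Agent",
    "TimeGrid",
    "GammaVariateSpec",
    "HypoxicBolusSpec",
    "ReturnMode",
    "AgentBolus",
    "gamma_variate_bolus",
    "hypoxic_bolus",
    "gd_to_dohb_equivalent",
    "truncate_bolus_to_duration",
]

#: molar susceptibility of Gd-DTPA in ppm/mM at 3T
CHI_GD_PPM_PER_MM = 0.026
#: susceptibility scale of fully deoxygenated blood, ppm (scaled by Hct)
CHI_DOHB_PPM = 0.264
#: default hematocrit fraction
DEFAULT_HCT = 0.4


class Agent(str, enum.Enum):
    GD = "gd"
    DOHB = "dohb"


class ReturnMode(str, enum.Enum):
    EXPONENTIAL = "exponential"
    STEP = "step"


class InvalidSpecification(ValueError):
    """Raised when a bolus or grid specification violates its invariants."""


@dataclass(frozen=True)
class TimeGrid:
    """Uniform simulation time grid.

    Parameters
    ----------
    dt : float
        Step in seconds.  The default fine grid uses 0.1 s so that 1-2 s
        transport delays and the 2.5 s gamma-variate time-to-peak are
        resolved well below the acquisition TR.
    duration : float
        Total span in seconds; the grid has ``floor(duration/dt) + 1``
        samples.
    t0 : float
        Time origin in seconds.
    """

    dt: float = 0.1
    duration: float = 120.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise InvalidSpecification(f"dt must be positive, got {self.dt}")
        if self.duration <= 0:
            raise InvalidSpecification(
                f"duration must be positive, got {self.duration}"
            )

    @property
    def n_samples(self) -> int:
        return int(np.floor(self.duration / self.dt)) + 1

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_samples)


@dataclass(frozen=True)
class GammaVariateSpec:
    """Gamma-variate Gd inlet: ``a * (t/b)^c * exp(c*(1 - t/b))``.

    ``a`` is the peak concentration in mM (reached at ``t = onset + b``),
    ``b`` the time-to-peak in seconds and ``c`` the unitless shape factor.
    Defaults model a standard injected bolus observed at the artery.
    """

    a: float = 2.0
    b: float = 2.5
    c: float = 3.0
    onset: float = 10.0

    def __post_init__(self) -> None:
        if self.a < 0:
            raise InvalidSpecification(f"peak concentration a must be >= 0, got {self.a}")
        if self.b <= 0 or self.c <= 0:
            raise InvalidSpecification(
                f"gamma-variate shape requires b > 0 and c > 0, got b={self.b}, c={self.c}"
            )


@dataclass(frozen=True)
class HypoxicBolusSpec:
    """Rectangular hypoxic SaO2 drop smoothed by a first-order exponential.

    The lungs take several breaths to wash out oxygen, so the saturation
    approaches the hypoxic target with time constant ``rise_tau``; the
    plateau is held for ``plateau_duration`` (~30 s experimentally) before
    returning to baseline, either through the same exponential
    (``return_mode='exponential'``) or abruptly (``'step'``, mimicking the
    single-breath resaturation).
    """

    base_sat: float = 0.98
    target_sat: float = 0.75
    plateau_duration: float = 30.0
    onset: float = 10.0
    rise_tau: float = 5.0
    return_mode: ReturnMode = ReturnMode.EXPONENTIAL

    def __post_init__(self) -> None:
        if not (0.0 <= self.target_sat <= self.base_sat <= 1.0):
            raise InvalidSpecification(
                "require 0 <= target_sat <= base_sat <= 1, got "
                f"target={self.target_sat}, base={self.base_sat}"
            )
        if self.plateau_duration <= 0:
            raise InvalidSpecification("plateau_duration must be positive")
        if self.rise_tau < 0:
            raise InvalidSpecification("rise_tau must be >= 0")

    @property
    def depth(self) -> float:
        """Magnitude of the saturation drop (positive)."""
        return self.base_sat - self.target_sat


@dataclass
class AgentBolus:
    """A contrast time course on a simulation grid.

    ``values`` holds [Gd](t) in mM for ``agent == Agent.GD`` (non-negative)
    or the saturation change ΔY(t) as a signed fraction for
    ``agent == Agent.DOHB`` (non-positive during hypoxia).  ``meta`` carries
    provenance such as the generating spec and any truncation bookkeeping.
    """

    agent: Agent
    grid: TimeGrid
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_samples,):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"({self.grid.n_samples} samples)"
            )

    @property
    def times(self) -> np.ndarray:
        return self.grid.times

    @property
    def area(self) -> float:
        """Time integral of the bolus (trapezoid), in value-units * s."""
        return float(np.trapezoid(self.values, dx=self.grid.dt))

    def to_frame(self):
        """Two-column (time_s, value) pandas frame for CSV export."""
        import pandas as pd

        return pd.DataFrame({"time_s": self.times, "value": self.values})


def gamma_variate_bolus(spec: GammaVariateSpec, grid: TimeGrid) -> AgentBolus:
    """Sample a gamma-variate Gd inlet on ``grid``.

    The curve is zero before ``spec.onset`` and peaks with value ``spec.a``
    at ``spec.onset + spec.b``.
    """
    t = grid.times - spec.onset
    values = np.zeros(grid.n_samples)
    rising = t > 0
    x = t[rising] / spec.b
    values[rising] = spec.a * x**spec.c * np.exp(spec.c * (1.0 - x))
    return AgentBolus(Agent.GD, grid, values, meta={"spec": spec})


def hypoxic_bolus(spec: HypoxicBolusSpec, grid: TimeGrid) -> AgentBolus:
    """Sample a smoothed rectangular hypoxic bolus ΔY(t) on ``grid``.

    Closed-form convolution of a rectangular pulse of depth
    ``-(base_sat - target_sat)`` and width ``plateau_duration`` with a
    unit-area decaying exponential of time constant ``rise_tau``.  With
    ``return_mode='step'`` only the falling (hypoxic) edge is smoothed and
    the return to baseline is abrupt.
    """
    t = grid.times
    depth = spec.depth
    t_on = spec.onset
    t_off = spec.onset + spec.plateau_duration
    values = np.zeros(grid.n_samples)

    if spec.rise_tau == 0.0:
        inside = (t >= t_on) & (t < t_off)
        values[inside] = -depth
        return AgentBolus(Agent.DOHB, grid, values, meta={"spec": spec})

    tau = spec.rise_tau
    during = (t >= t_on) & (t < t_off)
    values[during] = -depth * (1.0 - np.exp(-(t[during] - t_on) / tau))
    after = t >= t_off
    if spec.return_mode is ReturnMode.EXPONENTIAL:
        # exact rect (*) exp tail: the partial rise relaxes back to zero
        v_off = depth * (1.0 - np.exp(-spec.plateau_duration / tau))
        values[after] = -v_off * np.exp(-(t[after] - t_off) / tau)
    return AgentBolus(Agent.DOHB, grid, values, meta={"spec": spec})


def gd_to_dohb_equivalent(
    gd_conc, hct: float = DEFAULT_HCT, chi_gd: float = CHI_GD_PPM_PER_MM,
    chi_dohb: float = CHI_DOHB_PPM,
):
    """Saturation change with the same susceptibility effect as ``gd_conc`` mM Gd.

    Equating the dOHb and Gd frequency-shift expressions gives
    ``ΔY = -chi_gd / (chi_dohb * Hct) * [Gd]``; with the defaults the
    constant evaluates to 0.026/(0.264*0.4) = 0.2462, i.e. 1 mM of Gd is
    equivalent to a 24.6 % saturation drop at 3T.  The constant is computed
    from the configured hematocrit and molar susceptibilities so that a
    non-default Hct stays self-consistent.
    """
    return -chi_gd / (chi_dohb * hct) * np.asarray(gd_conc, dtype=float)


def truncate_bolus_to_duration(bolus: AgentBolus, duration: float) -> AgentBolus:
    """Shorten a bolus so its nominal width matches ``duration`` seconds.

    For a hypoxic bolus (whose generating spec travels in ``meta``) the
    plateau is shortened while the onset and rise time constant are kept,
    so a duration-matched short bolus has the physiologically realistic
    shape (it may not reach the full saturation drop).  For other boluses
    samples are removed after the peak so that the full width at 10 % of
    the peak matches ``duration``.  Identity when the bolus is already no
    wider than ``duration``; provenance records the new area and peak.
    """
    if duration <= 0:
        raise InvalidSpecification("duration must be positive")
    spec = bolus.meta.get("spec")
    if isinstance(spec, HypoxicBolusSpec):
        if duration < spec.rise_tau:
            warnings.warn(
                "requested duration is shorter than the bolus rise time; "
                "returning best effort", stacklevel=2,
            )
        new_plateau = min(spec.plateau_duration, max(duration, bolus.grid.dt))
        from dataclasses import replace as _replace

        new = hypoxic_bolus(_replace(spec, plateau_duration=new_plateau), bolus.grid)
        new.meta.update(
            truncated_to_s=duration if new_plateau < spec.plateau_duration else None,
            area=new.area, peak=float(np.abs(new.values).max()),
        )
        return new

    v = bolus.values
    dt = bolus.grid.dt
    mag = np.abs(v)
    peak = mag.max()
    meta = dict(bolus.meta)
    if peak == 0.0:
        return AgentBolus(bolus.agent, bolus.grid, v.copy(), meta)
    active = np.flatnonzero(mag >= 0.10 * peak)
    i0, i1 = active[0], active[-1]
    width = (i1 - i0) * dt
    if duration >= width:
        meta.update(truncated_to_s=None, area=bolus.area, peak=peak)
        return AgentBolus(bolus.agent, bolus.grid, v.copy(), meta)
    n_cut = int(round((width - duration) / dt))
    i_peak = int(np.argmax(mag))
    if duration < (i_peak - i0) * dt:
        warnings.warn(
            "requested duration is shorter than the bolus rise time; "
            "returning best effort", stacklevel=2,
        )
        n_cut = max(i1 - i_peak, 0)
    out = np.concatenate([v[: i_peak + 1], v[i_peak + 1 + n_cut:]])
    out = np.concatenate([out, np.zeros(bolus.grid.n_samples - out.size)])
    new = AgentBolus(bolus.agent, bolus.grid, out, meta)
    new.meta.update(truncated_to_s=duration, area=new.area, peak=peak)
    return new
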