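"""Residue-function transport of an arterial bolus to tissue and vein.

The vascular bed is summarized by a residue function R(t) (fraction of
tracer still inside the voxel t seconds after arrival).  Tissue uses a
biexponential R(t) with a fast and a slow flowing compartment; a vein is
treated as a single compartment with a monoexponential R(t).  The inlet
concentration is convolved with the unit-area transport kernel
k(t) = R(t)/∫R dt, which conserves steady-state amplitude (a constant
inlet emerges unchanged), and is then delayed by a whole-sample shift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Union

import numpy as np

from .contrast_inputs import AgentBolus, TimeGrid

__all__ = [
    "BiexponentialResidue",
    "MonoexponentialResidue",
    "TransportSpec",
    "residue_value",
    "residue_mtt",
    "transport_kernel",
    "transport",
]


@dataclass(frozen=True)
class BiexponentialResidue:
    """R(t) = f*exp(-t*t1) + (1-f)*exp(-t*t2).

    ``f`` is the flow fraction of the fast compartment and ``t1``/``t2``
    the fast/slow rate constants in 1/s.  The defaults give a tissue mean
    transit time of f/t1 + (1-f)/t2 = 2.953 s.
    """

    f: float = 0.92
    t1: float = 0.68
    t2: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"flow fraction f must be in [0,1], got {self.f}")
        if self.t1 <= 0 or self.t2 <= 0:
            raise ValueError("rate constants t1, t2 must be positive")


@dataclass(frozen=True)
class MonoexponentialResidue:
    """R(t) = exp(-t/mtt); single well-mixed compartment (venous default 4 s)."""

    mtt: float = 4.0

    def __post_init__(self) -> None:
        if self.mtt <= 0:
            raise ValueError(f"mtt must be positive, got {self.mtt}")


Residue = Union[BiexponentialResidue, MonoexponentialResidue]


@dataclass(frozen=True)
class TransportSpec:
    """A residue family plus a pure arrival delay in seconds."""

    residue: Residue
    delay: float = 0.0

    def __post_init__(self) -> None:
        if self.delay < 0:
            raise ValueError(f"delay must be >= 0, got {self.delay}")


def residue_value(residue: Residue, t) -> np.ndarray:
    """Evaluate R(t) for t >= 0."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("residue functions are defined for t >= 0 only")
    if isinstance(residue, BiexponentialResidue):
        return residue.f * np.exp(-t * residue.t1) + (1.0 - residue.f) * np.exp(
            -t * residue.t2
        )
    if isinstance(residue, MonoexponentialResidue):
        return np.exp(-t / residue.mtt)
    raise TypeError(f"unknown residue type: {type(residue)!r}")


def residue_mtt(residue: Residue) -> float:
    """Mean transit time implied by the residue function, ∫R(t)dt.

    Closed form: f/t1 + (1-f)/t2 for the biexponential, mtt for the
    monoexponential.
    """
    if isinstance(residue, BiexponentialResidue):
        return residue.f / residue.t1 + (1.0 - residue.f) / residue.t2
    if isinstance(residue, MonoexponentialResidue):
        return residue.mtt
    raise TypeError(f"unknown residue type: {type(residue)!r}")


def transport_kernel(residue: Residue, dt: float, tail_tol: float = 1e-9) -> np.ndarray:
    """Discrete unit-area transport kernel samples k(t) = R(t)/∫R.

    The support extends until R(t) has decayed below ``tail_tol`` so the
    slow compartment's tail is fully represented; the samples are trapezoid
    weighted and renormalized so that the discrete integral is exactly 1.
    """
    # slowest decay rate determines how far the tail must be followed
    if isinstance(residue, BiexponentialResidue):
        slowest = min(residue.t1, residue.t2)
    else:
        slowest = 1.0 / residue.mtt
    t_max = -np.log(tail_tol) / slowest
    n = int(np.ceil(t_max / dt)) + 1
    k = residue_value(residue, dt * np.arange(n))
    w = np.ones(n)
    w[0] = w[-1] = 0.5
    k = k * w
    k /= k.sum() * dt
    return k


def transport(inlet: AgentBolus, spec: TransportSpec) -> AgentBolus:
    """Propagate ``inlet`` through the residue kinetics plus delay.

    Computes (inlet ⊛ k)(t - delay) by discrete summation on the inlet's
    fine grid, where k is the unit-area kernel from
    :func:`transport_kernel`.  The delay is applied after the convolution
    as a whole-sample shift.
    """
    grid: TimeGrid = inlet.grid
    dt = grid.dt
    if 0.0 < spec.delay < dt:
        warnings.warn(
            f"delay {spec.delay} s is below the grid step {dt} s and rounds "
            "to zero samples", stacklevel=2,
        )
    k = transport_kernel(spec.residue, dt)
    out = np.convolve(inlet.values, k)[: grid.n_samples] * dt
    shift = int(round(spec.delay / dt))
    if shift > 0:
        out = np.concatenate([np.zeros(shift), out[:-shift]])
    meta = dict(inlet.meta)
    meta.update(
        transport={
            "residue": spec.residue,
            "delay_s": spec.delay,
            "kernel": "unit-area R(t)/∫R, trapezoid-weighted",
        }
    )
    return AgentBolus(inlet.agent, grid, out, meta)
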