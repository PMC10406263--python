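"""Biophysical T2*-weighted signal model for a multi-compartment voxel.

A voxel is a mixture of extravascular extracellular space (EES) and one or
more intravascular (IVS) compartments (artery, arteriole, capillary,
venule, vein), each with its own fractional blood volume, baseline oxygen
saturation Y0 and vessel-radius class.  Paramagnetic contrast —
deoxyhemoglobin (a saturation change ΔY) or gadolinium (a plasma
concentration in mM) — perturbs the intravascular susceptibility; the
resulting frequency shift on the vessel surface drives a linear
extravascular and a quadratic intravascular transverse relaxation rate
enhancement, and the voxel signal is the volume-weighted sum of
monoexponential compartment signals at the echo time.

Key conventions
---------------
* Frequency shifts are angular (rad/s), with gamma = 2*pi*42.6e6 rad/s/T.
* Per-compartment blood volumes (pCBV) enter the extravascular sum in
  PERCENT, because the radius-class coefficients are calibrated per one
  percent of CBV.
* Baseline deoxygenation (1 - Y0) contributes to the "contrast" relaxation
  terms even before any bolus: the quoted R2*_0 of blood (13.8 1/s) is for
  fully oxygenated blood, so a vein at Y0 = 0.60 relaxes faster at
  baseline, and baseline signals order artery > vein.
* Hyperoxic overshoot (negative effective deoxygenation) is clipped to
  zero rather than squared into a spurious positive relaxation.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .contrast_inputs import (
    Agent,
    AgentBolus,
    CHI_DOHB_PPM,
    CHI_GD_PPM_PER_MM,
    TimeGrid,
)
from .tracer_transport import TransportSpec, transport

__all__ = [
    "PhysicsConstants",
    "VesselClass",
    "CompartmentKind",
    "Compartment",
    "VoxelLabel",
    "VoxelModel",
    "SignalTimecourse",
    "frequency_shift",
    "ees_relaxation",
    "ivs_relaxation",
    "voxel_signal",
    "compartment_contrast_timecourses",
    "simulate_signal_timecourse",
    "arterial_voxel",
    "venous_voxel",
    "tissue_voxel",
    "csf_voxel",
]


@dataclass(frozen=True)
class PhysicsConstants:
    """Acquisition and blood-physics constants of the 3T gradient-echo model."""

    B0: float = 3.0                      # tesla
    gamma: float = 2 * np.pi * 42.6e6    # rad/s/T
    Hct: float = 0.4                     # hematocrit fraction
    TE: float = 0.030                    # s
    chi_dohb: float = CHI_DOHB_PPM       # ppm, fully deoxygenated blood scale
    chi_gd: float = CHI_GD_PPM_PER_MM    # ppm/mM
    R2_0_EES: float = 20.99              # 1/s, baseline extravascular rate
    R2_0_IVS: float = 13.8               # 1/s, fully oxygenated blood
    ivs_quadratic_coeff: float = 181.0   # 1/s, quadratic IVS relaxivity

    @property
    def gd_equivalent_dy(self) -> float:
        """Saturation drop equivalent in susceptibility to 1 mM Gd (~0.246)."""
        return self.chi_gd / (self.chi_dohb * self.Hct)


class VesselClass(enum.Enum):
    """Vessel-radius class and its linear extravascular relaxivity.

    The coefficient multiplies the angular frequency shift to give the
    extravascular rate enhancement per one percent of CBV; values come from
    Monte-Carlo calibrations of diffusing spins around cylinders of the
    stated radius.
    """

    CAPILLARY_5UM = ("capillary_5um", 0.0387)
    SMALL_VESSEL_16_200UM = ("small_vessel_16_200um", 0.0433)
    LARGE_VESSEL_200UM_90DEG = ("large_vessel_200um_90deg", 0.0798)

    def __init__(self, label: str, ees_coeff: float) -> None:
        self.label = label
        self.ees_coeff = ees_coeff


class CompartmentKind(str, enum.Enum):
    ARTERY = "artery"
    ARTERIOLE = "arteriole"
    CAPILLARY = "capillary"
    VENULE = "venule"
    VEIN = "vein"


@dataclass(frozen=True)
class Compartment:
    """One vascular compartment: volume in PERCENT of the voxel, baseline Y0."""

    kind: CompartmentKind
    pCBV: float           # percent of voxel volume, NOT a fraction
    Y0: float             # baseline oxygen saturation fraction
    vessel_class: VesselClass

    def __post_init__(self) -> None:
        if self.pCBV < 0:
            raise ValueError(f"pCBV must be >= 0, got {self.pCBV}")
        if not 0.0 <= self.Y0 <= 1.0:
            raise ValueError(f"Y0 must be in [0,1], got {self.Y0}")


class VoxelLabel(str, enum.Enum):
    ARTERIAL = "arterial"
    VENOUS = "venous"
    GM = "gm"
    WM = "wm"
    CSF = "csf"


@dataclass(frozen=True)
class VoxelModel:
    compartments: tuple
    label: VoxelLabel

    def __post_init__(self) -> None:
        object.__setattr__(self, "compartments", tuple(self.compartments))
        if self.total_CBV > 100.0 + 1e-9:
            raise ValueError(f"total CBV exceeds 100%: {self.total_CBV}")

    @property
    def total_CBV(self) -> float:
        """Summed blood volume in percent."""
        return float(sum(c.pCBV for c in self.compartments))


@dataclass
class SignalTimecourse:
    """Sampled S(t) with acquisition metadata (see :mod:`dscsim.dsc_quant`)."""

    samples: np.ndarray
    TR: float
    TE: float
    baseline_window: np.ndarray = None  # sample indices used for S0 / noise
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.baseline_window is None:
            self.baseline_window = np.arange(min(10, self.samples.size))
        else:
            self.baseline_window = np.asarray(self.baseline_window, dtype=int)
        if self.baseline_window.size == 0:
            raise ValueError("baseline_window must be non-empty")

    @property
    def times(self) -> np.ndarray:
        return self.TR * np.arange(self.samples.size)

    @property
    def s0(self) -> float:
        return float(self.samples[self.baseline_window].mean())


def _effective_deoxygenation(Y0, dY, gd, k: PhysicsConstants, clip: bool = True):
    """(1 - Y0 - ΔY) with the Gd susceptibility folded in as an equivalent ΔY."""
    deox = 1.0 - np.asarray(Y0, dtype=float) - np.asarray(dY, dtype=float) \
        + k.gd_equivalent_dy * np.asarray(gd, dtype=float)
    if clip and np.any(deox < -1e-12):
        warnings.warn(
            "negative effective deoxygenation (hyperoxic overshoot) clipped to 0",
            stacklevel=3,
        )
    return np.clip(deox, 0.0, None) if clip else deox


def frequency_shift(Y0, dY=0.0, gd=0.0, k: PhysicsConstants = PhysicsConstants()):
    """Angular frequency shift (rad/s) at the vessel surface.

    ``chi_dohb * 1e-6 * Hct * (1 - Y0 - ΔY) * gamma * B0`` plus the Gd term
    ``chi_gd * 1e-6 * [Gd] * gamma * B0``; equivalently the dOHb expression
    with an effective ΔY' = ΔY - 0.246*[Gd].
    """
    deox = _effective_deoxygenation(Y0, dY, gd, k)
    return k.chi_dohb * 1e-6 * k.Hct * deox * k.gamma * k.B0


def ees_relaxation(voxel: VoxelModel, shifts: Sequence) -> np.ndarray:
    """Extravascular rate enhancement: sum_i pCBV_i * coeff_i * shift_i (1/s).

    ``shifts`` must hold one (scalar or time-series) angular frequency
    shift per compartment of ``voxel``.
    """
    if len(shifts) != len(voxel.compartments):
        raise ValueError(
            f"got {len(shifts)} shifts for {len(voxel.compartments)} compartments"
        )
    total = 0.0
    for comp, dv in zip(voxel.compartments, shifts):
        total = total + comp.pCBV * comp.vessel_class.ees_coeff * np.asarray(dv)
    return total


def ivs_relaxation(Y0, dY=0.0, gd=0.0, k: PhysicsConstants = PhysicsConstants()):
    """Intravascular rate enhancement: 181 * (1 - Y0 - ΔY + 0.246*[Gd])^2 (1/s)."""
    deox = _effective_deoxygenation(Y0, dY, gd, k)
    return k.ivs_quadratic_coeff * deox**2


def _split_contrast(agent: Agent, values):
    """Map a bolus value array onto the (dY, gd) argument pair."""
    if agent is Agent.GD:
        return 0.0, values
    return values, 0.0


def voxel_signal(
    voxel: VoxelModel,
    agent: Agent = Agent.DOHB,
    contrast=0.0,
    k: PhysicsConstants = PhysicsConstants(),
) -> np.ndarray:
    """T2*-weighted signal of the voxel for a given contrast level.

    ``contrast`` is ΔY (signed fraction) for dOHb or [Gd] (mM) for Gd; a
    scalar gives the instantaneous signal, an array the full time course
    (every compartment sees the same contrast course, superimposed on its
    own baseline Y0).  The extravascular compartment is a single
    exponential with the summed rate enhancement; each intravascular
    compartment contributes its own exponential weighted by its volume
    fraction.
    """
    dY, gd = _split_contrast(agent, np.asarray(contrast, dtype=float))
    shifts = [frequency_shift(c.Y0, dY, gd, k) for c in voxel.compartments]
    r2_ees = k.R2_0_EES + ees_relaxation(voxel, shifts)
    cbv_frac = voxel.total_CBV / 100.0
    s = (1.0 - cbv_frac) * np.exp(-k.TE * r2_ees)
    for comp in voxel.compartments:
        r2_ivs = k.R2_0_IVS + ivs_relaxation(comp.Y0, dY, gd, k)
        s = s + comp.pCBV / 100.0 * np.exp(-k.TE * r2_ivs)
    return s


def compartment_contrast_timecourses(
    inlet: AgentBolus,
    voxel: VoxelModel,
    tissue_spec: TransportSpec,
    venous_spec: TransportSpec | None = None,
    csf_spec: TransportSpec | None = None,
) -> list[AgentBolus]:
    """Contrast time course seen by each compartment of ``voxel``.

    An arterial voxel receives the undelayed inlet; a venous voxel the
    venous transport output; tissue (GM/WM) compartments all share the
    tissue transport output.  An avascular CSF voxel receives no contrast;
    a CSF voxel with a residual vascular partial volume (slow pial/dural
    veins) receives the ``csf_spec`` transport output.
    """
    if not voxel.compartments and voxel.label is not VoxelLabel.CSF:
        raise ValueError("voxel has no compartments")
    if voxel.label is VoxelLabel.ARTERIAL:
        course = inlet
    elif voxel.label is VoxelLabel.VENOUS:
        if venous_spec is None:
            raise ValueError("venous voxel requires a venous TransportSpec")
        course = transport(inlet, venous_spec)
    elif voxel.label in (VoxelLabel.GM, VoxelLabel.WM):
        course = transport(inlet, tissue_spec)
    elif voxel.label is VoxelLabel.CSF:
        if voxel.compartments and csf_spec is not None:
            course = transport(inlet, csf_spec)
        else:
            course = AgentBolus(
                inlet.agent, inlet.grid, np.zeros(inlet.grid.n_samples)
            )
    else:
        raise ValueError(f"unknown voxel label {voxel.label!r}")
    return [course for _ in voxel.compartments] or [course]


def simulate_signal_timecourse(
    inlet: AgentBolus,
    voxel: VoxelModel,
    transport_spec: TransportSpec,
    TR: float = 1.5,
    duration: float | None = None,
    venous_spec: TransportSpec | None = None,
    csf_spec: TransportSpec | None = None,
    k: PhysicsConstants = PhysicsConstants(),
) -> SignalTimecourse:
    """Fine-grid forward simulation sampled at the acquisition TR.

    The voxel-appropriate transported contrast course is computed on the
    inlet's fine grid, converted to signal, and decimated to TR.  The
    baseline window is every TR sample before the first contrast arrival.
    """
    courses = compartment_contrast_timecourses(
        inlet, voxel, transport_spec, venous_spec, csf_spec
    )
    course = courses[0]
    grid: TimeGrid = inlet.grid
    if duration is None:
        duration = grid.duration
    elif duration < grid.duration:
        pass
    else:
        warnings.warn(
            "requested duration exceeds the simulation grid; clipping",
            stacklevel=2,
        )
        duration = grid.duration
    fine_signal = voxel_signal(voxel, inlet.agent, course.values, k)
    n_tr = int(np.floor(duration / TR)) + 1
    idx = np.round(np.arange(n_tr) * TR / grid.dt).astype(int)
    idx = idx[idx < grid.n_samples]
    samples = np.atleast_1d(fine_signal)[idx] if np.ndim(fine_signal) else np.full(
        idx.size, fine_signal
    )
    # baseline: TR samples strictly before any contrast reaches the voxel
    active = np.flatnonzero(np.abs(course.values) > 0)
    t_arrive = grid.times[active[0]] if active.size else duration
    baseline = np.flatnonzero(idx * grid.dt < t_arrive)
    if baseline.size == 0:
        baseline = np.array([0])
    return SignalTimecourse(
        samples,
        TR=TR,
        TE=k.TE,
        baseline_window=baseline,
        meta={
            "agent": inlet.agent,
            "voxel": voxel,
            "B0": k.B0,
            "Hct": k.Hct,
            "transport": course.meta.get("transport"),
        },
    )


# ---------------------------------------------------------------------------
# Voxel presets (single large-vessel voxels and the 1:2:2 tissue mixture)
# ---------------------------------------------------------------------------

def arterial_voxel(cbv: float = 100.0, y0: float = 0.98) -> VoxelModel:
    """Large-vessel arterial voxel (90-degree 200 um class).

    ``y0`` defaults to the physiological arterial baseline saturation used
    by the hypoxic paradigms (0.98); pass 1.0 for fully oxygenated blood.
    """
    return VoxelModel(
        (
            Compartment(
                CompartmentKind.ARTERY, cbv, y0, VesselClass.LARGE_VESSEL_200UM_90DEG
            ),
        ),
        VoxelLabel.ARTERIAL,
    )


def venous_voxel(cbv: float = 100.0, y0: float = 0.60) -> VoxelModel:
    """Large-vessel venous voxel (90-degree 200 um class, Y0 = 0.60)."""
    return VoxelModel(
        (
            Compartment(
                CompartmentKind.VEIN, cbv, y0, VesselClass.LARGE_VESSEL_200UM_90DEG
            ),
        ),
        VoxelLabel.VENOUS,
    )


def tissue_voxel(
    total_cbv: float = 4.0,
    label: VoxelLabel = VoxelLabel.GM,
    arterial_y0: float = 1.0,
) -> VoxelModel:
    """Mixed tissue voxel with the 1:2:2 artery/arteriole : capillary :
    vein/venule volume split.

    The arterial fifth is divided equally between artery (Y0 = 1.00) and
    arteriole (Y0 = 0.95); the venous two fifths equally between vein and
    venule (both Y0 = 0.60); capillaries carry Y0 = 0.775.  Capillaries use
    the 5 um radius class, all other intra-tissue vessels the 16-200 um
    class.
    """
    a = total_cbv / 5.0
    parts = (
        Compartment(CompartmentKind.ARTERY, a / 2, arterial_y0,
                    VesselClass.SMALL_VESSEL_16_200UM),
        Compartment(CompartmentKind.ARTERIOLE, a / 2, 0.95,
                    VesselClass.SMALL_VESSEL_16_200UM),
        Compartment(CompartmentKind.CAPILLARY, 2 * a, 0.775,
                    VesselClass.CAPILLARY_5UM),
        Compartment(CompartmentKind.VEIN, a, 0.60,
                    VesselClass.SMALL_VESSEL_16_200UM),
        Compartment(CompartmentKind.VENULE, a, 0.60,
                    VesselClass.SMALL_VESSEL_16_200UM),
    )
    return VoxelModel(parts, label)


def csf_voxel(partial_venous_cbv: float = 0.0) -> VoxelModel:
    """CSF voxel: extravascular water, optionally with a small venous
    partial volume.

    Sulcal and peri-ventricular CSF voxels in real data partial-volume
    with slow pial/dural venous structures, which is what gives CSF its
    characteristically long apparent transit time; pass a small
    ``partial_venous_cbv`` (percent) to emulate that.  The default is a
    fully avascular voxel with no contrast response.
    """
    if partial_venous_cbv <= 0:
        return VoxelModel((), VoxelLabel.CSF)
    return VoxelModel(
        (
            Compartment(
                CompartmentKind.VEIN, partial_venous_cbv, 0.60,
                VesselClass.SMALL_VESSEL_16_200UM,
            ),
        ),
        VoxelLabel.CSF,
    )
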