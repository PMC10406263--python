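"""Named contrast paradigms: the four hypoxic SaO2 profiles plus standard Gd.

The hypoxic paradigms vary the bolus magnitude (ΔSaO2) and the baseline
saturation (base-SaO2): small drop at high baseline (98-90 %), medium
(98-84 %), large (98-75 %), and small drop at low baseline (88-80 %).  The
Gd paradigm is a gamma-variate injection with ~2 mM peak arterial
concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .contrast_inputs import (
    Agent,
    AgentBolus,
    GammaVariateSpec,
    HypoxicBolusSpec,
    TimeGrid,
    gamma_variate_bolus,
    hypoxic_bolus,
)

__all__ = ["ParadigmSpec", "PARADIGMS", "DOHB_PARADIGM_ORDER", "make_inlet"]


@dataclass(frozen=True)
class ParadigmSpec:
    name: str
    agent: Agent
    base_sat: float | None = None       # dOHb only
    target_sat: float | None = None     # dOHb only
    peak_mM: float | None = None        # Gd only
    plateau_duration: float = 30.0
    rise_tau: float = 5.0
    onset: float = 10.0

    def bolus_spec(self):
        if self.agent is Agent.GD:
            return GammaVariateSpec(a=self.peak_mM, onset=self.onset)
        return HypoxicBolusSpec(
            base_sat=self.base_sat,
            target_sat=self.target_sat,
            plateau_duration=self.plateau_duration,
            rise_tau=self.rise_tau,
            onset=self.onset,
        )

    @property
    def arterial_baseline(self) -> float:
        """Baseline arterial saturation of the paradigm (0.98 for Gd)."""
        return self.base_sat if self.base_sat is not None else 0.98


PARADIGMS: dict[str, ParadigmSpec] = {
    "gd_standard": ParadigmSpec("gd_standard", Agent.GD, peak_mM=2.0),
    "dohb_small_high": ParadigmSpec(
        "dohb_small_high", Agent.DOHB, base_sat=0.98, target_sat=0.90
    ),
    "dohb_medium_high": ParadigmSpec(
        "dohb_medium_high", Agent.DOHB, base_sat=0.98, target_sat=0.84
    ),
    "dohb_large_high": ParadigmSpec(
        "dohb_large_high", Agent.DOHB, base_sat=0.98, target_sat=0.75
    ),
    "dohb_small_low": ParadigmSpec(
        "dohb_small_low", Agent.DOHB, base_sat=0.88, target_sat=0.80
    ),
}

#: order in which arterial-normalized rCBV overestimation decreases
DOHB_PARADIGM_ORDER = (
    "dohb_small_high",
    "dohb_medium_high",
    "dohb_large_high",
    "dohb_small_low",
)


def make_inlet(paradigm: ParadigmSpec, grid: TimeGrid | None = None) -> AgentBolus:
    """Arterial inlet bolus for a paradigm on the fine simulation grid."""
    if grid is None:
        grid = TimeGrid(dt=0.1, duration=120.0)
    spec = paradigm.bolus_spec()
    if paradigm.agent is Agent.GD:
        return gamma_variate_bolus(spec, grid)
    return hypoxic_bolus(spec, grid)
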