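"""YAML/JSON configuration loading for boluses, transport and phantoms."""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .contrast_inputs import (
    Agent,
    GammaVariateSpec,
    HypoxicBolusSpec,
    ReturnMode,
    TimeGrid,
)
from .paradigms import PARADIGMS, ParadigmSpec
from .phantom import PhantomSpec
from .tracer_transport import (
    BiexponentialResidue,
    MonoexponentialResidue,
    TransportSpec,
)

__all__ = [
    "load_config",
    "parse_grid",
    "parse_bolus_spec",
    "parse_transport",
    "parse_paradigm",
    "parse_phantom",
]


def load_config(path) -> dict:
    """Read a YAML (or JSON) configuration file into a dict."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def parse_grid(cfg: dict | None) -> TimeGrid:
    cfg = cfg or {}
    return TimeGrid(
        dt=cfg.get("dt", 0.1),
        duration=cfg.get("duration", 120.0),
        t0=cfg.get("t0", 0.0),
    )


def parse_bolus_spec(cfg: dict):
    """Build a gamma-variate or hypoxic bolus spec from a config mapping."""
    kind = cfg.get("kind", "gamma_variate")
    if kind == "gamma_variate":
        return GammaVariateSpec(
            a=cfg.get("a", 2.0), b=cfg.get("b", 2.5),
            c=cfg.get("c", 3.0), onset=cfg.get("onset", 10.0),
        )
    if kind == "hypoxic":
        return HypoxicBolusSpec(
            base_sat=cfg.get("base_sat", 0.98),
            target_sat=cfg.get("target_sat", 0.75),
            plateau_duration=cfg.get("plateau_duration", 30.0),
            onset=cfg.get("onset", 10.0),
            rise_tau=cfg.get("rise_tau", 5.0),
            return_mode=ReturnMode(cfg.get("return_mode", "exponential")),
        )
    raise ValueError(f"unknown bolus kind {kind!r}")


def parse_transport(cfg: dict) -> TransportSpec:
    res_cfg = cfg.get("residue", {})
    kind = res_cfg.get("kind", "biexponential")
    if kind == "biexponential":
        residue = BiexponentialResidue(
            f=res_cfg.get("f", 0.92),
            t1=res_cfg.get("t1", 0.68),
            t2=res_cfg.get("t2", 0.05),
        )
    elif kind == "monoexponential":
        residue = MonoexponentialResidue(mtt=res_cfg.get("mtt", 4.0))
    else:
        raise ValueError(f"unknown residue kind {kind!r}")
    return TransportSpec(residue, delay=cfg.get("delay", 0.0))


def parse_paradigm(cfg: dict | str) -> ParadigmSpec:
    """A named preset ('gd_standard', 'dohb_large_high', ...) or a custom spec."""
    if isinstance(cfg, str):
        return PARADIGMS[cfg]
    if "name" in cfg and cfg["name"] in PARADIGMS and len(cfg) == 1:
        return PARADIGMS[cfg["name"]]
    agent = Agent(cfg.get("agent", "dohb"))
    return ParadigmSpec(
        name=cfg.get("name", "custom"),
        agent=agent,
        base_sat=cfg.get("base_sat"),
        target_sat=cfg.get("target_sat"),
        peak_mM=cfg.get("peak_mM"),
        plateau_duration=cfg.get("plateau_duration", 30.0),
        rise_tau=cfg.get("rise_tau", 5.0),
        onset=cfg.get("onset", 10.0),
    )


def parse_phantom(cfg: dict | None) -> PhantomSpec:
    cfg = cfg or {}
    return PhantomSpec(
        grid_shape=tuple(cfg.get("grid_shape", (32, 32, 8))),
        noise_sigma=cfg.get("noise_sigma", 0.0),
        seed=cfg.get("seed", 0),
        TR=cfg.get("TR", 1.5),
        duration=cfg.get("duration", 120.0),
        dt=cfg.get("dt", 0.1),
    )
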