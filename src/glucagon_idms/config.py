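"""Run configuration: a single human-editable YAML file for the pipeline.

The config captures everything the analysis depends on — species
definitions, transition-list layout, calibration weighting, kinetics
options, the simulation scenario and the seed — so a run is reproducible
from the file plus the package version.  Unknown keys are rejected rather
than ignored, and a loaded config dumps back to an equivalent document.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict

import yaml

from glucagon_idms.species import TransitionLayout

__all__ = ["RunConfig", "load_config", "dump_config"]

_TOP_KEYS = {
    "species",
    "transition_layout",
    "calibration_weighting",
    "kinetics",
    "simulation",
    "seed",
    "output_dir",
}
_KINETICS_KEYS = {"ttr_denominator", "smoothing_window", "pool_fraction"}
_LAYOUT_KEYS = {
    "precursor_charge",
    "precursor_isotopologues_light",
    "precursor_isotopologues_labeled",
    "fragments",
    "fragment_charge",
    "fragment_isotopologues",
    "proton_mass",
}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    species: list[dict] = field(default_factory=list)  # empty -> built-ins
    transition_layout: TransitionLayout = field(default_factory=TransitionLayout)
    calibration_weighting: str = "none"
    ttr_denominator: str = "total"
    smoothing_window: int = 1
    pool_fraction: float = 1.0
    simulation: dict = field(default_factory=dict)
    seed: int = 0
    output_dir: str = "."

    def to_mapping(self) -> dict:
        return {
            "species": self.species,
            "transition_layout": asdict(self.transition_layout),
            "calibration_weighting": self.calibration_weighting,
            "kinetics": {
                "ttr_denominator": self.ttr_denominator,
                "smoothing_window": self.smoothing_window,
                "pool_fraction": self.pool_fraction,
            },
            "simulation": self.simulation,
            "seed": self.seed,
            "output_dir": self.output_dir,
        }

    def config_hash(self) -> str:
        text = yaml.safe_dump(self.to_mapping(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def _check_keys(mapping: dict, allowed: set[str], where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"unknown {where} config keys: {sorted(unknown)}")


def load_config(source) -> RunConfig:
    """Load a RunConfig from a YAML path, file object or string."""
    if hasattr(source, "read"):
        data = yaml.safe_load(source)
    elif isinstance(source, str) and "\n" in source:
        data = yaml.safe_load(source)
    else:
        with open(source) as fh:
            data = yaml.safe_load(fh)
    data = data or {}
    _check_keys(data, _TOP_KEYS, "top-level")
    kin = data.get("kinetics", {}) or {}
    _check_keys(kin, _KINETICS_KEYS, "kinetics")
    layout_map = data.get("transition_layout", {}) or {}
    _check_keys(layout_map, _LAYOUT_KEYS, "transition_layout")
    layout_kwargs = {
        k: tuple(v) if isinstance(v, list) else v for k, v in layout_map.items()
    }
    return RunConfig(
        species=data.get("species", []) or [],
        transition_layout=TransitionLayout(**layout_kwargs),
        calibration_weighting=data.get("calibration_weighting", "none"),
        ttr_denominator=kin.get("ttr_denominator", "total"),
        smoothing_window=int(kin.get("smoothing_window", 1)),
        pool_fraction=float(kin.get("pool_fraction", 1.0)),
        simulation=data.get("simulation", {}) or {},
        seed=int(data.get("seed", 0)),
        output_dir=str(data.get("output_dir", ".")),
    )


def dump_config(config: RunConfig) -> str:
    return yaml.safe_dump(config.to_mapping(), sort_keys=False)
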