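"""Configuration files and reproducibility manifests.

A run configuration is a flat TOML or YAML mapping; recognised keys
(all optional, defaults in parentheses):

    growth_rate_tag      ("mu1.1")   bundled parameter set
    volume_um3           (0.064)    reaction volume
    grid_spacing_nm      (20.0)     lattice spacing h
    relative_concentration (1.0)    joint dilution factor
    D_m2_per_s           (2.567e-12)
    k_diss_per_s         (1.0)
    max_rate_aa_per_s    (24.0)     t_cat = 1 / this
    jump_convention      ("published")
    burn_in_steps        (1000)
    stop_steps           (5000)
    seeds                (10)       replicate count
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import sys
import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .params import (
    KineticParams,
    LatticeSpec,
    ScenarioConfig,
    load_default_tables,
    rescale_volume,
    scale_scenario,
)

__all__ = ["RunManifest", "load_config", "scenario_from_config"]


@dataclass
class RunManifest:
    """Reproducibility metadata written next to every CLI output."""

    config_digest: str
    master_seed: int
    package_version: str
    command_line: str = ""
    started: str = ""
    finished: str = ""
    outputs: list[str] = field(default_factory=list)

    def start(self) -> "RunManifest":
        self.started = datetime.datetime.now(datetime.timezone.utc).isoformat()
        self.command_line = " ".join(sys.argv)
        return self

    def finish(self, path) -> None:
        self.finished = datetime.datetime.now(datetime.timezone.utc).isoformat()
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


def load_config(path) -> dict:
    path = Path(path)
    if path.suffix in (".toml", ".tml"):
        return tomllib.loads(path.read_text())
    return yaml.safe_load(path.read_text()) or {}


def scenario_from_config(cfg: dict) -> tuple[ScenarioConfig, dict]:
    """Build a ScenarioConfig from a flat config mapping.

    Returns the scenario and the residual run options (seeds, ...).
    """
    machines, trna, kinetics, lattice = load_default_tables(cfg.get("growth_rate_tag", "mu1.1"))
    kin_kwargs = {}
    if "D_m2_per_s" in cfg:
        kin_kwargs["D"] = float(cfg["D_m2_per_s"])
    if "k_diss_per_s" in cfg:
        kin_kwargs["k_diss"] = float(cfg["k_diss_per_s"])
    if "max_rate_aa_per_s" in cfg:
        kin_kwargs["t_cat"] = 1.0 / float(cfg["max_rate_aa_per_s"])
    if "burn_in_steps" in cfg:
        kin_kwargs["burn_in_steps"] = int(cfg["burn_in_steps"])
    if "stop_steps" in cfg:
        kin_kwargs["stop_steps"] = int(cfg["stop_steps"])
    if "jump_convention" in cfg:
        kin_kwargs["jump_convention"] = str(cfg["jump_convention"])
    if kin_kwargs:
        kinetics = replace(kinetics, **kin_kwargs)
    if "grid_spacing_nm" in cfg:
        lattice = LatticeSpec.from_volume(lattice.volume_um3, h_nm=float(cfg["grid_spacing_nm"]))
    scenario = ScenarioConfig(machines=machines, trna=trna, kinetics=kinetics, lattice=lattice)
    if "volume_um3" in cfg and float(cfg["volume_um3"]) != scenario.lattice.volume_um3:
        scenario = rescale_volume(scenario, float(cfg["volume_um3"]))
    if "relative_concentration" in cfg and float(cfg["relative_concentration"]) != 1.0:
        scenario = scale_scenario(scenario, float(cfg["relative_concentration"]))
    run_opts = {"seeds": int(cfg.get("seeds", 10))}
    return scenario, run_opts
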