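"""Run-configuration loading and validation.

A run is described by a YAML (or JSON) file layered over the shipped
``default.yaml``.  Unknown keys are rejected with the offending key name so
typos fail loudly rather than silently using a default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .community import Community, TraitGenConfig, generate_community, read_community
from .kernel import DistanceGrid, KernelParams
from .network import NicheConfig

__all__ = ["ConfigError", "RunConfig", "load_config", "default_config_dict"]


class ConfigError(ValueError):
    """Invalid or unknown run-configuration content."""


def default_config_dict() -> dict:
    """The shipped defaults as a plain nested dict."""
    text = resources.files("seedlink").joinpath("default.yaml").read_text()
    return yaml.safe_load(text)


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = dict(defaults)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigError(f"unknown configuration key: {here!r}")
        if isinstance(defaults[key], dict) and isinstance(value, dict):
            out[key] = _merge(defaults[key], value, here)
        else:
            out[key] = value
    return out


@dataclass
class RunConfig:
    """A fully resolved run configuration."""

    raw: dict

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    @property
    def output_dir(self) -> Path:
        return Path(self.raw["output_dir"])

    @property
    def trait_matching(self) -> bool:
        return bool(self.raw["trait_matching"])

    @property
    def s_levels(self) -> list[float]:
        return [float(s) for s in self.raw["niche"]["s_levels"]]

    @property
    def n_events(self) -> int:
        return int(self.raw["events"]["n_per_plant"])

    @property
    def event_mode(self) -> str:
        return str(self.raw["events"]["mode"])

    @property
    def n_iterations(self) -> int:
        return int(self.raw["grid"]["iterations"])

    def trait_gen_config(self) -> TraitGenConfig:
        c = self.raw["community"]
        return TraitGenConfig(
            n_plants=int(c["n_plants"]),
            n_birds=int(c["n_birds"]),
            seed=self.seed,
            fruit_diameter_log_mean=float(c["fruit_diameter_log_mean"]),
            fruit_diameter_log_sd=float(c["fruit_diameter_log_sd"]),
            plant_height_log_mean=float(c["plant_height_log_mean"]),
            plant_height_log_sd=float(c["plant_height_log_sd"]),
            fruit_mass_coeff=float(c["fruit_mass_coeff"]),
            body_mass_log_mean=float(c["body_mass_log_mean"]),
            body_mass_log_sd=float(c["body_mass_log_sd"]),
            gape_coeff=float(c["gape_coeff"]),
            gape_exp=float(c["gape_exp"]),
            gape_log_noise_sd=float(c["gape_log_noise_sd"]),
            wing_pointedness_log_mean=float(c["wing_pointedness_log_mean"]),
            wing_pointedness_log_sd=float(c["wing_pointedness_log_sd"]),
            plant_abundance_coeffs=tuple(c["plant_abundance_coeffs"]),
            bird_abundance_coeffs=tuple(c["bird_abundance_coeffs"]),
        )

    def community(self) -> Community:
        c = self.raw["community"]
        if c["plants_csv"] and c["birds_csv"]:
            return read_community(c["plants_csv"], c["birds_csv"], self.trait_gen_config())
        return generate_community(self.trait_gen_config())

    def niche_template(self) -> NicheConfig:
        n = self.raw["niche"]
        return NicheConfig(
            s=self.s_levels[0],
            skew_ratio=float(n["skew_ratio"]),
            sigma_match=float(n["sigma_match"]),
            sigma_strata=float(n["sigma_strata"]),
            s_exponent=float(n["s_exponent"]),
        )

    def kernel_params(self) -> KernelParams:
        k = self.raw["kernel"]
        return KernelParams(
            gpt_coeff=tuple(float(x) for x in k["gpt_coeff"]),
            speed_coeff=tuple(float(x) for x in k["speed_coeff"]),
            calibration=float(k["calibration"]),
            retention_cv=float(k["retention_cv"]),
            retention_max_factor=float(k["retention_max_factor"]),
        )

    def distance_grid(self) -> DistanceGrid:
        g = self.raw["grid"]
        return DistanceGrid(
            np.arange(
                float(g["distance_start"]),
                float(g["distance_stop"]) + 1e-9,
                float(g["distance_step"]),
            )
        )

    def richness_levels(self, n_plants: int) -> list[int]:
        levels = self.raw["grid"]["richness_levels"]
        if levels is None:
            return list(range(n_plants + 1))
        return [int(r) for r in levels]

    def dump(self, path: str | Path) -> None:
        """Echo the resolved configuration so a run can be reproduced from it."""
        Path(path).write_text(yaml.safe_dump(self.raw, sort_keys=False))


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and resolve a run configuration (defaults only when ``path=None``)."""
    merged = default_config_dict()
    if path is not None:
        text = Path(path).read_text()
        user = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        if user is None:
            user = {}
        if not isinstance(user, dict):
            raise ConfigError("configuration file must contain a mapping")
        merged = _merge(merged, user)
    cfg = RunConfig(merged)
    if not cfg.s_levels:
        raise ConfigError("niche.s_levels must be non-empty")
    if cfg.n_iterations < 1:
        raise ConfigError("grid.iterations must be >= 1")
    return cfg
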