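"""Run configuration: YAML-backed settings with strict key checking."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .geo import GEOConfig, PropensitySchedule
from .pipeline import FitnessWeights
from .synthetic import LesionGenParams


@dataclass(frozen=True)
class GeoSettings:
    population_size: int = 8
    iterations: int = 10
    pa0: float = 0.5
    paT: float = 2.0
    pc0: float = 1.0
    pcT: float = 0.5

    def to_geo_config(self, seed: int) -> GEOConfig:
        return GEOConfig(
            population_size=self.population_size,
            iterations=self.iterations,
            seed=seed,
            schedule=PropensitySchedule(self.pa0, self.paT, self.pc0, self.pcT,
                                        T=self.iterations),
        )


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    metric_mode: str = "standard"
    pixels_per_image: int = 500
    tune_pixels_per_image: int = 200
    val_fraction: float = 0.25
    geo: GeoSettings = field(default_factory=GeoSettings)
    weights: FitnessWeights = field(default_factory=FitnessWeights)
    generator: LesionGenParams = field(default_factory=LesionGenParams)

    def __post_init__(self):
        if self.metric_mode not in ("standard", "paper_fidelity"):
            raise ValueError(f"unknown metric_mode {self.metric_mode!r}")
        if not (0.0 < self.val_fraction < 1.0):
            raise ValueError("val_fraction must be in (0, 1)")


def _build(cls, data: dict, context: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(
            f"unknown configuration key {sorted(unknown)[0]!r} in {context}"
        )
    return data


def config_from_dict(data: Optional[dict]) -> RunConfig:
    """Build a RunConfig, rejecting unknown keys with the offending name."""
    data = dict(data or {})
    _build(RunConfig, data, "run config")
    kwargs = {}
    if "geo" in data:
        kwargs["geo"] = GeoSettings(**_build(GeoSettings, data.pop("geo"), "geo"))
    if "weights" in data:
        kwargs["weights"] = FitnessWeights(
            **_build(FitnessWeights, data.pop("weights"), "weights"))
    if "generator" in data:
        gen = data.pop("generator")
        for key in ("skin_tone", "n_color_patches_benign",
                    "n_color_patches_malignant", "base_radius_frac_benign",
                    "base_radius_frac_malignant", "harmonic_amps_benign",
                    "harmonic_amps_malignant", "ellipticity_benign",
                    "ellipticity_malignant"):
            if key in gen:
                gen[key] = tuple(gen[key])
        kwargs["generator"] = LesionGenParams(
            **_build(LesionGenParams, gen, "generator"))
    return RunConfig(**data, **kwargs)


def load_config(path=None) -> RunConfig:
    if path is None:
        return RunConfig()
    with open(Path(path)) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})
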