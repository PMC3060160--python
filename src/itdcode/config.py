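"""YAML/JSON configuration for the analysis defaults.

Keys mirror the model parameters: head geometry (inter_ear_distance_m,
sound_speed_m_s, prior_grid_size), the rate-noise law (v1, v2,
stimulus_duration_s, noise_scale), and the synthetic-population
generator.  Any subset of keys may be given; the rest fall back to the
package defaults.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .acoustics import HeadGeometry
from .noise_model import RateNoiseModel
from .synthetic_data import PopulationGeneratorConfig, ShapeDistribution


@dataclass(frozen=True)
class AnalysisConfig:
    geometry: HeadGeometry = field(default_factory=HeadGeometry)
    prior_grid_size: int = 201
    noise: RateNoiseModel = field(default_factory=RateNoiseModel)
    generator: PopulationGeneratorConfig = field(
        default_factory=PopulationGeneratorConfig
    )


def load_config(path=None) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML or JSON file."""
    if path is None:
        return AnalysisConfig()
    text = Path(path).read_text()
    raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    raw = raw or {}
    geometry = HeadGeometry(
        inter_ear_distance=raw.get("inter_ear_distance_m", HeadGeometry().inter_ear_distance),
        sound_speed=raw.get("sound_speed_m_s", HeadGeometry().sound_speed),
    )
    base_noise = RateNoiseModel()
    noise = RateNoiseModel(
        v1=raw.get("v1", base_noise.v1),
        v2=raw.get("v2", base_noise.v2),
        duration=raw.get("stimulus_duration_s", base_noise.duration),
        noise_scale=raw.get("noise_scale", base_noise.noise_scale),
    )
    gen_raw = raw.get("generator", {})
    shape_raw = gen_raw.get("shapes", {})
    generator = PopulationGeneratorConfig(
        n_cells=gen_raw.get("n_cells", 153),
        bf_band=tuple(gen_raw.get("bf_band", (800.0, 1000.0))),
        mean_best_phase=gen_raw.get("mean_best_phase", 0.2),
        best_phase_spread=gen_raw.get("best_phase_spread", 0.1),
        cd_jitter_ms=gen_raw.get("cd_jitter_ms", 0.05),
        shapes=ShapeDistribution(**shape_raw) if shape_raw else ShapeDistribution(),
        seed=gen_raw.get("seed", 0),
    )
    return AnalysisConfig(
        geometry=geometry,
        prior_grid_size=raw.get("prior_grid_size", 201),
        noise=noise,
        generator=generator,
    )
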