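"""Synthetic pre/post age-rating datasets.

The original aftereffect data (per-face pre- and post-adaptation age
judgments under three adapting conditions) are not publicly deposited, so
this module generates datasets with the same statistical structure: test
faces whose pre-adaptation perceived ages span the adult range, three
adapting conditions (young / middle / old), and aftereffects produced by a
chosen truth model plus rating noise of a few years.

Generative recipe (per condition):

1. True pre-adaptation perceived ages are laid out evenly over
   ``[test_age_min, test_age_max]`` with uniform jitter of up to half the
   grid spacing, emulating a face set that tiles the adult age range.
2. The truth model (renormalization, repulsion, or none) gives each face its
   noiseless aftereffect at its true pre age.
3. Each simulated observer contributes a pre rating
   ``pre_true + N(0, pre_rating_noise_sd)`` and a post rating
   ``pre_true + aftereffect + N(0, rating_noise_sd)``; recorded pre/post
   ages are the across-observer means.

The recorded aftereffect therefore deviates from the truth curve with
standard deviation ``sqrt(pre_sd^2 + post_sd^2) / sqrt(n_observers)``.
Defaults (24 faces per condition, one observer, post-rating noise SD of
3 years, no pre-rating noise) put synthetic no-model RMS values in the
~2.5-3.5-year range typical of age-rating experiments.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .models_core import (
    CONDITIONS,
    AftereffectPoint,
    GDRepulsionParams,
    NormalizationParams,
    StudyDesign,
    predict_condition,
)

TRUTH_MODELS = ("normalization", "repulsion", "none")

CSV_COLUMNS = ["condition", "face_id", "pre_age", "post_age", "aftereffect"]


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to regenerate a dataset byte-for-byte."""

    design: StudyDesign = field(default_factory=StudyDesign)
    truth_model: str = "normalization"
    truth_params: GDRepulsionParams | NormalizationParams | None = None
    n_faces_per_condition: int = 24
    n_observers: int = 1
    rating_noise_sd: float = 3.0
    pre_rating_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.truth_model not in TRUTH_MODELS:
            raise ConfigError(f"unknown truth_model {self.truth_model!r}")
        if self.n_faces_per_condition < 2:
            raise ConfigError("n_faces_per_condition must be >= 2")
        if self.n_observers < 1:
            raise ConfigError("n_observers must be >= 1")
        if self.rating_noise_sd < 0 or self.pre_rating_noise_sd < 0:
            raise ConfigError("noise SDs must be >= 0")
        if self.truth_model != "none" and self.truth_params is None:
            default = (
                NormalizationParams(gain_k=0.1, norm_age=self.design.norm_age)
                if self.truth_model == "normalization"
                else GDRepulsionParams(amplitude_A=2.4, sigma=20.0)
            )
            object.__setattr__(self, "truth_params", default)


@dataclass
class RatingDataset:
    """A list of per-face aftereffect points plus provenance."""

    points: list[AftereffectPoint]
    config_echo: SimulationConfig | str | None = None

    def conditions(self) -> list[str]:
        present = {p.condition for p in self.points}
        return [c for c in CONDITIONS if c in present]

    def subset(self, condition: str) -> "RatingDataset":
        return RatingDataset(
            [p for p in self.points if p.condition == condition], self.config_echo
        )

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(pre_ages, aftereffects, condition labels) in row order."""
        pre = np.array([p.pre_age for p in self.points], dtype=float)
        after = np.array([p.aftereffect for p in self.points], dtype=float)
        cond = np.array([p.condition for p in self.points])
        return pre, after, cond

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "condition": p.condition,
                    "face_id": p.face_id,
                    "pre_age": p.pre_age,
                    "post_age": p.post_age,
                    "aftereffect": p.aftereffect,
                }
                for p in self.points
            ],
            columns=CSV_COLUMNS,
        )

    def __len__(self) -> int:
        return len(self.points)


def _truth_prediction(config: SimulationConfig, condition: str, ages: np.ndarray) -> np.ndarray:
    if config.truth_model == "none":
        return np.zeros_like(ages)
    return predict_condition(config.design, condition, config.truth_params, ages)


def generate_dataset(config: SimulationConfig) -> RatingDataset:
    """Simulate one dataset under ``config``; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    design = config.design
    n = config.n_faces_per_condition
    points: list[AftereffectPoint] = []
    grid = np.linspace(design.test_age_min, design.test_age_max, n)
    half_gap = 0.5 * (grid[1] - grid[0])
    for condition in CONDITIONS:
        jitter = rng.uniform(-half_gap, half_gap, size=n)
        pre_true = np.clip(grid + jitter, design.test_age_min, design.test_age_max)
        truth = _truth_prediction(config, condition, pre_true)
        pre_noise = rng.normal(
            0.0, config.pre_rating_noise_sd, size=(config.n_observers, n)
        )
        post_noise = rng.normal(
            0.0, config.rating_noise_sd, size=(config.n_observers, n)
        )
        pre_rated = (pre_true + pre_noise).mean(axis=0)
        post_rated = (pre_true + truth + post_noise).mean(axis=0)
        for i in range(n):
            points.append(
                AftereffectPoint(
                    condition=condition,
                    face_id=f"{condition}_{i:03d}",
                    pre_age=float(pre_rated[i]),
                    post_age=float(post_rated[i]),
                )
            )
    return RatingDataset(points=points, config_echo=config)


def write_fixture(dataset: RatingDataset, path: str | Path) -> Path:
    """Write the dataset as a ratings CSV (round-trips through the reader)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dataset.to_dataframe().to_csv(path, index=False, float_format="%.12g")
    return path
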