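"""Body-mass-driven seed-dispersal distances.

Seed-dispersal distance is the product of how long a seed stays in a bird's
gut and how fast and how far that bird actually displaces while carrying it.
Both ingredients scale allometrically with body mass: larger birds retain
seeds longer and fly faster, so they move seeds farther.  Per event the
retention time is stochastic (log-normal around the allometric gut passage
time) while flight speed is deterministic, and a calibration factor < 1
absorbs time spent perched and deviations from straight-line flight.

Dispersal success against a grid of between-patch distances is a simple
threshold: an event dispersed at least as far as the patch distance can
reach the patch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import Community
from .network import DispersalEventSet

__all__ = [
    "KernelParams",
    "DistanceGrid",
    "DistancedEventSet",
    "gut_passage_time",
    "flight_speed",
    "sample_distances",
    "reach_indicator",
    "reach_matrix",
]


@dataclass(frozen=True)
class KernelParams:
    """Allometric movement parameters.

    ``gpt_coeff = (a_g, b_g)``: gut passage time ``a_g * M**b_g`` in minutes
    for body mass M in grams.  ``speed_coeff = (a_v, b_v)``: flight speed
    ``a_v * M**b_v`` in m/min.  ``calibration`` in (0, 1] scales the raw
    speed x retention displacement down to an effective dispersal distance.
    ``retention_cv`` is the coefficient of variation of the log-normal
    per-event retention time (0 switches the stochasticity off) and
    ``retention_max_factor`` truncates individual retention times at that
    multiple of the bird's mean gut passage time, keeping the community
    kernel bounded (a seed is not carried indefinitely).
    """

    gpt_coeff: tuple[float, float] = (12.0, 0.25)
    speed_coeff: tuple[float, float] = (360.0, 0.15)
    calibration: float = 0.004
    retention_cv: float = 0.5
    retention_max_factor: float = 3.5

    def __post_init__(self) -> None:
        if self.gpt_coeff[0] <= 0 or self.speed_coeff[0] <= 0:
            raise ValueError("allometric intercepts must be positive")
        if not (0 < self.calibration <= 1):
            raise ValueError("calibration must lie in (0, 1]")
        if self.retention_cv < 0:
            raise ValueError("retention_cv must be >= 0")
        if self.retention_max_factor <= 1:
            raise ValueError("retention_max_factor must exceed 1")


def _power_law(mass, coeffs, what: str):
    m = np.asarray(mass, dtype=float)
    if np.any(~np.isfinite(m)) or np.any(m <= 0):
        raise ValueError(f"body mass must be positive and finite for {what}")
    out = coeffs[0] * m ** coeffs[1]
    if np.ndim(mass) == 0:
        return float(out)
    return out


def gut_passage_time(body_mass, params: KernelParams):
    """Seed retention time (minutes) from body mass (g): ``a_g * M**b_g``."""
    return _power_law(body_mass, params.gpt_coeff, "gut passage time")


def flight_speed(body_mass, params: KernelParams):
    """Flight speed (m/min) from body mass (g): ``a_v * M**b_v``."""
    return _power_law(body_mass, params.speed_coeff, "flight speed")


@dataclass(frozen=True)
class DistanceGrid:
    """Ordered between-patch distances (m); default 0-600 m in 10 m steps."""

    distances: np.ndarray = field(default_factory=lambda: np.arange(0.0, 601.0, 10.0))

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        if d.ndim != 1 or d.size == 0:
            raise ValueError("distance grid must be a non-empty 1-D array")
        if np.any(d < 0) or np.any(np.diff(d) <= 0):
            raise ValueError("distances must be non-negative and strictly increasing")
        object.__setattr__(self, "distances", d)

    def __len__(self) -> int:
        return len(self.distances)


@dataclass
class DistancedEventSet:
    """Dispersal events annotated with a sampled dispersal distance (m)."""

    events: DispersalEventSet
    distances: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        if d.shape != (len(self.events),):
            raise ValueError("need exactly one distance per event")
        if np.any(~np.isfinite(d)) or np.any(d < 0):
            raise ValueError("distances must be finite and non-negative")
        self.distances = d

    def __len__(self) -> int:
        return len(self.events)

    def to_frame(self) -> pd.DataFrame:
        frame = self.events.to_frame()
        frame["distance_m"] = self.distances
        return frame


def sample_distances(
    events: DispersalEventSet,
    community: Community,
    params: KernelParams,
    seed=None,
) -> DistancedEventSet:
    """Draw a dispersal distance for every event.

    Retention time is log-normal with mean equal to the bird's allometric
    gut passage time and coefficient of variation ``retention_cv``,
    truncated at ``retention_max_factor`` times that mean; distance is
    ``calibration * flight_speed * retention``.  Deterministic when
    ``retention_cv = 0`` or under a fixed seed.
    """
    if np.any(events.bird_index >= community.n_birds):
        raise ValueError("event refers to a bird outside the community")
    rng = np.random.default_rng(seed)
    mass = community.birds["body_mass_g"].to_numpy()[events.bird_index]
    gpt = gut_passage_time(mass, params)
    speed = flight_speed(mass, params)
    if len(events) == 0:
        retention = np.empty(0)
    elif params.retention_cv == 0:
        retention = np.asarray(gpt, dtype=float)
    else:
        sigma2 = np.log1p(params.retention_cv**2)
        mu = np.log(gpt) - sigma2 / 2.0
        retention = np.minimum(
            rng.lognormal(mu, np.sqrt(sigma2)), params.retention_max_factor * gpt
        )
    return DistancedEventSet(events=events, distances=params.calibration * speed * retention)


def reach_indicator(event_distance, patch_distance):
    """1 if the event dispersed at least as far as the patch, else 0.

    Inclusive at equality: a seed moved exactly the between-patch distance
    can reach the patch.
    """
    ed = np.asarray(event_distance, dtype=float)
    pd_ = np.asarray(patch_distance, dtype=float)
    if np.any(ed < 0) or np.any(pd_ < 0):
        raise ValueError("distances must be non-negative")
    out = (ed >= pd_).astype(np.int64)
    if np.ndim(event_distance) == 0 and np.ndim(patch_distance) == 0:
        return int(out)
    return out


def reach_matrix(distanced: DistancedEventSet, grid: DistanceGrid) -> np.ndarray:
    """Events x distances {0,1} matrix of potential dispersal success.

    Each row is non-increasing along the grid (a survival curve), and the
    column at distance 0 is all ones.
    """
    return reach_indicator(distanced.distances[:, None], grid.distances[None, :])
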