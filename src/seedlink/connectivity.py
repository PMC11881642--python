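"""Community-level plant functional connectivity.

Connectivity is measured by combining, per dispersal event, whether the
seed travels far enough to reach the target patch (the distance component)
with the probability that its carrier chooses to fly there (the relative
attractiveness of the target).  Summing the resulting arrival probabilities
over each plant's events gives the expected number of seeds of that species
reaching the patch; a species whose expected total falls below one seed is
treated as not arriving at all.  The spread of the arriving seed counts
across plant species is summarized as the effective seed diversity
(exponential Shannon entropy), the second connectivity measure; species
dropped by the one-seed floor contribute no arriving seeds and hence no
seed diversity.

`run_grid` sweeps the full factorial of specialization level, between-patch
distance, and target-patch richness (with replicated random patch
compositions) and returns a long-format results table.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .attractiveness import (
    Patch,
    attractiveness_without_matching,
    effective_resource_diversity,
    general_attractiveness,
    relative_attractiveness,
    sample_target_patch,
)
from .community import Community
from .kernel import DistanceGrid, KernelParams, reach_matrix, sample_distances
from .network import (
    DispersalEventSet,
    InteractionMatrix,
    NicheConfig,
    h2_prime,
    interaction_probabilities,
    sample_dispersal_events,
)

__all__ = [
    "Scenario",
    "ConnectivityResult",
    "arrival_probabilities",
    "species_probability_sums",
    "seeds_per_species",
    "effective_seed_diversity",
    "run_scenario",
    "run_grid",
    "RESULT_COLUMNS",
]

RESULT_COLUMNS = (
    "s",
    "H2_prime",
    "distance_m",
    "richness",
    "iteration",
    "effective_resource_diversity",
    "n_seeds",
    "effective_seed_diversity",
)


@dataclass(frozen=True)
class Scenario:
    """One cell of the experimental grid."""

    s: float
    patch_distance: float
    target_richness: int
    iteration: int = 0
    seed: int | None = None


@dataclass
class ConnectivityResult:
    """Connectivity measures for one scenario.

    ``species_sums`` holds the raw per-species arrival-probability sums;
    ``seeds_per_species`` applies the one-seed floor (sums below 1 drop to
    0) and is the input to the seed-diversity measure.
    """

    scenario: Scenario
    plant_ids: list[str]
    species_sums: np.ndarray
    seeds_per_species: np.ndarray
    n_seeds_total: float
    effective_seed_diversity: float
    effective_resource_diversity: float
    h2_prime: float


def arrival_probabilities(reach: np.ndarray, ra: np.ndarray, events: DispersalEventSet) -> np.ndarray:
    """Per-event arrival probability: reach indicator times the carrier's RA.

    ``reach`` may be a vector (one patch distance) or an events x distances
    matrix; the event's bird RA multiplies each row.
    """
    reach = np.asarray(reach, dtype=float)
    ra = np.asarray(ra, dtype=float)
    weights = ra[events.bird_index]
    if reach.ndim == 1:
        return reach * weights
    return reach * weights[:, None]


def species_probability_sums(arrival: np.ndarray, events: DispersalEventSet, n_plants: int) -> np.ndarray:
    """Sum per-event arrival probabilities within each plant species."""
    arrival = np.asarray(arrival, dtype=float)
    if arrival.ndim == 1:
        return np.bincount(events.plant_index, weights=arrival, minlength=n_plants)
    out = np.zeros((n_plants,) + arrival.shape[1:])
    np.add.at(out, events.plant_index, arrival)
    return out


def _floor_rule(sums: np.ndarray) -> np.ndarray:
    return np.where(np.asarray(sums, dtype=float) < 1.0, 0.0, sums)


def seeds_per_species(arrival: np.ndarray, events: DispersalEventSet, n_plants: int) -> np.ndarray:
    """Expected seed count per plant species with the one-seed floor.

    The per-species sum of arrival probabilities is the expected number of
    seeds of that species reaching the patch; an expectation below one seed
    is set to 0 (the species effectively fails to arrive).
    """
    return _floor_rule(species_probability_sums(arrival, events, n_plants))


def effective_seed_diversity(sums) -> float:
    """Effective number of plant species among arriving seeds.

    Exponential of the Shannon entropy of the per-species seed counts
    (normalized to proportions); 0 when nothing arrives.  The pipeline
    feeds it the floored counts, so species that fail the one-seed floor
    add no diversity.
    """
    s = np.asarray(sums, dtype=float)
    if np.any(s < 0):
        raise ValueError("probability sums must be non-negative")
    total = s.sum()
    if total <= 0:
        return 0.0
    q = s[s > 0] / total
    return float(np.exp(-(q * np.log(q)).sum()))


def _stage_seed(master: int | None, *key: int):
    if master is None:
        return None
    return np.random.SeedSequence([int(master), *key])


def run_scenario(
    community: Community,
    scenario: Scenario,
    niche_template: NicheConfig,
    kernel_params: KernelParams | None = None,
    n_events: int = 100,
    event_mode: str = "uniform_per_plant",
    trait_matching: bool = True,
) -> ConnectivityResult:
    """Execute the full pipeline for a single grid cell.

    Network build, event sampling, distance sampling, target-patch sampling
    and the arrival combination, deterministic under ``scenario.seed``.
    ``niche_template`` supplies the niche shape; its ``s`` is replaced by
    the scenario's.
    """
    kernel_params = kernel_params if kernel_params is not None else KernelParams()
    niche = replace(niche_template, s=scenario.s)
    matrix = interaction_probabilities(community, niche)
    h2 = h2_prime(matrix.w)
    events = sample_dispersal_events(
        matrix, community, n_events=n_events, mode=event_mode,
        seed=_stage_seed(scenario.seed, 1),
    )
    distanced = sample_distances(events, community, kernel_params, seed=_stage_seed(scenario.seed, 2))
    patch = sample_target_patch(
        community, scenario.target_richness, seed=_stage_seed(scenario.seed, 3)
    )
    source = Patch.from_community(community)
    if trait_matching:
        a_target = general_attractiveness(patch, matrix)
        a_source = general_attractiveness(source, matrix)
    else:
        a_target = attractiveness_without_matching(patch, community.n_birds)
        a_source = attractiveness_without_matching(source, community.n_birds)
    ra = relative_attractiveness(a_target, a_source)

    reach = (distanced.distances >= scenario.patch_distance).astype(float)
    arrival = arrival_probabilities(reach, ra, events)
    sums = species_probability_sums(arrival, events, community.n_plants)
    seeds = _floor_rule(sums)
    return ConnectivityResult(
        scenario=scenario,
        plant_ids=community.plant_ids,
        species_sums=sums,
        seeds_per_species=seeds,
        n_seeds_total=float(seeds.sum()),
        effective_seed_diversity=effective_seed_diversity(seeds),
        effective_resource_diversity=effective_resource_diversity(patch),
        h2_prime=h2,
    )


def run_grid(
    community: Community,
    s_levels,
    grid: DistanceGrid,
    richness_levels,
    n_iterations: int = 100,
    seed: int | None = None,
    niche_template: NicheConfig | None = None,
    kernel_params: KernelParams | None = None,
    n_events: int = 100,
    event_mode: str = "uniform_per_plant",
    trait_matching: bool = True,
) -> pd.DataFrame:
    """Sweep the (s, distance, richness, iteration) experimental grid.

    Per specialization level one source network is built and one pool of
    dispersal events with distances is sampled; iterations then vary only
    the composition of the target patch at each richness level, so each
    iteration draws a fresh random subset of plant species.  Patch
    compositions are seeded independently of ``s`` and are therefore shared
    across specialization levels, making the levels directly comparable.

    Returns a long-format table with one row per grid cell
    (columns in :data:`RESULT_COLUMNS`).
    """
    s_levels = list(s_levels)
    richness_levels = [int(r) for r in richness_levels]
    if not s_levels or not richness_levels or n_iterations < 1:
        raise ValueError("grids must be non-empty and n_iterations >= 1")
    niche_template = niche_template if niche_template is not None else NicheConfig(s=s_levels[0])
    kernel_params = kernel_params if kernel_params is not None else KernelParams()
    source = Patch.from_community(community)
    n_plants, n_birds = community.n_plants, community.n_birds
    n_dist = len(grid)

    rows = []
    for si, s in enumerate(s_levels):
        niche = replace(niche_template, s=float(s))
        matrix = interaction_probabilities(community, niche)
        h2 = h2_prime(matrix.w)
        events = sample_dispersal_events(
            matrix, community, n_events=n_events, mode=event_mode,
            seed=_stage_seed(seed, 1, si),
        )
        distanced = sample_distances(
            events, community, kernel_params, seed=_stage_seed(seed, 2, si)
        )
        reach = reach_matrix(distanced, grid).astype(float)
        # events folded into per-(plant, bird, distance) reach counts: the
        # arrival sums for any patch are then a single contraction with RA
        counts = np.zeros((n_plants, n_birds, n_dist))
        np.add.at(counts, (events.plant_index, events.bird_index), reach)

        if trait_matching:
            a_source = general_attractiveness(source, matrix)
        else:
            a_source = attractiveness_without_matching(source, n_birds)

        for iteration in range(n_iterations):
            for richness in richness_levels:
                patch = sample_target_patch(
                    community, richness, seed=_stage_seed(seed, 3, iteration, richness)
                )
                if trait_matching:
                    a_target = general_attractiveness(patch, matrix)
                else:
                    a_target = attractiveness_without_matching(patch, n_birds)
                ra = relative_attractiveness(a_target, a_source)
                sums = np.einsum("pjd,j->pd", counts, ra)
                seeds = _floor_rule(sums)
                erd = effective_resource_diversity(patch)
                for di, distance in enumerate(grid.distances):
                    rows.append(
                        (
                            float(s),
                            h2,
                            float(distance),
                            richness,
                            iteration,
                            erd,
                            float(seeds[:, di].sum()),
                            effective_seed_diversity(seeds[:, di]),
                        )
                    )
    return pd.DataFrame(rows, columns=list(RESULT_COLUMNS))
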