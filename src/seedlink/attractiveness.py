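"""Target-patch selection by foraging frugivores.

Where a bird carries a seed depends on where it chooses to fly, and fruit
resources drive that choice.  A patch's *general attractiveness* to a bird
sums, over the plants present, the bird's interaction probability with each
plant times that plant's fruit abundance.  The *relative attractiveness* of
a target patch — the probability that the bird visits it rather than stays
at the source — is the target's share of the combined attractiveness of
target and source.  Because the source patch always holds the complete
community, relative attractiveness tops out at 0.5 (target identical to
source) and is 0 for an empty target.

A patch's resource diversity is reported as the effective number of fruit
species: the exponential of the Shannon entropy of its fruit abundances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import Community
from .network import InteractionMatrix

__all__ = [
    "Patch",
    "AttractivenessResult",
    "general_attractiveness",
    "relative_attractiveness",
    "attractiveness_without_matching",
    "effective_resource_diversity",
    "sample_target_patch",
]

logger = logging.getLogger(__name__)


@dataclass
class Patch:
    """A set of plant species (with fruit abundances) occupying a patch.

    Member abundances are the species' community-wide fruit abundances:
    each species produces a fixed number of fruits wherever it occurs, so
    varying patch membership varies both richness and total abundance.
    """

    plant_ids: list[str]
    abundances: np.ndarray
    role: str = "target"

    def __post_init__(self) -> None:
        ab = np.asarray(self.abundances, dtype=float)
        if len(self.plant_ids) != ab.size:
            raise ValueError("one abundance per member plant required")
        if len(set(self.plant_ids)) != len(self.plant_ids):
            raise ValueError("duplicate plant ids in patch")
        if ab.size and (np.any(~np.isfinite(ab)) or np.any(ab <= 0)):
            raise ValueError("member abundances must be finite and positive")
        self.abundances = ab

    @classmethod
    def from_community(cls, community: Community, role: str = "source") -> "Patch":
        """The full-community patch (the default source patch)."""
        return cls(community.plant_ids, community.plant_abundances, role=role)

    @property
    def richness(self) -> int:
        return len(self.plant_ids)

    @property
    def total_abundance(self) -> float:
        return float(self.abundances.sum()) if self.richness else 0.0


@dataclass
class AttractivenessResult:
    """Per-bird general (A) and relative (RA) attractiveness of a target patch."""

    general: np.ndarray
    relative: np.ndarray
    bird_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bird_id": self.bird_ids, "A": self.general, "RA": self.relative}
        )


def _patch_indices(patch: Patch, matrix: InteractionMatrix) -> np.ndarray:
    lookup = {pid: k for k, pid in enumerate(matrix.plant_ids)}
    try:
        return np.array([lookup[pid] for pid in patch.plant_ids], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"patch plant {exc.args[0]!r} not in the interaction matrix") from exc


def general_attractiveness(patch: Patch, matrix: InteractionMatrix) -> np.ndarray:
    """A_kj = sum over plants i in patch k of P'_ij * b_i, per bird j.

    Additive in patch membership; an empty patch attracts nobody (all
    zeros).
    """
    if patch.richness == 0:
        return np.zeros(matrix.n_birds)
    idx = _patch_indices(patch, matrix)
    return patch.abundances @ matrix.p_prime[idx, :]


def relative_attractiveness(a_target: np.ndarray, a_source: np.ndarray) -> np.ndarray:
    """Probability of visiting the target patch: A_t / (A_t + A_s) per bird.

    0.5 when the patches are equally attractive; 0 for an empty target.  A
    bird with zero attractiveness in both patches has no resources anywhere
    and cannot act as a vector: its RA is defined as 0.
    """
    a_t = np.asarray(a_target, dtype=float)
    a_s = np.asarray(a_source, dtype=float)
    if a_t.shape != a_s.shape:
        raise ValueError("attractiveness vectors must have matching shapes")
    if np.any(a_t < 0) or np.any(a_s < 0):
        raise ValueError("attractiveness must be non-negative")
    denom = a_t + a_s
    ra = np.zeros_like(a_t)
    positive = denom > 0
    ra[positive] = a_t[positive] / denom[positive]
    n_orphans = int(np.count_nonzero(~positive))
    if n_orphans:
        logger.info("%d bird(s) with zero attractiveness everywhere; RA set to 0", n_orphans)
    return ra


def attractiveness_without_matching(patch: Patch, n_birds: int) -> np.ndarray:
    """General attractiveness with trait matching removed (P' set to 1).

    Every bird then sees only total fruit abundance, so the vector is
    constant across birds — the resource-abundance-only sensitivity
    scenario.
    """
    return np.full(n_birds, patch.total_abundance)


def effective_resource_diversity(patch: Patch) -> float:
    """Effective number of fruit species: exp of the Shannon entropy of b_i.

    Equals richness for equal abundances and 1 for a monoculture; defined
    as 0 for an empty patch.
    """
    if patch.richness == 0:
        return 0.0
    q = patch.abundances / patch.abundances.sum()
    return float(np.exp(-(q * np.log(q)).sum()))


def sample_target_patch(community: Community, richness: int, seed=None) -> Patch:
    """Uniformly random target patch of the requested species richness.

    Members are drawn without replacement from the community's plants and
    keep their community fruit abundances.
    """
    if not (0 <= richness <= community.n_plants):
        raise ValueError(
            f"richness must be in [0, {community.n_plants}], got {richness}"
        )
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(community.n_plants, size=richness, replace=False))
    ids = [community.plant_ids[k] for k in idx]
    return Patch(ids, community.plant_abundances[idx], role="target")
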