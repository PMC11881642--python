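"""Synthetic plant and frugivore communities.

The simulations operate on a species pool of fleshy-fruited plants and
frugivorous birds described by the four traits that drive seed-dispersal
interactions: fruit diameter and plant height on the plant side, gape width
and wing pointedness on the bird side.  Bird body mass additionally drives
movement (gut passage time and flight speed), and fruit mass drives resource
abundance.  Species abundances decline allometrically with size, so small
fruits and small birds are the most abundant members of the community.

Trait values are drawn from log-normal distributions whose defaults emulate a
species-rich tropical forest community (50 plants, 60 birds).  Communities can
also be read from / written to plain CSV trait tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CommunityError",
    "PLANT_COLUMNS",
    "BIRD_COLUMNS",
    "TraitGenConfig",
    "Community",
    "allometric_abundance",
    "standardize_traits",
    "generate_community",
    "read_community",
    "write_community",
]


class CommunityError(ValueError):
    """Invalid community configuration or malformed trait table."""


#: required columns of a plant trait table (fruit_abundance may be absent on read)
PLANT_COLUMNS = ("id", "fruit_diameter_mm", "fruit_mass_g", "plant_height_m", "fruit_abundance")
#: required columns of a bird trait table (abundance may be absent on read)
BIRD_COLUMNS = ("id", "gape_width_mm", "wing_pointedness", "body_mass_g", "abundance")


def allometric_abundance(size_measure, coeffs):
    """Abundance of a species from its size via a declining power law.

    Parameters
    ----------
    size_measure : float or array-like
        Positive size measure (fruit mass in g for plants, body mass in g
        for birds).
    coeffs : (c, beta)
        Intercept ``c > 0`` (abundance at unit size) and exponent
        ``beta >= 0``.

    Returns
    -------
    float or ndarray
        ``ceil(c * size**-beta)``, at least 1, so abundance is a strictly
        positive count that never increases with size.
    """
    c, beta = float(coeffs[0]), float(coeffs[1])
    if c <= 0:
        raise CommunityError(f"allometric intercept must be positive, got {c}")
    if beta < 0:
        raise CommunityError(f"allometric exponent must be >= 0, got {beta}")
    size = np.asarray(size_measure, dtype=float)
    if size.size == 0 or np.any(~np.isfinite(size)) or np.any(size <= 0):
        raise CommunityError("size measure must be finite and strictly positive")
    out = np.maximum(np.ceil(c * size ** (-beta)), 1.0)
    if np.ndim(size_measure) == 0:
        return float(out)
    return out


def standardize_traits(values):
    """z-score a trait so plants and birds share a common scale.

    Used to put plant height and wing pointedness (the vertical-stratum
    matching pair) on the same dimensionless scale.  Requires at least two
    distinct values; a constant trait has no scale to standardize by.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise CommunityError("need at least two values to standardize")
    if np.any(~np.isfinite(x)):
        raise CommunityError("trait values must be finite")
    sd = x.std(ddof=0)
    if sd == 0:
        raise CommunityError("cannot standardize a constant trait")
    return (x - x.mean()) / sd


@dataclass
class TraitGenConfig:
    """Parameters of the synthetic community generator.

    Trait marginals are log-normal, parameterized by location and scale on
    the natural-log scale.  Gape width is tied to body mass through an
    allometric power law with multiplicative log-normal noise, so larger
    birds have larger gapes.  Fruit mass follows from fruit diameter through
    a spherical-fruit approximation (``mass = k * diameter^3``), keeping the
    two plant size measures consistent.  Abundances follow
    ``c * size**-beta`` on fruit mass (plants) and body mass (birds).
    """

    n_plants: int = 50
    n_birds: int = 60
    seed: int | None = None

    # plant traits
    fruit_diameter_log_mean: float = math.log(10.0)  # ln(mm)
    fruit_diameter_log_sd: float = 0.6
    plant_height_log_mean: float = math.log(8.0)  # ln(m)
    plant_height_log_sd: float = 0.6
    fruit_mass_coeff: float = 5.24e-4  # g per mm^3; sphere at pulp density ~1 g/cm^3

    # bird traits
    body_mass_log_mean: float = math.log(30.0)  # ln(g)
    body_mass_log_sd: float = 0.9
    gape_coeff: float = 4.0  # mm at 1 g body mass
    gape_exp: float = 1.0 / 3.0
    gape_log_noise_sd: float = 0.15
    wing_pointedness_log_mean: float = math.log(25.0)  # hand-wing-index-like scale
    wing_pointedness_log_sd: float = 0.35

    # allometric abundances, c * size**-beta
    plant_abundance_coeffs: tuple[float, float] = (50.0, 0.75)  # size = fruit mass (g)
    bird_abundance_coeffs: tuple[float, float] = (300.0, 0.75)  # size = body mass (g)

    def validate(self) -> None:
        if self.n_plants < 1 or self.n_birds < 1:
            raise CommunityError("n_plants and n_birds must be >= 1")
        for name in (
            "fruit_diameter_log_sd",
            "plant_height_log_sd",
            "body_mass_log_sd",
            "wing_pointedness_log_sd",
        ):
            if getattr(self, name) <= 0:
                raise CommunityError(f"{name} must be positive")
        if self.gape_log_noise_sd < 0:
            raise CommunityError("gape_log_noise_sd must be >= 0")
        if self.fruit_mass_coeff <= 0 or self.gape_coeff <= 0:
            raise CommunityError("fruit_mass_coeff and gape_coeff must be positive")
        for coeffs in (self.plant_abundance_coeffs, self.bird_abundance_coeffs):
            if coeffs[0] <= 0 or coeffs[1] < 0:
                raise CommunityError("abundance coefficients need c > 0 and beta >= 0")


def _standardized_or_zero(values: np.ndarray) -> np.ndarray:
    """z-scores, or zeros when the trait is constant / a single species.

    A degenerate guild (one species, or identical values) carries no stratum
    information; zero mismatch everywhere is the neutral choice.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2 or x.std(ddof=0) == 0:
        return np.zeros_like(x)
    return standardize_traits(x)


@dataclass
class Community:
    """A paired species pool of plants and birds.

    ``plants`` and ``birds`` are trait tables with the columns in
    :data:`PLANT_COLUMNS` / :data:`BIRD_COLUMNS`.  On construction the
    tables are validated and the stratum-matching traits (plant height,
    wing pointedness) are standardized within the community; the z-scored
    columns ``plant_height_std`` / ``wing_pointedness_std`` are derived,
    never read from file.
    """

    plants: pd.DataFrame
    birds: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        self.plants = self._validated(self.plants, PLANT_COLUMNS, "plant")
        self.birds = self._validated(self.birds, BIRD_COLUMNS, "bird")
        self.plants["plant_height_std"] = _standardized_or_zero(
            self.plants["plant_height_m"].to_numpy()
        )
        self.birds["wing_pointedness_std"] = _standardized_or_zero(
            self.birds["wing_pointedness"].to_numpy()
        )

    @staticmethod
    def _validated(table: pd.DataFrame, columns: tuple[str, ...], guild: str) -> pd.DataFrame:
        missing = [c for c in columns if c not in table.columns]
        if missing:
            raise CommunityError(f"{guild} table missing column(s): {missing}")
        table = table.loc[:, list(columns)].reset_index(drop=True).copy()
        if len(table) == 0:
            raise CommunityError(f"{guild} table is empty")
        if table["id"].duplicated().any():
            dupes = table.loc[table["id"].duplicated(), "id"].tolist()
            raise CommunityError(f"duplicate {guild} ids: {dupes}")
        numeric = [c for c in columns if c != "id"]
        try:
            table[numeric] = table[numeric].apply(pd.to_numeric, errors="raise")
        except (ValueError, TypeError) as exc:
            raise CommunityError(f"non-numeric trait value in {guild} table: {exc}") from exc
        values = table[numeric].to_numpy(dtype=float)
        if np.any(~np.isfinite(values)) or np.any(values <= 0):
            raise CommunityError(f"{guild} traits and abundances must be finite and positive")
        return table

    # -- convenience accessors -------------------------------------------------
    @property
    def n_plants(self) -> int:
        return len(self.plants)

    @property
    def n_birds(self) -> int:
        return len(self.birds)

    @property
    def plant_ids(self) -> list[str]:
        return self.plants["id"].tolist()

    @property
    def bird_ids(self) -> list[str]:
        return self.birds["id"].tolist()

    @property
    def plant_abundances(self) -> np.ndarray:
        return self.plants["fruit_abundance"].to_numpy(dtype=float)

    @property
    def bird_abundances(self) -> np.ndarray:
        return self.birds["abundance"].to_numpy(dtype=float)


def generate_community(config: TraitGenConfig) -> Community:
    """Draw a synthetic community from the generator configuration.

    Deterministic for a fixed ``config.seed``.  Fruit mass is derived from
    fruit diameter (spherical approximation) and abundances follow the
    allometric power laws, so small species dominate numerically.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    diam = rng.lognormal(config.fruit_diameter_log_mean, config.fruit_diameter_log_sd, config.n_plants)
    height = rng.lognormal(config.plant_height_log_mean, config.plant_height_log_sd, config.n_plants)
    fruit_mass = config.fruit_mass_coeff * diam**3
    plants = pd.DataFrame(
        {
            "id": [f"plant_{k + 1:03d}" for k in range(config.n_plants)],
            "fruit_diameter_mm": diam,
            "fruit_mass_g": fruit_mass,
            "plant_height_m": height,
            "fruit_abundance": allometric_abundance(fruit_mass, config.plant_abundance_coeffs),
        }
    )

    mass = rng.lognormal(config.body_mass_log_mean, config.body_mass_log_sd, config.n_birds)
    gape_noise = rng.lognormal(0.0, config.gape_log_noise_sd, config.n_birds) if config.gape_log_noise_sd > 0 else 1.0
    gape = config.gape_coeff * mass**config.gape_exp * gape_noise
    wing = rng.lognormal(config.wing_pointedness_log_mean, config.wing_pointedness_log_sd, config.n_birds)
    birds = pd.DataFrame(
        {
            "id": [f"bird_{k + 1:03d}" for k in range(config.n_birds)],
            "gape_width_mm": gape,
            "wing_pointedness": wing,
            "body_mass_g": mass,
            "abundance": allometric_abundance(mass, config.bird_abundance_coeffs),
        }
    )
    return Community(plants, birds, provenance=f"generated(seed={config.seed})")


def read_community(
    plants_csv: str | Path,
    birds_csv: str | Path,
    abundance_config: TraitGenConfig | None = None,
) -> Community:
    """Load a community from two CSV trait tables.

    The abundance columns are optional; when absent they are filled in from
    the allometric power laws of ``abundance_config`` (defaults if ``None``).
    """
    cfg = abundance_config if abundance_config is not None else TraitGenConfig()
    try:
        plants = pd.read_csv(plants_csv)
        birds = pd.read_csv(birds_csv)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise CommunityError(f"cannot read community tables: {exc}") from exc
    if "fruit_abundance" not in plants.columns:
        if "fruit_mass_g" not in plants.columns:
            raise CommunityError("plant table missing column(s): ['fruit_mass_g']")
        plants["fruit_abundance"] = allometric_abundance(
            pd.to_numeric(plants["fruit_mass_g"]).to_numpy(), cfg.plant_abundance_coeffs
        )
    if "abundance" not in birds.columns:
        if "body_mass_g" not in birds.columns:
            raise CommunityError("bird table missing column(s): ['body_mass_g']")
        birds["abundance"] = allometric_abundance(
            pd.to_numeric(birds["body_mass_g"]).to_numpy(), cfg.bird_abundance_coeffs
        )
    return Community(plants, birds, provenance=f"read({plants_csv}, {birds_csv})")


def write_community(community: Community, plants_csv: str | Path, birds_csv: str | Path) -> None:
    """Write the two trait tables as CSV (derived z-score columns excluded)."""
    community.plants.loc[:, list(PLANT_COLUMNS)].to_csv(plants_csv, index=False)
    community.birds.loc[:, list(BIRD_COLUMNS)].to_csv(birds_csv, index=False)
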