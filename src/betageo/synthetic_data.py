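"""Synthetic region chains and faunas with controllable assembly structure.

The generator emulates a long north-south peninsula of 14 mainland regions
plus 3 offshore islands (17 regions in all) holding an 88-species fauna of
two suborders: weak dispersers ("Zygoptera") and strong dispersers
("Anisoptera"). Three assembly forces can be switched on independently:

* climate filtering — each species has a thermal optimum; occupancy decays
  as a Gaussian of the mismatch with regional mean temperature (niche
  breadth in deg C);
* dispersal limitation — occupancy decays exponentially with great-circle
  distance from a source region (per-km rate, suborder-specific; water
  crossings to islands pay an extra distance multiplier);
* historical blocks — species belong to latitude blocks of regions and get
  an occupancy boost inside their block and a penalty outside, emulating
  shared history that neither current climate nor geography explains.

Presences are then independent Bernoulli draws from the resulting
probability surface. Named scenarios wire presets for calibration and
power experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data_model import (
    OccurrenceMatrix,
    RegionTable,
    ValidationError,
    geographic_distance_matrix,
)

SCENARIOS = ("climate_only", "distance_only", "historical", "null")


@dataclass
class SyntheticConfig:
    """Defaults mirror the 17-region, 88-species study system."""

    n_regions: int = 17
    n_mainland: int = 14
    n_species: int = 88
    zygoptera_fraction: float = 0.35
    # climate gradients: value = slope * lat + intercept + N(0, noise_sd)
    pmean_slope: float = 60.0       # mm per degree latitude
    pmean_intercept: float = -1700.0
    pmean_noise_sd: float = 80.0
    tmean_slope: float = -0.9       # deg C per degree latitude (elevation
                                    # reinforces latitude along the chain)
    tmean_intercept: float = 50.0
    tmean_noise_sd: float = 0.6
    seasonal_half_range: float = 8.0  # tmean +/- this -> tmax/tmin backbone
    niche_breadth: float = 2.0      # sd (deg C) of climatic tolerance
    rainfall_effect: float = 1.0    # occupancy ~ (pmean/pmean_max)^this
    dispersal_decay_zygoptera: float = 0.0030   # per km
    dispersal_decay_anisoptera: float = 0.0012  # per km
    island_distance_multiplier: float = 3.0
    source_position: str = "none"   # {north, south, none}
    historical_blocks: int = 0
    block_effect: float = 0.0       # in [0, 1]
    occupancy_max: float = 0.9
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.zygoptera_fraction <= 1:
            raise ValidationError("zygoptera_fraction must be in [0, 1]")
        if not 0 <= self.block_effect <= 1:
            raise ValidationError("block_effect must be in [0, 1]")
        if self.n_mainland > self.n_regions:
            raise ValidationError("n_mainland cannot exceed n_regions")
        if self.historical_blocks < 0:
            raise ValidationError("historical_blocks must be >= 0")
        for name in ("pmean_noise_sd", "tmean_noise_sd", "niche_breadth",
                     "rainfall_effect",
                     "dispersal_decay_zygoptera", "dispersal_decay_anisoptera"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.source_position not in ("north", "south", "none"):
            raise ValidationError("source_position must be north/south/none")


def generate_regions(config: SyntheticConfig) -> RegionTable:
    """Mainland chain down a ~9-degree latitude span plus offset islands."""
    rng = np.random.default_rng(config.seed)
    n_main = config.n_mainland
    n_isl = config.n_regions - n_main
    lat = np.linspace(46.5, 37.5, n_main)
    # gentle eastward drift with a small bow, like a real peninsula
    frac = np.linspace(0.0, 1.0, n_main)
    lon = 8.0 + 8.0 * frac + 1.5 * np.sin(np.pi * frac)
    ids = [f"R{i + 1:02d}" for i in range(config.n_regions)]
    mainland = [True] * n_main + [False] * n_isl
    # islands offset to the west/south of the chain tip
    isl_lat = np.array([37.3, 39.9, 42.1])[:n_isl] if n_isl <= 3 else (
        37.0 + rng.uniform(0, 4, n_isl))
    isl_lon = np.array([14.0, 9.0, 9.2])[:n_isl] if n_isl <= 3 else (
        8.0 + rng.uniform(0, 3, n_isl))
    lat = np.concatenate([lat, np.atleast_1d(isl_lat)])
    lon = np.concatenate([lon, np.atleast_1d(isl_lon)])

    pmean = (config.pmean_slope * lat + config.pmean_intercept
             + rng.normal(0, config.pmean_noise_sd, config.n_regions))
    pmean = np.clip(pmean, 50.0, None)
    tmean = (config.tmean_slope * lat + config.tmean_intercept
             + rng.normal(0, config.tmean_noise_sd, config.n_regions))
    half = config.seasonal_half_range
    tmin = tmean - half + rng.normal(0, 0.5, config.n_regions)
    tmax = tmean + half + rng.normal(0, 0.5, config.n_regions)
    tmin = np.minimum(tmin, tmean)
    tmax = np.maximum(tmax, tmean)
    area = np.exp(rng.normal(np.log(15000.0), 0.4, config.n_regions))
    return RegionTable(pd.DataFrame({
        "region_id": ids,
        "name": ids,
        "lat": lat, "lon": lon, "area": area,
        "pmean": pmean, "tmean": tmean, "tmin": tmin, "tmax": tmax,
        "mainland": mainland,
    }))


def _occupancy_surface(config: SyntheticConfig, regions: RegionTable,
                       rng: np.random.Generator):
    """Per-species x region occupancy probabilities plus suborder labels."""
    n_sp, n_reg = config.n_species, len(regions)
    n_zyg = int(round(config.zygoptera_fraction * n_sp))
    suborder = ["Zygoptera"] * n_zyg + ["Anisoptera"] * (n_sp - n_zyg)
    tmean = regions.data["tmean"].to_numpy()
    lat = regions.data["lat"].to_numpy()
    mainland = regions.data["mainland"].to_numpy()

    optima = rng.uniform(tmean.min() - 1.0, tmean.max() + 1.0, n_sp)
    if np.isfinite(config.niche_breadth) and config.niche_breadth > 0:
        match = np.exp(-((optima[:, None] - tmean[None, :]) ** 2)
                       / (2 * config.niche_breadth**2))
    else:
        match = np.ones((n_sp, n_reg))

    geo = geographic_distance_matrix(regions).values.copy()
    # water crossings to islands pay an isolation penalty
    water = mainland[:, None] != mainland[None, :]
    water |= (~mainland[:, None]) & (~mainland[None, :])
    water &= ~np.eye(n_reg, dtype=bool)
    geo_eff = np.where(water, geo * config.island_distance_multiplier, geo)

    if config.source_position == "north":
        source = np.full(n_sp, int(np.argmax(lat[mainland])))
    elif config.source_position == "south":
        main_idx = np.flatnonzero(mainland)
        source = np.full(n_sp, int(main_idx[np.argmin(lat[main_idx])]))
    else:
        source = rng.integers(0, n_reg, n_sp)
    decay = np.where(
        np.array(suborder) == "Zygoptera",
        config.dispersal_decay_zygoptera, config.dispersal_decay_anisoptera,
    )
    reach = np.exp(-decay[:, None] * geo_eff[source, :])

    # freshwater availability: drier regions support fewer species
    pmean = regions.data["pmean"].to_numpy()
    rain = (pmean / pmean.max()) ** config.rainfall_effect
    prob = config.occupancy_max * match * reach * rain[None, :]

    if config.historical_blocks > 0 and config.block_effect > 0:
        order = np.argsort(-lat)  # north to south
        blocks = np.array_split(order, config.historical_blocks)
        region_block = np.empty(n_reg, dtype=int)
        for b, members in enumerate(blocks):
            region_block[members] = b
        species_block = rng.integers(0, config.historical_blocks, n_sp)
        inside = species_block[:, None] == region_block[None, :]
        boosted = prob + config.block_effect * (1.0 - prob)
        penalised = prob * (1.0 - 0.5 * config.block_effect)
        prob = np.where(inside, boosted, penalised)

    return prob, suborder


def generate_fauna(config: SyntheticConfig, regions: RegionTable,
                   rng: np.random.Generator | None = None) -> OccurrenceMatrix:
    """Sample a presence/absence matrix from the occupancy surface.

    Every region and every species is guaranteed at least one incidence
    (the most probable candidate is seeded in) so downstream dissimilarity
    matrices are non-degenerate.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    prob, suborder = _occupancy_surface(config, regions, rng)
    if prob.max() < 1e-6:
        raise ValidationError(
            "occupancy probabilities are all ~0; check decay/niche settings"
        )
    inc = (rng.random(prob.shape) < prob).astype(np.int8)
    # re-seed empty regions and everywhere-absent species deterministically
    for j in np.flatnonzero(inc.sum(axis=0) == 0):
        inc[int(np.argmax(prob[:, j])), j] = 1
    for i in np.flatnonzero(inc.sum(axis=1) == 0):
        inc[i, int(np.argmax(prob[i]))] = 1
    species = [f"sp{i + 1:03d}" for i in range(config.n_species)]
    return OccurrenceMatrix(species, regions.region_ids, inc, suborder)


def area_faunas(occ: OccurrenceMatrix, regions: RegionTable,
                 rng: np.random.Generator) -> dict[str, set[str]]:
    """Four synthetic adjacent-area faunas anchored NW, N, NE and S.

    Each area's fauna is the pooled fauna of the three regions nearest its
    anchor plus a sprinkling of additional external species, so similarity
    against the regions falls off with distance from the anchor.
    """
    lat = regions.data["lat"].to_numpy()
    lon = regions.data["lon"].to_numpy()
    anchors = {
        "north_west": (lat.max() + 1.5, lon.min() - 1.5),
        "north": (lat.max() + 2.0, float(np.mean(lon))),
        "north_east": (lat.max() + 1.5, lon.max() + 1.5),
        "south": (lat.min() - 2.5, float(np.mean(lon))),
    }
    faunas: dict[str, set[str]] = {}
    for k, (alat, alon) in anchors.items():
        d = np.hypot(lat - alat, lon - alon)
        nearest = np.argsort(d)[:3]
        pool: set[str] = set()
        for j in nearest:
            pool |= occ.region_fauna(occ.region_ids[j])
        extern = {f"ext_{k}_{i}" for i in range(1 + rng.integers(0, 4))}
        faunas[k] = pool | extern
    return faunas


def scenario(name: str, seed: int | None = None,
             **overrides) -> tuple[RegionTable, OccurrenceMatrix, dict[str, set[str]]]:
    """Preset (regions, fauna, adjacent-area faunas) triples.

    climate_only   thermal filtering, no dispersal limits, no history
    distance_only  distance decay from random sources, no climate filter
    historical     climate filtering + two latitude blocks (effect 0.8)
    null           flat occupancy 0.5 everywhere (pure Bernoulli noise)
    """
    presets = {
        "climate_only": dict(niche_breadth=2.0,
                             dispersal_decay_zygoptera=0.0,
                             dispersal_decay_anisoptera=0.0),
        "distance_only": dict(niche_breadth=np.inf, rainfall_effect=0.0),
        "historical": dict(niche_breadth=2.0,
                           dispersal_decay_zygoptera=0.0,
                           dispersal_decay_anisoptera=0.0,
                           historical_blocks=2, block_effect=0.8),
        "null": dict(niche_breadth=np.inf, rainfall_effect=0.0,
                     dispersal_decay_zygoptera=0.0,
                     dispersal_decay_anisoptera=0.0,
                     occupancy_max=0.5),
    }
    if name not in presets:
        raise ValidationError(
            f"unknown scenario {name!r}; valid names: {sorted(presets)}"
        )
    config = SyntheticConfig(seed=seed, **{**presets[name], **overrides})
    rng = np.random.default_rng(seed)
    regions = generate_regions(replace(config, seed=int(rng.integers(2**31 - 1))))
    fauna = generate_fauna(config, regions,
                           np.random.default_rng(int(rng.integers(2**31 - 1))))
    areas = area_faunas(fauna, regions, rng)
    return regions, fauna, areas
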