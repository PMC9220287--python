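"""Composite inference procedures of the biogeographical pipeline.

Four analyses stitched together from the lower-level modules:

* richness gradient — per-region species richness, Moran's I spatial
  pre-test, Pearson correlation of richness with latitude over mainland
  regions, and AICc multimodel inference on area/latitude/climate;
* Mantel battery — simple and partial Mantel tests of each beta-diversity
  component against geographic and climatic distances (12 cells);
* random-split test — split the species pool in two at random, recompute the
  dissimilarity matrices per half, and test the partial correlation between
  the halves controlling geography or climate: a significant residual
  association is a historical signal that neither force explains;
* adjacency profile — Sorensen/Simpson similarity of each region to an
  external area fauna, with latitude correlations corrected for spatial
  autocorrelation (Dutilleul) whenever a Moran pre-test fires at 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import betadiv, model_selection, spatial_stats
from .data_model import (
    DistanceMatrix,
    OccurrenceMatrix,
    RegionTable,
    ValidationError,
    geographic_distance_matrix,
)

MORAN_PRETEST_ALPHA = 0.05


# ---------------------------------------------------------------------------
# richness gradient
# ---------------------------------------------------------------------------

@dataclass
class RichnessGradientResult:
    richness: pd.Series
    moran: spatial_stats.MoranResult
    latitude_r: float
    latitude_p: float
    n_mainland: int
    averaging: model_selection.AveragingResult


def richness_gradient_analysis(
    occ: OccurrenceMatrix,
    regions: RegionTable,
    subset: str = "all",
    predictors: tuple[str, ...] = ("area", "lat", "pmean", "tmean", "tmin", "tmax"),
    moran_alternative: str = "two_sided",
) -> RichnessGradientResult:
    """Richness per region, spatial pre-test, mainland latitude correlation
    and AICc model averaging of geographic/climatic predictors."""
    occ = occ.subset(subset)
    if occ.region_ids != regions.region_ids:
        raise ValidationError("occurrence and region tables disagree on regions")
    richness = occ.richness()

    weights = spatial_stats.inverse_distance_weights(
        geographic_distance_matrix(regions))
    moran = spatial_stats.morans_i(richness.to_numpy(), weights,
                                   alternative=moran_alternative)

    main = regions.data["mainland"]
    if main.sum() < 5:
        raise ValidationError("need at least 5 mainland regions")
    rich_main = richness[main[main].index].to_numpy(dtype=float)
    lat_main = regions.data.loc[main, "lat"].to_numpy()
    r = float(np.corrcoef(rich_main, lat_main)[0, 1])
    p = spatial_stats.pearson_two_sided_p(r, len(rich_main))

    x = regions.data[list(predictors)].astype(float)
    models = model_selection.all_subsets(richness.to_numpy(dtype=float), x)
    averaging = model_selection.model_average(models)
    return RichnessGradientResult(richness, moran, r, p,
                                  int(main.sum()), averaging)


# ---------------------------------------------------------------------------
# Mantel battery
# ---------------------------------------------------------------------------

def mantel_battery(
    triplet: betadiv.BetaTriplet,
    geo: DistanceMatrix,
    clim: DistanceMatrix,
    n_permutations: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simple and partial Mantel tests of each beta component vs geography
    and climate — the 12-cell table (index, comparison, controlling, r, p)."""
    rng = np.random.default_rng(seed)
    rows = []
    for index_name, beta in triplet:
        beta = beta.align(geo.labels)
        cells = [
            ("geographic", None, geo, None),
            ("climatic", None, clim, None),
            ("climatic", "geographic", clim, geo),
            ("geographic", "climatic", geo, clim),
        ]
        for comparison, controlling, b, c in cells:
            s = int(rng.integers(2**31 - 1))
            if c is None:
                res = spatial_stats.mantel_test(beta, b, n_permutations,
                                                seed=s)
            else:
                res = spatial_stats.partial_mantel_test(
                    beta, b, c, n_permutations, seed=s)
            rows.append({
                "index": index_name,
                "comparison": comparison,
                "controlling": controlling or "",
                "r": res.statistic_r,
                "p": res.p_value,
                "n_permutations": res.n_permutations,
                "partial": res.partial,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# random-split historical-signal test
# ---------------------------------------------------------------------------

@dataclass
class SplitTestResult:
    table: pd.DataFrame  # index, controlling, split, r, p
    group_sizes: list[tuple[int, int]]
    n_splits: int
    seed: int | None

    def median_r(self, index: str, controlling: str) -> float:
        sub = self.table[(self.table["index"] == index)
                         & (self.table["controlling"] == controlling)]
        return float(sub["r"].median())


def _split_species(occ: OccurrenceMatrix, rng: np.random.Generator,
                   max_retries: int = 20):
    """Random near-equal halves; redraw while a region empties out."""
    n = occ.n_species
    for attempt in range(max_retries):
        perm = rng.permutation(n)
        half1, half2 = perm[: n // 2], perm[n // 2:]
        m1 = occ.incidence[half1]
        m2 = occ.incidence[half2]
        if m1.sum(axis=0).min() > 0 and m2.sum(axis=0).min() > 0:
            return half1, half2
    warnings.warn("random split left a region empty after retries; "
                  "degenerate-pair rule will apply")
    return half1, half2


def _half_matrix(occ: OccurrenceMatrix, rows: np.ndarray) -> OccurrenceMatrix:
    return OccurrenceMatrix(
        [occ.species_ids[i] for i in rows],
        list(occ.region_ids),
        occ.incidence[rows],
        [occ.suborder[i] for i in rows],
    )


def random_split_test(
    occ: OccurrenceMatrix,
    geo: DistanceMatrix,
    clim: DistanceMatrix,
    n_permutations: int = 999,
    n_splits: int = 1,
    seed: int | None = None,
) -> SplitTestResult:
    """Partial Mantel between the dissimilarity matrices of two random
    species halves, controlling geography and climate in turn."""
    if occ.n_species < 8:
        raise ValidationError("random-split test needs at least 8 species")
    rng = np.random.default_rng(seed)
    rows, sizes = [], []
    for split in range(n_splits):
        half1, half2 = _split_species(occ, rng)
        sizes.append((len(half1), len(half2)))
        t1 = betadiv.dissimilarity_matrices(_half_matrix(occ, half1))
        t2 = betadiv.dissimilarity_matrices(_half_matrix(occ, half2))
        for (index_name, b1), (_, b2) in zip(t1, t2):
            for ctrl_name, ctrl in (("geographic", geo), ("climatic", clim)):
                s = int(rng.integers(2**31 - 1))
                try:
                    res = spatial_stats.partial_mantel_test(
                        b1.align(ctrl.labels), b2.align(ctrl.labels), ctrl,
                        n_permutations, seed=s)
                    r, p = res.statistic_r, res.p_value
                except ValidationError as err:
                    warnings.warn(f"{index_name} | {ctrl_name}: {err}")
                    r, p = np.nan, np.nan
                rows.append({"index": index_name, "controlling": ctrl_name,
                             "split": split, "r": r, "p": p})
    return SplitTestResult(pd.DataFrame(rows), sizes, n_splits, seed)


# ---------------------------------------------------------------------------
# adjacency profiles
# ---------------------------------------------------------------------------

@dataclass
class AdjacencyResult:
    similarities: pd.DataFrame   # region_id, area, sorensen, simpson
    correlations: pd.DataFrame   # area, index, r, classical_p, moran_p,
                                 # corrected, effective_n, p


def adjacency_profile(
    occ: OccurrenceMatrix,
    area_faunas: dict[str, set],
    regions: RegionTable,
    subset: str = "all",
) -> AdjacencyResult:
    """Similarity of every region to each external area, and the latitude
    trend of each similarity profile with a spatial-autocorrelation-aware
    p-value (Dutilleul correction when Moran's I pre-test fires)."""
    if len(area_faunas) < 2:
        raise ValidationError("need at least 2 external areas")
    weights = spatial_stats.inverse_distance_weights(
        geographic_distance_matrix(regions))
    lat = regions.data["lat"].to_numpy()
    coords = regions.data[["lat", "lon"]].to_numpy()

    sims = []
    rows = []
    for area, fauna in area_faunas.items():
        prof = betadiv.similarity_to_area(occ, fauna, subset, area_label=area)
        sims.append(prof)
        for index_name in ("sorensen", "simpson"):
            v = prof[index_name].to_numpy(dtype=float)
            moran_p = np.nan
            if np.ptp(v) > 0:
                moran_p = spatial_stats.morans_i(v, weights).p_value
            flagged = bool(moran_p < MORAN_PRETEST_ALPHA) if np.isfinite(moran_p) else False
            res = spatial_stats.modified_ttest(v, lat, coords)
            p = res.corrected_p if (flagged and res.corrected) else res.classical_p
            rows.append({
                "area": area, "index": index_name,
                "r": res.pearson_r, "classical_p": res.classical_p,
                "moran_p": moran_p, "corrected": flagged and res.corrected,
                "effective_n": res.effective_sample_size if flagged else len(v),
                "p": p,
            })
    return AdjacencyResult(pd.concat(sims, ignore_index=True),
                           pd.DataFrame(rows))
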