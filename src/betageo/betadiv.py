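"""Pairwise beta-diversity partitioning on presence/absence data.

Total dissimilarity between two regional faunas (beta_sor, the complement of
the Sorensen similarity) is split into a pure spatial-turnover component
(beta_sim, the complement of the Simpson similarity, insensitive to richness
differences) and a nestedness-resultant component (beta_nest = beta_sor -
beta_sim), which captures dissimilarity caused by ordered species loss.

With a = number of shared species and b, c = species exclusive to either
fauna:

    beta_sor  = (b + c) / (2a + b + c)
    beta_sim  = min(b, c) / (a + min(b, c))
    beta_nest = beta_sor - beta_sim

Region-to-area similarity profiles use the similarity forms 2a/(2a+b+c)
(Sorensen) and a/(a+min(b,c)) (Simpson).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import DistanceMatrix, OccurrenceMatrix, ValidationError


def pairwise_components(fauna_a: set, fauna_b: set) -> tuple[int, int, int]:
    """(shared, only-in-A, only-in-B) species counts for two faunas."""
    fauna_a, fauna_b = set(fauna_a), set(fauna_b)
    a = len(fauna_a & fauna_b)
    return a, len(fauna_a) - a, len(fauna_b) - a


def _partition(a, b, c):
    """Vectorised beta_sor/beta_sim/beta_nest with the degenerate-pair rule:
    two empty faunas -> all zero; exactly one empty -> (1, 0, 1)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    m = np.minimum(b, c)
    with np.errstate(divide="ignore", invalid="ignore"):
        sor = np.where(2 * a + b + c > 0, (b + c) / (2 * a + b + c), 0.0)
        sim = np.where(a + m > 0, m / (a + m), 0.0)
    one_empty = ((a + b == 0) ^ (a + c == 0))
    sor = np.where(one_empty, 1.0, sor)
    sim = np.where(one_empty, 0.0, sim)
    return sor, sim, sor - sim


def pairwise_dissimilarity(fauna_a: set, fauna_b: set) -> tuple[float, float, float]:
    """(beta_sor, beta_sim, beta_nest) for a single fauna pair."""
    a, b, c = pairwise_components(fauna_a, fauna_b)
    sor, sim, nest = _partition(a, b, c)
    return float(sor), float(sim), float(nest)


@dataclass
class BetaTriplet:
    """The three region x region dissimilarity matrices of one fauna subset."""

    beta_sor: DistanceMatrix
    beta_sim: DistanceMatrix
    beta_nest: DistanceMatrix
    subset_label: str = "all"

    def __post_init__(self) -> None:
        s = self.beta_sor.values
        t = self.beta_sim.values
        n = self.beta_nest.values
        if not np.allclose(s, t + n, atol=1e-12):
            raise ValidationError("beta_sor != beta_sim + beta_nest")
        if (t - s > 1e-12).any() or (s > 1 + 1e-12).any():
            raise ValidationError("need 0 <= beta_sim <= beta_sor <= 1")

    @property
    def labels(self) -> list[str]:
        return self.beta_sor.labels

    def __iter__(self):
        yield "beta_sor", self.beta_sor
        yield "beta_sim", self.beta_sim
        yield "beta_nest", self.beta_nest


def dissimilarity_matrices(occ: OccurrenceMatrix, subset: str = "all") -> BetaTriplet:
    """Pairwise beta_sor/beta_sim/beta_nest matrices for a suborder subset."""
    occ = occ.subset(subset)
    x = occ.incidence.astype(float)
    richness = x.sum(axis=0)
    if (richness == 0).any():
        empty = [r for r, k in zip(occ.region_ids, richness) if k == 0]
        warnings.warn(
            f"regions with no species after subsetting {subset!r}: {empty}; "
            "degenerate-pair rule applied"
        )
    a = x.T @ x  # shared species per region pair
    b = richness[:, None] - a
    c = richness[None, :] - a
    sor, sim, nest = _partition(a, b, c)
    for m in (sor, sim, nest):
        np.fill_diagonal(m, 0.0)
    lab = occ.region_ids
    return BetaTriplet(
        DistanceMatrix(lab, sor), DistanceMatrix(lab, sim),
        DistanceMatrix(lab, nest), subset_label=subset,
    )


def similarity_to_area(
    occ: OccurrenceMatrix, area_fauna: set, subset: str = "all",
    area_label: str = "area",
) -> pd.DataFrame:
    """Sorensen and Simpson similarity of every region to an external fauna.

    Species in ``area_fauna`` that are absent from the occurrence matrix
    still count as exclusive to the area.
    """
    if not area_fauna:
        raise ValidationError("area fauna is empty")
    occ = occ.subset(subset)
    rows = []
    for region in occ.region_ids:
        fauna = occ.region_fauna(region)
        a, b, c = pairwise_components(fauna, set(area_fauna))
        sor = 2 * a / (2 * a + b + c) if 2 * a + b + c > 0 else 0.0
        sim = a / (a + min(b, c)) if a + min(b, c) > 0 else 0.0
        rows.append((region, area_label, sor, sim))
    return pd.DataFrame(rows, columns=["region_id", "area", "sorensen", "simpson"])
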