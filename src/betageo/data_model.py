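"""Domain containers and distance-matrix construction.

The package works on three in-memory objects: a binary species x region
occurrence matrix (with a suborder label per species), a per-region metadata
table (centroid, area, climate), and labelled square distance matrices.
Geographic distances are great-circle distances between region centroids;
climatic distances are Euclidean distances on z-scored climate variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: IUGG mean Earth radius, km.
EARTH_RADIUS_KM = 6371.0088

#: Climate columns of a RegionTable usable for climatic distances / models.
CLIMATE_VARIABLES = ("pmean", "tmean", "tmin", "tmax", "delta_t")

SUBORDERS = ("Zygoptera", "Anisoptera")


class ValidationError(ValueError):
    """Raised when an input file or container violates its contract."""


@dataclass
class OccurrenceMatrix:
    """Binary species x region incidence with a suborder label per species.

    Parameters
    ----------
    species_ids : list of str
        Unique species labels, one per matrix row.
    region_ids : list of str
        Unique region labels, one per matrix column.
    incidence : ndarray of shape (n_species, n_regions)
        0/1 presence matrix.
    suborder : list of str
        Per-species label, typically ``Zygoptera``/``Anisoptera`` (anything
        else is tolerated and grouped as "other" by suborder subsetting).
    """

    species_ids: list[str]
    region_ids: list[str]
    incidence: np.ndarray
    suborder: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.incidence = np.asarray(self.incidence)
        if not self.suborder:
            self.suborder = ["other"] * len(self.species_ids)
        self.validate()

    # -- contract ---------------------------------------------------------
    def validate(self) -> None:
        n_sp, n_reg = self.incidence.shape
        if n_sp != len(self.species_ids) or n_reg != len(self.region_ids):
            raise ValidationError("incidence shape does not match labels")
        if len(set(self.species_ids)) != n_sp:
            raise ValidationError("duplicate species ids")
        if len(set(self.region_ids)) != n_reg:
            raise ValidationError("duplicate region ids")
        if n_sp < 2 or n_reg < 2:
            raise ValidationError("need at least 2 species and 2 regions")
        if len(self.suborder) != n_sp:
            raise ValidationError("suborder labels must match species count")
        bad = ~np.isin(self.incidence, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-binary cell at species {self.species_ids[i]!r}, "
                f"region {self.region_ids[j]!r}: {self.incidence[i, j]!r}"
            )
        self.incidence = self.incidence.astype(np.int8)

    # -- views ------------------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def richness(self) -> pd.Series:
        """Species count per region, in region order."""
        return pd.Series(self.incidence.sum(axis=0), index=self.region_ids)

    def subset(self, suborder: str) -> "OccurrenceMatrix":
        """Rows of one suborder ('all' returns self); region order kept."""
        if suborder == "all":
            return self
        mask = np.array([s == suborder for s in self.suborder])
        if mask.sum() < 2:
            raise ValidationError(f"fewer than 2 species labelled {suborder!r}")
        return OccurrenceMatrix(
            [s for s, m in zip(self.species_ids, mask) if m],
            list(self.region_ids),
            self.incidence[mask],
            [s for s, m in zip(self.suborder, mask) if m],
        )

    def region_fauna(self, region_id: str) -> set[str]:
        j = self.region_ids.index(region_id)
        return {s for s, v in zip(self.species_ids, self.incidence[:, j]) if v}

    # -- I/O ---------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.incidence, columns=self.region_ids)
        df.insert(0, "suborder", self.suborder)
        df.insert(0, "species_id", self.species_ids)
        return df

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_occurrence_matrix(path) -> OccurrenceMatrix:
    """Read a `species_id,suborder,<region>...` CSV of 0/1 cells."""
    df = pd.read_csv(path, dtype={0: str, 1: str})
    if df.shape[1] < 4 or df.columns[0] != "species_id":
        raise ValidationError(
            "expected columns species_id,suborder,<region_1>,...,<region_R>"
        )
    regions = list(df.columns[2:])
    values = df.iloc[:, 2:].to_numpy()
    if not np.isin(values, (0, 1)).all():
        i, j = np.argwhere(~np.isin(values, (0, 1)))[0]
        raise ValidationError(
            f"non-binary cell at species {df.iloc[i, 0]!r}, "
            f"region {regions[j]!r}: {values[i, j]!r}"
        )
    return OccurrenceMatrix(
        df["species_id"].tolist(), regions, values, df["suborder"].tolist()
    )


REGION_COLUMNS = [
    "region_id", "name", "lat", "lon", "area_km2",
    "pmean_mm", "tmean_c", "tmin_c", "tmax_c", "mainland",
]

_CSV_TO_FIELD = {
    "area_km2": "area", "pmean_mm": "pmean", "tmean_c": "tmean",
    "tmin_c": "tmin", "tmax_c": "tmax",
}


@dataclass
class RegionTable:
    """Per-region centroid, area, climate and mainland flag.

    Stored as a DataFrame indexed by ``region_id`` with columns
    ``name, lat, lon, area, pmean, tmean, tmin, tmax, delta_t, mainland``.
    ``delta_t`` is always recomputed as ``tmax - tmin``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.name != "region_id":
            if "region_id" in df.columns:
                df = df.set_index("region_id")
            else:
                raise ValidationError("region table needs a region_id column")
        if df.index.duplicated().any():
            raise ValidationError("duplicate region ids")
        if len(df) < 2:
            raise ValidationError("need at least 2 regions")
        for col in ("lat", "lon", "area", "pmean", "tmean", "tmin", "tmax"):
            if col not in df.columns:
                raise ValidationError(f"region table missing column {col!r}")
            if df[col].isna().any():
                bad = df.index[df[col].isna()][0]
                raise ValidationError(f"missing {col!r} for region {bad!r}")
        if ((df["lat"] < -90) | (df["lat"] > 90)).any():
            raise ValidationError("latitude outside [-90, 90]")
        if ((df["lon"] < -180) | (df["lon"] > 180)).any():
            raise ValidationError("longitude outside [-180, 180]")
        if (df["area"] <= 0).any():
            raise ValidationError("area must be positive")
        if ((df["tmin"] > df["tmean"]) | (df["tmean"] > df["tmax"])).any():
            raise ValidationError("need tmin <= tmean <= tmax")
        df = df.copy()
        df["delta_t"] = df["tmax"] - df["tmin"]
        if "mainland" not in df.columns:
            df["mainland"] = True
        df["mainland"] = df["mainland"].astype(bool)
        self.data = df

    @property
    def region_ids(self) -> list[str]:
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)

    def mainland(self) -> "RegionTable":
        return RegionTable(self.data[self.data["mainland"]].copy())

    def write_csv(self, path) -> None:
        out = self.data.reset_index()[
            ["region_id", "name", "lat", "lon", "area", "pmean",
             "tmean", "tmin", "tmax", "mainland"]
        ]
        out.columns = REGION_COLUMNS
        out.to_csv(path, index=False)


def read_region_table(path) -> RegionTable:
    """Read the `region_id,name,lat,lon,area_km2,...` region CSV."""
    df = pd.read_csv(path)
    missing = set(REGION_COLUMNS) - {"name"} - set(df.columns)
    if missing:
        raise ValidationError(f"region CSV missing columns {sorted(missing)}")
    df = df.rename(columns=_CSV_TO_FIELD)
    if "name" not in df.columns:
        df["name"] = df["region_id"]
    return RegionTable(df)


@dataclass
class DistanceMatrix:
    """Labelled square symmetric distance matrix."""

    labels: list[str]
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValidationError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-10):
            raise ValidationError("distance matrix diagonal not zero")
        if (self.values < -1e-12).any():
            raise ValidationError("negative distances")
        self.values = np.clip((self.values + self.values.T) / 2.0, 0.0, None)

    @property
    def n(self) -> int:
        return len(self.labels)

    def align(self, labels: list[str]) -> "DistanceMatrix":
        """Reindex to the given label order (must be a permutation)."""
        if set(labels) != set(self.labels) or len(labels) != len(self.labels):
            raise ValidationError("label sets differ; cannot align")
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)],
                              self.units)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries as a flat vector (row-major)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def write_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.labels,
                     columns=self.labels).to_csv(path)


def read_distance_matrix(path, units: str = "") -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValidationError("row and column labels differ")
    return DistanceMatrix([str(l) for l in df.index], df.to_numpy(), units)


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km on a sphere of IUGG mean radius."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def geographic_distance_matrix(regions: RegionTable) -> DistanceMatrix:
    """Pairwise great-circle distances between region centroids (km)."""
    lat = regions.data["lat"].to_numpy()
    lon = regions.data["lon"].to_numpy()
    d = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(regions.region_ids, d, units="km")


def climate_distance_matrix(
    regions: RegionTable,
    variables: list[str] | tuple[str, ...] = ("pmean", "tmean", "tmin", "tmax"),
) -> DistanceMatrix:
    """Euclidean distance on z-scored (ddof=1) climate variables.

    ``delta_t`` is dropped with a warning when requested alongside both
    ``tmin`` and ``tmax`` (it is their exact difference).
    """
    variables = list(variables)
    if "delta_t" in variables and {"tmin", "tmax"} <= set(variables):
        import warnings

        warnings.warn("delta_t dropped: exactly collinear with tmin and tmax")
        variables = [v for v in variables if v != "delta_t"]
    cols = []
    for v in variables:
        if v not in regions.data.columns:
            raise ValidationError(f"unknown climate variable {v!r}")
        x = regions.data[v].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValidationError(f"variable {v!r} is constant across regions")
        cols.append((x - x.mean()) / sd)
    z = np.column_stack(cols)
    from scipy.spatial.distance import squareform, pdist

    d = squareform(pdist(z, metric="euclidean"))
    return DistanceMatrix(regions.region_ids, d)
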