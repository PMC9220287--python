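"""Non-metric multidimensional scaling with restart convergence and
four-corner RGB colouring of the resulting map.

The NMDS engine is SMACOF with isotonic (monotone) regression of the
configuration distances on the dissimilarity ranks, run from many random
starts. Restarts stop early once a new solution both matches the best
stress within ``tol`` and sits within ``tol`` symmetric Procrustes distance
of the best configuration, i.e. the optimiser keeps finding the same
minimum. Reported stress is Kruskal's stress-1

    stress1 = sqrt( sum (d_ij - dhat_ij)^2 / sum d_ij^2 )

with d the configuration distances and dhat the monotone disparities
(primary tie treatment: tied dissimilarities are ordered by configuration
distance before the monotone fit, which lets ties break in stress's favour).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import procrustes as _scipy_procrustes
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import MDS

from .data_model import DistanceMatrix, ValidationError

__all__ = [
    "NMDSResult", "RGBMap", "nmds", "stress1",
    "procrustes_distance", "assign_rgb",
]

#: Corner colours of the RGB map, package convention (recorded in output):
#: origin (0,0) blue, (0,ymax) green, (1,0) yellow, (1,ymax) red.
CORNER_COLORS = {
    "origin": (0, 0, 255),
    "top_left": (0, 255, 0),
    "bottom_right": (255, 255, 0),
    "top_right": (255, 0, 0),
}


@dataclass
class NMDSResult:
    coordinates: np.ndarray
    labels: list[str]
    stress: float
    n_restarts_used: int
    converged: bool
    seed: int | None


@dataclass
class RGBMap:
    labels: list[str]
    scaled_coordinates: np.ndarray
    colors: np.ndarray  # (n, 3) uint8
    corner_assignment: dict


def stress1(coords: np.ndarray, dissim: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against a dissimilarity matrix."""
    iu = np.triu_indices(len(dissim), k=1)
    delta = dissim[iu]
    d = squareform(pdist(coords))[iu]
    # primary tie treatment: within tied delta, order by d
    order = np.lexsort((d, delta))
    dhat = IsotonicRegression().fit_transform(np.arange(len(d)), d[order])
    resid = ((d[order] - dhat) ** 2).sum()
    denom = (d**2).sum()
    if denom == 0:
        raise ValidationError("degenerate configuration (all points identical)")
    return float(np.sqrt(resid / denom))


def procrustes_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Symmetric Procrustes root-sum-of-squares after optimal translation,
    scaling and rotation/reflection of both configurations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("configurations must have the same shape")
    if np.allclose(x - x.mean(axis=0), 0) or np.allclose(y - y.mean(axis=0), 0):
        raise ValidationError("degenerate configuration (all points identical)")
    _, _, disparity = _scipy_procrustes(x, y)
    return float(np.sqrt(disparity))


def nmds(
    d: DistanceMatrix,
    n_dim: int = 2,
    n_restarts: int = 50,
    max_iter: int = 300,
    tol: float = 1e-3,
    seed: int | None = None,
) -> NMDSResult:
    """Restart NMDS keeping the lowest-stress solution.

    Convergence is declared when a later restart lands within ``tol`` of the
    best stress AND within ``tol`` Procrustes distance of the best
    configuration; otherwise all ``n_restarts`` are used and the best is
    returned with ``converged=False``.
    """
    values = d.values.copy()
    n = d.n
    if n < 4:
        raise ValidationError("NMDS needs at least 4 objects")
    iu = np.triu_indices(n, k=1)
    if np.ptp(values[iu]) == 0:
        raise ValidationError("all off-diagonal distances equal; NMDS undefined")
    zero = (values[iu] == 0).sum()
    if zero:
        warnings.warn(f"{zero} zero dissimilarities between distinct objects "
                      "perturbed by 1e-9 before rank transformation")
        values[iu] += np.where(values[iu] == 0, 1e-9, 0.0)
        values.T[iu] = values[iu]

    rng = np.random.default_rng(seed)
    best_coords, best_stress = None, np.inf
    converged = False
    used = 0
    for used in range(1, n_restarts + 1):
        engine = MDS(
            n_components=n_dim, metric="precomputed", metric_mds=False,
            init="random", n_init=1, max_iter=max_iter, eps=1e-9,
            random_state=int(rng.integers(2**31 - 1)),
            normalized_stress=True,
        )
        coords = engine.fit_transform(values)
        s = stress1(coords, values)
        if s < best_stress - 1e-15:
            if (
                best_coords is not None
                and abs(s - best_stress) <= tol
                and procrustes_distance(coords, best_coords) <= tol
            ):
                best_coords, best_stress = coords, s
                converged = True
                break
            best_coords, best_stress = coords, s
        elif (
            best_coords is not None
            and abs(s - best_stress) <= tol
            and procrustes_distance(coords, best_coords) <= tol
        ):
            converged = True
            break
    coords = best_coords - best_coords.mean(axis=0)
    return NMDSResult(coords, list(d.labels), float(best_stress),
                      used, converged, seed)


def assign_rgb(coords: np.ndarray, labels: list[str] | None = None) -> RGBMap:
    """Min-max scale the dominant axis to [0,1] (second axis shares the same
    scale factor) and colour each point by bilinear interpolation between the
    four corner colours of the bounding box."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 2 or coords.shape[1] != 2:
        raise ValidationError("need a regions x 2 coordinate matrix")
    if labels is None:
        labels = [str(i) for i in range(len(coords))]
    var = coords.var(axis=0)
    if np.all(var == 0):
        raise ValidationError("zero variance on both axes")
    major = int(np.argmax(var))
    x = coords[:, major]
    y = coords[:, 1 - major]
    span = np.ptp(x)
    u = (x - x.min()) / span
    v = (y - y.min()) / span
    ymax = v.max()
    t = v / ymax if ymax > 0 else np.zeros_like(v)

    blue = np.array(CORNER_COLORS["origin"], dtype=float)
    green = np.array(CORNER_COLORS["top_left"], dtype=float)
    yellow = np.array(CORNER_COLORS["bottom_right"], dtype=float)
    red = np.array(CORNER_COLORS["top_right"], dtype=float)
    rgb = (
        np.outer((1 - u) * (1 - t), blue)
        + np.outer((1 - u) * t, green)
        + np.outer(u * (1 - t), yellow)
        + np.outer(u * t, red)
    )
    colors = np.rint(rgb).astype(np.uint8)
    assignment = {
        "major_axis": major,
        "ymax": float(ymax),
        "corners": {k: list(v) for k, v in CORNER_COLORS.items()},
    }
    return RGBMap(list(labels), np.column_stack([u, v]), colors, assignment)
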