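"""Spatially aware correlation statistics and permutation tests.

Three tools used throughout the pipeline:

* Moran's I under the randomization null (permutation-moment normal
  approximation), with inverse-distance weights as the package default;
* Mantel and partial Mantel tests between labelled distance matrices, with
  joint row/column permutations and the add-one p-value estimator;
* Dutilleul's modified t-test for the Pearson correlation of two spatially
  autocorrelated variables, which replaces the sample size by an effective
  sample size estimated from distance-class autocovariances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model import DistanceMatrix, ValidationError, haversine_km

__all__ = [
    "MoranResult", "MantelResult", "CorrelationResult",
    "morans_i", "inverse_distance_weights",
    "mantel_test", "partial_mantel_test", "modified_ttest",
]


# ---------------------------------------------------------------------------
# Moran's I
# ---------------------------------------------------------------------------

@dataclass
class MoranResult:
    observed_i: float
    expected_i: float
    sd_i: float
    p_value: float
    alternative: str


def inverse_distance_weights(distances: DistanceMatrix) -> np.ndarray:
    """1/d weights with zero diagonal (conventional distance-based Moran)."""
    d = distances.values.copy()
    np.fill_diagonal(d, np.inf)
    if (d <= 0).any():
        raise ValidationError("zero off-diagonal distance; cannot invert")
    return 1.0 / d


def morans_i(
    values, weights, alternative: str = "two_sided"
) -> MoranResult:
    """Moran's I with moments under the randomization null.

    I = (n/W) * sum_ij w_ij z_i z_j / sum_i z_i^2 with z centred values,
    W the sum of weights and zero self-weights. The p-value uses the
    normal approximation with the classical randomization variance.
    """
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    n = len(x)
    if n < 3:
        raise ValidationError("Moran's I needs at least 3 observations")
    if w.shape != (n, n):
        raise ValidationError("weights shape does not match values")
    if (w < 0).any():
        raise ValidationError("negative weights")
    if np.diag(w).any():
        raise ValidationError("weights must have a zero diagonal")
    z = x - x.mean()
    s2 = (z**2).sum()
    if s2 == 0:
        raise ValidationError("values are constant; Moran's I undefined")
    big_w = w.sum()
    if big_w <= 0:
        raise ValidationError("weight sum must be positive")
    observed = (n / big_w) * (z @ w @ z) / s2
    expected = -1.0 / (n - 1)

    s1 = 0.5 * ((w + w.T) ** 2).sum()
    s2s = ((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum()
    b2 = n * (z**4).sum() / s2**2
    num = (
        n * ((n**2 - 3 * n + 3) * s1 - n * s2s + 3 * big_w**2)
        - b2 * ((n**2 - n) * s1 - 2 * n * s2s + 6 * big_w**2)
    )
    den = (n - 1) * (n - 2) * (n - 3) * big_w**2
    sd = float(np.sqrt(max(num / den - expected**2, 0.0))) if n > 3 else np.nan

    if np.isnan(sd) or sd == 0:
        p = np.nan
    else:
        zscore = (observed - expected) / sd
        if alternative == "greater":
            p = stats.norm.sf(zscore)
        elif alternative == "less":
            p = stats.norm.cdf(zscore)
        elif alternative == "two_sided":
            p = 2 * stats.norm.sf(abs(zscore))
        else:
            raise ValidationError(f"unknown alternative {alternative!r}")
    return MoranResult(float(observed), float(expected), sd, float(p), alternative)


# ---------------------------------------------------------------------------
# Mantel machinery
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    statistic_r: float
    p_value: float
    n_permutations: int
    tail: str
    partial: bool
    seed: int | None


def _aligned_vectors(*mats: DistanceMatrix) -> list[np.ndarray]:
    labels = mats[0].labels
    out = []
    for m in mats:
        if m.labels != labels:
            if set(m.labels) != set(labels):
                raise ValidationError("distance matrices have different labels")
            m = m.align(labels)
        out.append(m)
    return out


def _check_not_constant(vec: np.ndarray, name: str) -> None:
    if np.ptp(vec) == 0:
        raise ValidationError(f"off-diagonal entries of {name} are constant")


def _corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation of vector a with each row of 2-D (or 1-D) b."""
    a = (a - a.mean()) / a.std()
    b = np.atleast_2d(b)
    bc = b - b.mean(axis=1, keepdims=True)
    sd = bc.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (bc @ a) / (len(a) * sd)
    return r


def _permuted_rows(values: np.ndarray, perms: np.ndarray,
                   iu: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """Upper-triangle vectors of values under each joint row/col permutation."""
    i, j = iu
    return values[perms[:, i], perms[:, j]]


def _pvalue(obs: float, perm_stats: np.ndarray, tail: str) -> float:
    if tail == "greater":
        k = int((perm_stats >= obs - 1e-12).sum())
    elif tail == "less":
        k = int((perm_stats <= obs + 1e-12).sum())
    elif tail == "two_sided":
        k = int((np.abs(perm_stats) >= abs(obs) - 1e-12).sum())
    else:
        raise ValidationError(f"unknown tail {tail!r}")
    return (1 + k) / (1 + len(perm_stats))


def mantel_test(
    a: DistanceMatrix, b: DistanceMatrix,
    n_permutations: int = 999, tail: str = "greater",
    seed: int | None = None,
) -> MantelResult:
    """Mantel test: Pearson r over upper triangles, permuting B's objects."""
    a, b = _aligned_vectors(a, b)
    n = a.n
    if n < 4:
        raise ValidationError("Mantel test needs at least 4 objects")
    iu = np.triu_indices(n, k=1)
    va, vb = a.values[iu], b.values[iu]
    _check_not_constant(va, "matrix A")
    _check_not_constant(vb, "matrix B")
    r_obs = float(_corr(va, vb)[0])

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_permutations)])
    perm_vecs = _permuted_rows(b.values, perms, iu)
    r_perm = _corr(va, perm_vecs)
    p = _pvalue(r_obs, r_perm, tail)
    return MantelResult(r_obs, p, n_permutations, tail, False, seed)


def partial_correlation(r_ab: float, r_ac: float, r_bc: float) -> float:
    """First-order partial correlation r_AB.C."""
    den = (1 - r_ac**2) * (1 - r_bc**2)
    if den <= 0:
        raise ValidationError("degenerate control: |r_AC| or |r_BC| is 1")
    return (r_ab - r_ac * r_bc) / np.sqrt(den)


def partial_mantel_test(
    a: DistanceMatrix, b: DistanceMatrix, c: DistanceMatrix,
    n_permutations: int = 999, tail: str = "greater",
    seed: int | None = None,
) -> MantelResult:
    """Partial Mantel test of A vs B controlling C.

    The objects of A are permuted and the full partial statistic
    r_AB.C is recomputed for every draw.
    """
    a, b, c = _aligned_vectors(a, b, c)
    n = a.n
    if n < 4:
        raise ValidationError("partial Mantel test needs at least 4 objects")
    iu = np.triu_indices(n, k=1)
    va, vb, vc = a.values[iu], b.values[iu], c.values[iu]
    for v, name in ((va, "matrix A"), (vb, "matrix B"), (vc, "matrix C")):
        _check_not_constant(v, name)
    if np.array_equal(vb, vc):
        # controlling B for itself leaves nothing to test: the partial
        # correlation collapses to 0 identically
        return MantelResult(0.0, 1.0, n_permutations, tail, True, seed)
    r_bc = float(_corr(vb, vc)[0])
    r_obs = float(
        partial_correlation(float(_corr(va, vb)[0]), float(_corr(va, vc)[0]), r_bc)
    )

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_permutations)])
    perm_vecs = _permuted_rows(a.values, perms, iu)
    r_ab = _corr(vb, perm_vecs)
    r_ac = _corr(vc, perm_vecs)
    with np.errstate(invalid="ignore", divide="ignore"):
        r_perm = (r_ab - r_ac * r_bc) / np.sqrt((1 - r_ac**2) * (1 - r_bc**2))
    p = _pvalue(r_obs, r_perm, tail)
    return MantelResult(r_obs, p, n_permutations, tail, True, seed)


# ---------------------------------------------------------------------------
# Dutilleul's modified t-test
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    pearson_r: float
    classical_p: float
    effective_sample_size: float
    corrected_p: float
    corrected: bool


def pearson_two_sided_p(r: float, n: float) -> float:
    """Two-sided p for Pearson r via t = r*sqrt(n-2)/sqrt(1-r^2)."""
    if n <= 2:
        return 1.0
    t = r * np.sqrt((n - 2) / max(1 - r**2, 1e-300))
    return float(2 * stats.t.sf(abs(t), n - 2))


def _class_covariance(z: np.ndarray, class_masks: list[np.ndarray]) -> np.ndarray:
    """Autocovariance matrix from distance-class averages of cross-products."""
    n = len(z)
    cp = np.outer(z, z)
    sigma = np.empty((n, n))
    np.fill_diagonal(sigma, (z**2).mean())
    for mask in class_masks:
        if mask.any():
            sigma[mask] = cp[mask].mean()
    return (sigma + sigma.T) / 2


def modified_ttest(
    x, y, coords, n_classes: int | None = None
) -> CorrelationResult:
    """Pearson correlation with Dutilleul's effective-sample-size correction.

    Autocovariances of x and y are estimated per great-circle distance class
    (equal-width bins, Sturges' rule on the pair count by default); the
    effective sample size is

        M = 1 + tr(B Sx B) tr(B Sy B) / tr(B Sx B Sy)

    with B the centring matrix, and the corrected p comes from
    F = (M - 2) r^2 / (1 - r^2) on F(1, M - 2). With fewer than two
    non-empty distance classes the classical test is returned unchanged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n = len(x)
    if n < 5:
        raise ValidationError("modified t-test needs at least 5 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("constant variable; correlation undefined")

    r = float(np.corrcoef(x, y)[0, 1])
    classical_p = pearson_two_sided_p(r, n)

    lat, lon = coords[:, 0], coords[:, 1]
    d = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    iu = np.triu_indices(n, k=1)
    pair_d = d[iu]
    m = len(pair_d)
    if n_classes is None:
        n_classes = int(np.ceil(np.log2(m) + 1))
    edges = np.linspace(pair_d.min(), pair_d.max(), n_classes + 1)
    cls = np.clip(np.digitize(d, edges[1:-1]), 0, n_classes - 1)
    off = ~np.eye(n, dtype=bool)
    masks = []
    for k in range(n_classes):
        mask = (cls == k) & off
        if mask.any():
            masks.append(mask)
    if len(masks) < 2:
        return CorrelationResult(r, classical_p, float(n), classical_p, False)

    zx = x - x.mean()
    zy = y - y.mean()
    sx = _class_covariance(zx, masks)
    sy = _class_covariance(zy, masks)
    b = np.eye(n) - np.ones((n, n)) / n
    bx = b @ sx @ b
    by = b @ sy @ b
    denom = np.trace(bx @ sy)
    if denom <= 0:
        return CorrelationResult(r, classical_p, float(n), classical_p, False)
    ess = 1.0 + np.trace(bx) * np.trace(by) / denom
    ess = float(min(max(ess, 2.0 + 1e-9), n))

    f = (ess - 2) * r**2 / max(1 - r**2, 1e-300)
    corrected_p = float(stats.f.sf(f, 1, ess - 2))
    return CorrelationResult(r, classical_p, ess, corrected_p, True)
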