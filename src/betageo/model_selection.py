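"""All-subsets OLS with AICc ranking and full-model averaging.

Every admissible predictor subset (including the intercept-only model) is
fit by ordinary least squares and ranked by the small-sample Akaike
criterion AICc = -2 logL + 2k + 2k(k+1)/(n-k-1), where the Gaussian
log-likelihood uses the ML error variance RSS/n and k counts the
coefficients, the intercept and the error variance. Models within
``delta_max`` of the best are averaged with renormalised Akaike weights;
the full average substitutes 0 for a predictor absent from a model, and the
unconditional standard error follows sqrt(sum_i w_i (var_i + (b_i - bbar)^2)).

The yearly temperature range (delta_t) is dropped from the candidate pool
whenever tmin and tmax are both candidates: it is their exact difference
and makes every joint design singular.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data_model import ValidationError

__all__ = [
    "ModelRecord", "AveragingResult",
    "ols_fit", "aicc", "all_subsets", "model_average",
]


@dataclass
class ModelRecord:
    predictors: tuple[str, ...]
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    t_pvalues: dict[str, float]
    rss: float
    loglik: float
    k: int
    n: int
    aicc: float = np.nan
    delta_aicc: float = np.nan
    akaike_weight: float = np.nan


@dataclass
class AveragingResult:
    estimates: pd.DataFrame  # index: term; columns: estimate, se, p, sw
    n_models_averaged: int
    single_model: bool
    models: list[ModelRecord] = field(default_factory=list, repr=False)


def ols_fit(y, x: pd.DataFrame, predictors: tuple[str, ...] | None = None) -> ModelRecord:
    """OLS fit of y on the given predictor columns (plus an intercept)."""
    y = np.asarray(y, dtype=float)
    if predictors is None:
        predictors = tuple(x.columns)
    design = sm.add_constant(x[list(predictors)].to_numpy(dtype=float),
                             has_constant="add")
    n, p = design.shape
    if np.linalg.matrix_rank(design) < p:
        raise ValidationError(
            f"rank-deficient design for predictors {predictors}"
        )
    k = p + 1  # coefficients incl. intercept + error variance
    if n <= p:
        raise ValidationError("need more observations than coefficients")
    fit = sm.OLS(y, design).fit()
    rss = float(fit.ssr)
    # Gaussian log-likelihood at the ML variance RSS/n (statsmodels' llf);
    # a numerically saturated fit has an unbounded likelihood, flagged as
    # +inf so AICc computation rejects it with a clear error.
    scale = float(np.abs(y).max() ** 2 + 1.0)
    loglik = np.inf if rss <= 1e-10 * scale else float(fit.llf)
    names = ("Intercept",) + tuple(predictors)
    return ModelRecord(
        predictors=tuple(predictors),
        coefficients=dict(zip(names, fit.params)),
        std_errors=dict(zip(names, fit.bse)),
        t_pvalues=dict(zip(names, fit.pvalues)),
        rss=rss, loglik=loglik, k=k, n=n,
    )


def aicc(loglik: float, k: int, n: int) -> float:
    """AICc = -2 logL + 2k + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        raise ValidationError(f"AICc undefined for n={n}, k={k} (n <= k+1)")
    if not np.isfinite(loglik):
        raise ValidationError("non-finite log-likelihood (saturated fit?)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _drop_exact_collinear(predictors: list[str]) -> list[str]:
    if "delta_t" in predictors and {"tmin", "tmax"} <= set(predictors):
        warnings.warn("delta_t dropped from candidates (tmax - tmin)")
        return [p for p in predictors if p != "delta_t"]
    return predictors


def all_subsets(
    y, x: pd.DataFrame, n_max_terms: int | None = None
) -> list[ModelRecord]:
    """Fit every predictor subset, rank by AICc, attach deltas and weights."""
    y = np.asarray(y, dtype=float)
    predictors = _drop_exact_collinear(list(x.columns))
    if not predictors:
        raise ValidationError("no candidate predictors")
    if n_max_terms is None:
        n_max_terms = len(predictors)
    n = len(y)
    records = []
    for size in range(0, n_max_terms + 1):
        for subset in combinations(predictors, size):
            if n - (size + 2) - 1 <= 0:
                continue  # AICc undefined at this size
            try:
                rec = ols_fit(y, x, subset)
                rec.aicc = aicc(rec.loglik, rec.k, n)
            except ValidationError as err:
                warnings.warn(f"subset {subset} skipped: {err}")
                continue
            records.append(rec)
    if not records:
        raise ValidationError("no admissible model could be fit")
    records.sort(key=lambda r: r.aicc)
    best = records[0].aicc
    deltas = np.array([r.aicc - best for r in records])
    w = np.exp(-deltas / 2)
    w /= w.sum()
    for rec, d, wi in zip(records, deltas, w):
        rec.delta_aicc = float(d)
        rec.akaike_weight = float(wi)
    return records


def model_average(
    models: list[ModelRecord], delta_max: float = 2.0
) -> AveragingResult:
    """Full-average coefficients over the models within delta_max of the best.

    If exactly one model is selected, its plain OLS estimates and t-test
    p-values are reported with ``single_model=True``.
    """
    selected = [m for m in models if m.delta_aicc <= delta_max]
    if not selected:
        raise ValidationError("no model within delta_max of the best")
    terms = ["Intercept"]
    for m in models:
        for p in m.predictors:
            if p not in terms:
                terms.append(p)

    if len(selected) == 1:
        m = selected[0]
        rows = []
        for t in ("Intercept",) + m.predictors:
            rows.append((t, m.coefficients[t], m.std_errors[t],
                         m.t_pvalues[t], 1.0))
        df = pd.DataFrame(rows, columns=["term", "estimate", "se", "p", "sw"])
        return AveragingResult(df.set_index("term"), 1, True, selected)

    w = np.array([m.akaike_weight for m in selected])
    w = w / w.sum()
    rows = []
    for t in terms:
        betas = np.array([m.coefficients.get(t, 0.0) for m in selected])
        ses = np.array([m.std_errors.get(t, 0.0) for m in selected])
        present = np.array([t == "Intercept" or t in m.predictors
                            for m in selected])
        est = float(w @ betas)
        se = float(np.sqrt(w @ (ses**2 + (betas - est) ** 2)))
        z = est / se if se > 0 else 0.0
        p = float(2 * stats.norm.sf(abs(z)))
        sw = float(w[present].sum())
        if t != "Intercept" and sw == 0:
            continue  # predictor absent from the whole selected set
        rows.append((t, est, se, p, sw))
    df = pd.DataFrame(rows, columns=["term", "estimate", "se", "p", "sw"])
    return AveragingResult(df.set_index("term"), len(selected), False, selected)
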