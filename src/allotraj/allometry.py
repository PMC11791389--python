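"""Per-species static allometry: multivariate regression of shape on lnCS.

Within one species and sex, shape scores Y (n x m) are regressed on log
centroid size x (n), giving a slope vector b (the allometric trajectory
direction), a multivariate R-squared (trace-based: model sum of squares
summed over all m responses divided by the total), and a Wilks' lambda
significance test. With a single predictor Rao's F transform of lambda is
exact: F = ((1 - L)/L) * (df2/df1) with df1 = m and df2 = n - m - 1.

A regression is called "non-negligible" when p < alpha (default 0.005) or
Rsq > rsq_threshold (default 0.05); only those species enter the
trajectory-angle analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import StudyConfig
from .procrustes import TangentScores

logger = logging.getLogger("allotraj")


@dataclass
class AllometricFit:
    """Multivariate regression of one species' shape scores on lnCS."""

    species: str
    sex: str
    n: int
    slope: np.ndarray
    intercept: np.ndarray
    rsq: float
    wilks_lambda: float
    f_stat: float
    df1: int
    df2: int
    p_value: float
    mean_ln_cs: float
    mean_scores: np.ndarray
    non_negligible: bool | None = None


@dataclass
class AllometricPrediction:
    """Allometry-predicted shapes and/or their 1D summary axis."""

    scores_on_axis: np.ndarray | None = None
    axis_variance_fraction: float | None = None
    axis: np.ndarray | None = None
    shape_at_min: np.ndarray | None = None
    shape_at_max: np.ndarray | None = None
    magnification: float | None = None


def fit_static_allometry(scores: np.ndarray, ln_cs: np.ndarray,
                         species: str = "", sex: str = "") -> AllometricFit:
    """Least-squares multivariate regression of shape scores onto lnCS.

    Requires n > m + 1 (so the Wilks test has positive error degrees of
    freedom) and non-constant lnCS.
    """
    y = np.asarray(scores, dtype=float)
    x = np.asarray(ln_cs, dtype=float)
    n, m = y.shape
    if x.shape != (n,):
        raise ValueError(f"ln_cs has shape {x.shape}, expected ({n},)")
    if n <= m + 1:
        raise ValueError(
            f"species {species!r}: n={n} too small for m={m} shape variables "
            f"(need n > m + 1)"
        )
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx <= 1e-14:
        raise ValueError(f"species {species!r}: constant lnCS, allometry undefined")
    yc = y - y.mean(axis=0)
    slope = (xc @ yc) / sxx
    intercept = y.mean(axis=0) - slope * x.mean()
    fitted = np.outer(xc, slope)
    resid = yc - fitted
    h = fitted.T @ fitted       # model cross-products
    e = resid.T @ resid         # residual cross-products
    total = float(np.trace(h) + np.trace(e))
    rsq = float(np.trace(h) / total) if total > 0 else 0.0
    sign_e, logdet_e = np.linalg.slogdet(e)
    sign_t, logdet_t = np.linalg.slogdet(e + h)
    df1, df2 = m, n - m - 1
    if sign_t <= 0:
        raise ValueError(f"species {species!r}: degenerate total cross-product matrix")
    if sign_e <= 0:  # perfect fit: residuals rank-deficient
        wilks, f_stat, p = 0.0, np.inf, 0.0
    else:
        wilks = float(np.exp(logdet_e - logdet_t))
        f_stat = float((1.0 - wilks) / wilks * (df2 / df1))
        p = float(stats.f.sf(f_stat, df1, df2))
    return AllometricFit(
        species=species, sex=sex, n=n, slope=slope, intercept=intercept,
        rsq=rsq, wilks_lambda=wilks, f_stat=f_stat, df1=df1, df2=df2,
        p_value=p, mean_ln_cs=float(x.mean()), mean_scores=y.mean(axis=0),
    )


def classify_non_negligible(fit: AllometricFit, config: StudyConfig) -> bool:
    """True when p < alpha or Rsq > rsq_threshold (either branch suffices)."""
    return bool(fit.p_value < config.alpha or fit.rsq > config.rsq_threshold)


def fit_species_allometries(scores: np.ndarray, ln_cs: np.ndarray, species_labels,
                            sex: str, config: StudyConfig):
    """Fit every species independently; mark the non-negligible rule.

    Returns ``(fits, untestable)`` where ``untestable`` lists species with
    n <= m + 1 (reported, never silently dropped).
    """
    species_labels = np.asarray(species_labels)
    m = scores.shape[1]
    fits: list[AllometricFit] = []
    untestable: list[str] = []
    for sp in sorted(set(species_labels)):
        idx = np.flatnonzero(species_labels == sp)
        if len(idx) <= m + 1:
            untestable.append(sp)
            continue
        fit = fit_static_allometry(scores[idx], ln_cs[idx], species=sp, sex=sex)
        fit.non_negligible = classify_non_negligible(fit, config)
        fits.append(fit)
    if untestable:
        logger.warning("untestable species (n <= m + 1), excluded from angles: %s", untestable)
    return fits, untestable


def fits_to_table(fits) -> pd.DataFrame:
    """Per-species fit table (species, sex, N, Rsq, Wilks, F, df, p, flag)."""
    return pd.DataFrame(
        {
            "species": [f.species for f in fits],
            "sex": [f.sex for f in fits],
            "N": [f.n for f in fits],
            "Rsq": [f.rsq for f in fits],
            "Wilks": [f.wilks_lambda for f in fits],
            "F": [f.f_stat for f in fits],
            "df1": [f.df1 for f in fits],
            "df2": [f.df2 for f in fits],
            "p": [f.p_value for f in fits],
            "non_negligible": [f.non_negligible for f in fits],
        }
    )


def predict_allometric_shapes(fit: AllometricFit, basis: TangentScores,
                              ln_cs_range: tuple[float, float],
                              magnification: float = 1.0) -> AllometricPrediction:
    """Landmark shapes predicted at the lnCS extremes of one species.

    The deviation of each predicted score vector from the species mean is
    multiplied by ``magnification`` before reconstruction through the PC
    basis, exaggerating subtle allometric displacement for display.
    """
    if magnification <= 0:
        raise ValueError("magnification must be positive")
    lo, hi = ln_cs_range
    shapes = []
    for l in (lo, hi):
        pred = fit.intercept + fit.slope * l
        magnified = fit.mean_scores + magnification * (pred - fit.mean_scores)
        shapes.append(basis.reconstruct(magnified))
    return AllometricPrediction(
        shape_at_min=shapes[0], shape_at_max=shapes[1], magnification=magnification
    )


def allometric_summary_axis(fits, scores: np.ndarray, ln_cs: np.ndarray,
                            species_labels) -> AllometricPrediction:
    """One summary axis through all species' allometric predictions.

    Per-specimen predicted scores (from each species' own regression) are
    pooled; the axis is the unit vector in their span maximizing
    covariance with lnCS (the regression-score construction), and the
    fraction of prediction variance it carries is reported.
    """
    if len(fits) < 1:
        raise ValueError("need at least one fitted species")
    species_labels = np.asarray(species_labels)
    by_species = {f.species: f for f in fits}
    rows, lcs = [], []
    for i, sp in enumerate(species_labels):
        f = by_species.get(sp)
        if f is None:
            continue
        rows.append(f.mean_scores + f.slope * (ln_cs[i] - f.mean_ln_cs))
        lcs.append(ln_cs[i])
    pred = np.asarray(rows)
    lcs = np.asarray(lcs)
    predc = pred - pred.mean(axis=0)
    total_var = float((predc**2).sum())
    if total_var <= 1e-14:
        raise ValueError("all allometric predictions identical; summary axis undefined")
    cov = predc.T @ (lcs - lcs.mean())
    norm = np.linalg.norm(cov)
    if norm <= 1e-14:
        raise ValueError("predictions uncorrelated with lnCS; axis undefined")
    w = cov / norm
    axis_scores = predc @ w
    frac = float((axis_scores**2).sum() / total_var)
    return AllometricPrediction(
        scores_on_axis=axis_scores, axis_variance_fraction=frac, axis=w
    )
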