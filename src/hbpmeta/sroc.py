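"""Summary ROC curve and confidence/prediction regions.

The SROC curve is the conditional-expectation line of logit(TPR) given
logit(FPR) under the fitted bivariate normal:

    E[logit TPR | logit FPR = f] = mu1 + (tau12 / tau2^2) (f - mu2),

mapped through the inverse logit.  The 95% confidence region is the
chi-square ellipse of the fixed-effect estimates on the logit scale (shape
matrix ``vcov_fixed``); the prediction region for a new study adds the
between-study covariance (shape ``vcov_fixed + Sigma_b``).  The inverse
logit is monotone in each coordinate, so containment of the ellipses is
preserved on the probability scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import chi2

from .bivariate import BivariateFit

__all__ = ["SROCResult", "sroc_curve", "confidence_region", "prediction_region", "compute_sroc"]


@dataclass(frozen=True)
class SROCResult:
    """SROC curve, summary point and 95% regions on the (FPR, TPR) plane."""

    curve: np.ndarray  # (m, 2) columns FPR, TPR
    summary_point: tuple[float, float]
    confidence_region: np.ndarray  # (m, 2) closed polyline
    prediction_region: np.ndarray
    level: float


def sroc_curve(
    fit: BivariateFit,
    fpr_grid: np.ndarray | None = None,
    *,
    fpr_range: tuple[float, float] | None = None,
    n_points: int = 200,
) -> np.ndarray:
    """SROC curve as (FPR, TPR) pairs.

    ``fpr_range`` restricts the curve (default: the central 99.9% Wald range
    of study-level FPR under the fit, a stand-in for the observed range when
    none is given).  With tau2 = 0 the regression slope is undefined and the
    curve degenerates to the horizontal line TPR = expit(mu1).
    """
    mu1, mu2 = float(fit.mu[0]), float(fit.mu[1])
    t22 = float(fit.sigma_between[1, 1])
    t12 = float(fit.sigma_between[0, 1])
    if fpr_grid is None:
        if fpr_range is None:
            spread = 3.29 * math.sqrt(t22 + fit.vcov_fixed[1, 1])
            fpr_range = (float(expit(mu2 - spread)), float(expit(mu2 + spread)))
        fpr_grid = np.linspace(fpr_range[0], fpr_range[1], n_points)
    fpr_grid = np.clip(np.asarray(fpr_grid, dtype=float), 1e-12, 1 - 1e-12)
    f = np.log(fpr_grid / (1 - fpr_grid))
    if t22 <= 0:
        warnings.warn("tau2 = 0: SROC slope undefined; returning flat curve at pooled TPR")
        tpr = np.full_like(f, expit(mu1))
    else:
        tpr = expit(mu1 + (t12 / t22) * (f - mu2))
    return np.column_stack([fpr_grid, tpr])


def _ellipse(center: np.ndarray, shape: np.ndarray, level: float, n_points: int) -> np.ndarray:
    """Chi-square(2) ellipse on the logit plane, mapped to probabilities."""
    shape = np.asarray(shape, dtype=float)
    try:
        L = np.linalg.cholesky(shape)
    except np.linalg.LinAlgError:
        warnings.warn("shape matrix not positive definite; adding 1e-10 ridge")
        L = np.linalg.cholesky(shape + 1e-10 * np.eye(2))
    r = math.sqrt(chi2.ppf(level, df=2))
    t = np.linspace(0, 2 * math.pi, n_points)
    circle = np.column_stack([np.cos(t), np.sin(t)])
    pts = center[None, :] + r * circle @ L.T  # logit scale (y1, y2)
    # map to (FPR, TPR) probability coordinates
    return np.column_stack([expit(pts[:, 1]), expit(pts[:, 0])])


def confidence_region(fit: BivariateFit, level: float = 0.95, n_points: int = 360) -> np.ndarray:
    """Confidence ellipse for the summary point (closed polyline)."""
    return _ellipse(np.asarray(fit.mu[:2], dtype=float), fit.vcov_fixed, level, n_points)


def prediction_region(fit: BivariateFit, level: float = 0.95, n_points: int = 360) -> np.ndarray:
    """Prediction ellipse for a new study's (FPR, TPR) pair."""
    shape = fit.vcov_fixed + fit.sigma_between
    return _ellipse(np.asarray(fit.mu[:2], dtype=float), shape, level, n_points)


def compute_sroc(
    fit: BivariateFit,
    *,
    level: float = 0.95,
    fpr_range: tuple[float, float] | None = None,
    n_points: int = 360,
) -> SROCResult:
    """Bundle curve, summary point and both regions."""
    mu1, mu2 = float(fit.mu[0]), float(fit.mu[1])
    return SROCResult(
        curve=sroc_curve(fit, fpr_range=fpr_range),
        summary_point=(float(expit(mu2)), float(expit(mu1))),
        confidence_region=confidence_region(fit, level, n_points),
        prediction_region=prediction_region(fit, level, n_points),
        level=level,
    )
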