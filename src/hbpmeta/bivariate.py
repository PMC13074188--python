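"""Bivariate logit-normal random-effects model for paired accuracy data.

Study i contributes Y_i = (logit sens_i, logit fpr_i) with within-study
covariance C_i = diag(v1_i, v2_i) (the two disease arms are independent).
The model is

    Y_i ~ N(X_i beta, Sigma_b + C_i),

with Sigma_b the 2x2 between-study covariance (tau1^2, tau2^2, off-diagonal
tau12 = rho_b tau1 tau2).  The default design X_i = I_2 estimates one mean
pair; metaregression passes covariate designs.  Variance components are
estimated by restricted maximum likelihood (REML) over the unconstrained
parameterisation (ln tau1, ln tau2, atanh rho_b), with fixed effects
profiled out by generalised least squares; maximum likelihood (ML) is
available for likelihood-ratio comparisons of fixed-effect structures.

Pooled sensitivity/specificity CIs are Wald intervals on the logit scale;
likelihood-ratio and DOR CIs come from Monte-Carlo sampling of the fixed
effects, following standard practice for these derived quantities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .io_model import StudyDataset, TransformedStudy, transform_dataset

__all__ = [
    "BivariateFit",
    "PooledSummary",
    "FitError",
    "InsufficientDataError",
    "fit_bivariate_reml",
    "fit_bivariate_ml",
    "pooled_summary",
    "lr_from_sens_spec",
    "threshold_correlation",
    "cochran_q_i2",
    "reml_grid_search",
]

_LOG_TAU_FLOOR = -8.0  # tau = exp(-8) ~ 3.4e-4: numerically zero variance
_TAU_ZERO = 1.5e-3  # taus below this are reported as boundary zeros


class FitError(RuntimeError):
    """Optimizer failed to converge from every start."""


class InsufficientDataError(ValueError):
    """Too few studies for the requested model."""


@dataclass(frozen=True)
class BivariateFit:
    """REML/ML fit of the bivariate model."""

    mu: np.ndarray  # fixed effects (beta); first two = (mu1, mu2) for X=I
    sigma_between: np.ndarray  # 2x2
    vcov_fixed: np.ndarray  # covariance of fixed-effect estimates
    loglik: float
    method: str  # "reml" or "ml"
    n_studies: int
    n_fixed: int
    converged: bool
    trace: tuple = field(default_factory=tuple)

    @property
    def tau1(self) -> float:
        return float(math.sqrt(max(self.sigma_between[0, 0], 0.0)))

    @property
    def tau2(self) -> float:
        return float(math.sqrt(max(self.sigma_between[1, 1], 0.0)))

    @property
    def rho_b(self) -> float:
        t1, t2 = self.tau1, self.tau2
        if t1 <= _TAU_ZERO or t2 <= _TAU_ZERO:
            return float("nan")
        return float(self.sigma_between[0, 1] / (t1 * t2))


@dataclass(frozen=True)
class PooledSummary:
    """Back-transformed pooled accuracy with heterogeneity diagnostics."""

    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    lr_pos: float
    lr_pos_ci: tuple[float, float]
    lr_neg: float
    lr_neg_ci: tuple[float, float]
    dor: float
    dor_ci: tuple[float, float]
    q_sens: float
    i2_sens: float
    q_spec: float
    i2_spec: float
    threshold_correlation: float  # rho_b: corr(logit sens, logit FPR)
    threshold_correlation_vs_spec: float  # corr(logit sens, logit spec) = -rho_b
    mc_draws: int
    seed: int


def _stack(transformed: Sequence[TransformedStudy]) -> tuple[np.ndarray, np.ndarray]:
    y = np.array([[t.y1, t.y2] for t in transformed])
    v = np.array([[t.v1, t.v2] for t in transformed])
    return y, v


def _theta_to_sigma(theta: np.ndarray) -> tuple[float, float, float]:
    t1 = math.exp(theta[0])
    t2 = math.exp(theta[1])
    rho = math.tanh(theta[2])
    return t1, t2, rho


def _profiled_loglik(
    t1: float,
    t2: float,
    rho: float,
    y: np.ndarray,
    v: np.ndarray,
    X: np.ndarray,
    restricted: bool,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Log-likelihood with beta profiled out by GLS.

    X has shape (k, q): per-study covariate row; the full design for study i
    is kron(I2, x_i'), so beta = (beta_sens (q), beta_fpr (q)).
    Returns (loglik, beta_hat, M) with M = sum X_i' V_i^-1 X_i (2q x 2q).
    """
    k, q = X.shape
    a = t1 * t1 + v[:, 0]
    d = t2 * t2 + v[:, 1]
    b = rho * t1 * t2
    det = a * d - b * b
    if np.any(det <= 0):
        return -np.inf, np.zeros(2 * q), np.eye(2 * q)
    i11 = d / det
    i22 = a / det
    i12 = -b / det

    if q == 1:  # intercept-only: closed-form 2x2 GLS (hot path)
        S11 = float(i11.sum())
        S22 = float(i22.sum())
        S12 = float(i12.sum())
        detS = S11 * S22 - S12 * S12
        if detS <= 0:
            return -np.inf, np.zeros(2), np.eye(2)
        r1 = float(np.dot(i11, y[:, 0]) + np.dot(i12, y[:, 1]))
        r2 = float(np.dot(i12, y[:, 0]) + np.dot(i22, y[:, 1]))
        b1 = (S22 * r1 - S12 * r2) / detS
        b2 = (S11 * r2 - S12 * r1) / detS
        e1 = y[:, 0] - b1
        e2 = y[:, 1] - b2
        quad = float(np.dot(i11, e1 * e1) + 2 * np.dot(i12, e1 * e2) + np.dot(i22, e2 * e2))
        ll = -0.5 * (2 * k * math.log(2 * math.pi) + float(np.log(det).sum()) + quad)
        M = np.array([[S11, S12], [S12, S22]])
        if restricted:
            ll += -0.5 * math.log(detS) + math.log(2 * math.pi)
        return ll, np.array([b1, b2]), M

    xxT = np.einsum("ki,kj->kij", X, X)
    M = np.empty((2 * q, 2 * q))
    M[:q, :q] = np.einsum("k,kij->ij", i11, xxT)
    M[q:, q:] = np.einsum("k,kij->ij", i22, xxT)
    M[:q, q:] = np.einsum("k,kij->ij", i12, xxT)
    M[q:, :q] = M[:q, q:].T

    r1 = i11 * y[:, 0] + i12 * y[:, 1]
    r2 = i12 * y[:, 0] + i22 * y[:, 1]
    rhs = np.concatenate([X.T @ r1, X.T @ r2])
    try:
        beta = np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError:
        return -np.inf, np.zeros(2 * q), M
    m1 = X @ beta[:q]
    m2 = X @ beta[q:]
    e1 = y[:, 0] - m1
    e2 = y[:, 1] - m2
    quad = float(np.sum(i11 * e1 * e1 + 2 * i12 * e1 * e2 + i22 * e2 * e2))
    ll = -0.5 * (2 * k * math.log(2 * math.pi) + float(np.sum(np.log(det))) + quad)
    if restricted:
        sign, logdetM = np.linalg.slogdet(M)
        if sign <= 0:
            return -np.inf, beta, M
        ll += -0.5 * logdetM + 0.5 * 2 * q * math.log(2 * math.pi)
    return ll, beta, M


def _fit(
    y: np.ndarray,
    v: np.ndarray,
    X: np.ndarray,
    *,
    restricted: bool,
    n_random_starts: int = 5,
    seed: int = 0,
) -> BivariateFit:
    k, q = X.shape

    def nll(theta: np.ndarray) -> float:
        t1, t2, rho = _theta_to_sigma(theta)
        ll, _, _ = _profiled_loglik(t1, t2, rho, y, v, X, restricted)
        return -ll if np.isfinite(ll) else 1e12

    # deterministic starts spanning small/moderate/large heterogeneity
    starts = [
        np.array([math.log(0.1), math.log(0.1), 0.0]),
        np.array([math.log(0.5), math.log(0.5), 0.0]),
        np.array([math.log(1.0), math.log(1.0), 0.0]),
        np.array([math.log(0.5), math.log(0.5), math.atanh(0.7)]),
        np.array([math.log(0.5), math.log(0.5), math.atanh(-0.7)]),
    ]
    rng = np.random.default_rng(seed)
    for _ in range(n_random_starts):
        starts.append(
            np.array(
                [
                    rng.uniform(math.log(0.05), math.log(1.5)),
                    rng.uniform(math.log(0.05), math.log(1.5)),
                    math.atanh(rng.uniform(-0.95, 0.95)),
                ]
            )
        )

    best, trace = None, []
    for s in starts:
        res = minimize(
            nll,
            s,
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000, "maxfev": 2000},
        )
        theta = np.clip(res.x, [_LOG_TAU_FLOOR, _LOG_TAU_FLOOR, -6], [5, 5, 6])
        val = nll(theta)
        trace.append((tuple(np.round(s, 3)), float(val), bool(res.success)))
        if best is None or val < best[1]:
            best = (theta, val, res.success)
    if best is None or not np.isfinite(best[1]):
        raise FitError(f"bivariate {'REML' if restricted else 'ML'} fit failed; trace={trace}")

    theta, nll_best, ok = best
    t1, t2, rho = _theta_to_sigma(theta)
    ll, beta, M = _profiled_loglik(t1, t2, rho, y, v, X, restricted)
    # snap boundary-zero variances (tau driven to the floor) to exact zero
    if t1 <= _TAU_ZERO:
        t1 = 0.0
    if t2 <= _TAU_ZERO:
        t2 = 0.0
    off = rho * t1 * t2
    sigma = np.array([[t1 * t1, off], [off, t2 * t2]])
    vcov = np.linalg.inv(M)
    return BivariateFit(
        mu=beta,
        sigma_between=sigma,
        vcov_fixed=vcov,
        loglik=float(ll),
        method="reml" if restricted else "ml",
        n_studies=k,
        n_fixed=2 * q,
        converged=bool(ok),
        trace=tuple(trace),
    )


def _prepare(
    data: StudyDataset | Sequence[TransformedStudy],
    correction: float,
    correction_mode: str,
) -> list[TransformedStudy]:
    if isinstance(data, StudyDataset):
        return transform_dataset(data, correction=correction, mode=correction_mode)
    return list(data)


def fit_bivariate_reml(
    data: StudyDataset | Sequence[TransformedStudy],
    *,
    X: np.ndarray | None = None,
    correction: float = 0.5,
    correction_mode: str = "any-zero-all-cells",
    n_random_starts: int = 5,
    seed: int = 0,
) -> BivariateFit:
    """REML fit of the bivariate model (the headline pooled analysis)."""
    transformed = _prepare(data, correction, correction_mode)
    k = len(transformed)
    if k < 2:
        raise InsufficientDataError(f"need at least 2 studies, got {k}")
    if k == 2:
        import warnings

        warnings.warn("bivariate fit with k=2 is fragile; interpret with caution")
    y, v = _stack(transformed)
    design = np.ones((k, 1)) if X is None else np.asarray(X, dtype=float)
    return _fit(y, v, design, restricted=True, n_random_starts=n_random_starts, seed=seed)


def fit_bivariate_ml(
    data: StudyDataset | Sequence[TransformedStudy],
    *,
    X: np.ndarray | None = None,
    correction: float = 0.5,
    correction_mode: str = "any-zero-all-cells",
    n_random_starts: int = 5,
    seed: int = 0,
) -> BivariateFit:
    """ML fit; log-likelihoods are comparable across fixed-effect designs."""
    transformed = _prepare(data, correction, correction_mode)
    k = len(transformed)
    if k < 2:
        raise InsufficientDataError(f"need at least 2 studies, got {k}")
    y, v = _stack(transformed)
    design = np.ones((k, 1)) if X is None else np.asarray(X, dtype=float)
    return _fit(y, v, design, restricted=False, n_random_starts=n_random_starts, seed=seed)


def reml_grid_search(
    data: StudyDataset | Sequence[TransformedStudy],
    *,
    tau_max: float = 1.5,
    step: float = 0.01,
    rho_step: float = 0.01,
    correction: float = 0.5,
) -> tuple[float, tuple[float, float, float]]:
    """Exhaustive restricted-log-likelihood grid search (oracle).

    Scans (tau1, tau2, rho_b) on a regular grid and returns the best
    restricted log-likelihood and its grid point.  Independent of the
    optimizer path: used to audit ``fit_bivariate_reml``.
    """
    transformed = _prepare(data, correction, "any-zero-all-cells")
    y, v = _stack(transformed)
    k = len(transformed)
    taus = np.arange(0.0, tau_max + step / 2, step)
    rhos = np.arange(-0.99, 0.99 + rho_step / 2, rho_step)
    T1, T2 = np.meshgrid(taus, taus, indexing="ij")

    best_ll, best_pt = -np.inf, (0.0, 0.0, 0.0)
    v1 = v[:, 0][:, None, None]
    v2 = v[:, 1][:, None, None]
    y1 = y[:, 0][:, None, None]
    y2 = y[:, 1][:, None, None]
    A = T1**2 + v1  # (k, m, m)
    D = T2**2 + v2
    const = 2 * k * math.log(2 * math.pi) - 2 * math.log(2 * math.pi)
    for rho in rhos:
        B = rho * T1 * T2  # (m, m)
        det = A * D - B**2
        i11 = D / det
        i22 = A / det
        i12 = -B / det
        S11 = i11.sum(axis=0)
        S22 = i22.sum(axis=0)
        S12 = i12.sum(axis=0)
        detS = S11 * S22 - S12**2
        r1 = (i11 * y1 + i12 * y2).sum(axis=0)
        r2 = (i12 * y1 + i22 * y2).sum(axis=0)
        b1 = (S22 * r1 - S12 * r2) / detS
        b2 = (S11 * r2 - S12 * r1) / detS
        e1 = y1 - b1[None]
        e2 = y2 - b2[None]
        quad = (i11 * e1**2 + 2 * i12 * e1 * e2 + i22 * e2**2).sum(axis=0)
        ll = -0.5 * (const + np.log(det).sum(axis=0) + np.log(detS) + quad)
        idx = np.unravel_index(np.nanargmax(ll), ll.shape)
        if ll[idx] > best_ll:
            best_ll = float(ll[idx])
            best_pt = (float(taus[idx[0]]), float(taus[idx[1]]), float(rho))
    return best_ll, best_pt


def lr_from_sens_spec(sens: float, spec: float) -> tuple[float, float, float]:
    """(LR+, LR-, DOR) from a sensitivity/specificity pair."""
    if not (0 < sens < 1 and 0 < spec < 1):
        raise ValueError(
            "sensitivity and specificity must lie strictly inside (0,1); "
            "apply a continuity correction upstream for boundary proportions"
        )
    lr_pos = sens / (1 - spec)
    lr_neg = (1 - sens) / spec
    return lr_pos, lr_neg, lr_pos / lr_neg


def threshold_correlation(fit: BivariateFit) -> float:
    """Between-study correlation of logit sensitivity and logit FPR (rho_b).

    |rho_b| near 1 flags a threshold effect.  NaN when either between-study
    variance is at the zero boundary (correlation undefined).
    """
    return fit.rho_b


def cochran_q_i2(
    transformed: Sequence[TransformedStudy],
    outcome: str = "sensitivity",
) -> tuple[float, float]:
    """Descriptive Cochran's Q and I^2 for one logit outcome.

    Univariate inverse-variance fixed-effect pooling of logit(sens) or
    logit(FPR); I^2 = max(0, (Q - (k-1))/Q) * 100.  Note logit(FPR) and
    logit(spec) differ only in sign, so Q and I^2 for "fpr" equal those
    for specificity.
    """
    if outcome not in ("sensitivity", "fpr"):
        raise ValueError("outcome must be 'sensitivity' or 'fpr'")
    k = len(transformed)
    if k < 2:
        raise InsufficientDataError("Q/I^2 need at least 2 studies")
    if outcome == "sensitivity":
        yv = np.array([(t.y1, t.v1) for t in transformed])
    else:
        yv = np.array([(t.y2, t.v2) for t in transformed])
    w = 1.0 / yv[:, 1]
    yhat = float(np.sum(w * yv[:, 0]) / np.sum(w))
    q = float(np.sum(w * (yv[:, 0] - yhat) ** 2))
    i2 = max(0.0, (q - (k - 1)) / q) * 100.0 if q > 0 else 0.0
    return q, i2


def pooled_summary(
    fit: BivariateFit,
    transformed: Sequence[TransformedStudy] | None = None,
    *,
    mc_draws: int = 100_000,
    seed: int = 0,
    level: float = 0.95,
) -> PooledSummary:
    """Back-transform a fit into the pooled accuracy summary.

    Wald CIs on the logit scale for sensitivity/specificity; Monte-Carlo
    percentile CIs (draws of the fixed effects from N(mu, vcov_fixed)) for
    LR+/LR-/DOR.
    """
    from scipy.stats import norm as _norm

    if fit.n_fixed != 2:
        raise ValueError("pooled_summary expects an intercept-only fit")
    z = _norm.ppf(0.5 + level / 2)
    mu1, mu2 = float(fit.mu[0]), float(fit.mu[1])
    se1 = math.sqrt(fit.vcov_fixed[0, 0])
    se2 = math.sqrt(fit.vcov_fixed[1, 1])
    sens = float(expit(mu1))
    spec = float(1.0 - expit(mu2))
    sens_ci = (float(expit(mu1 - z * se1)), float(expit(mu1 + z * se1)))
    spec_ci = (float(1 - expit(mu2 + z * se2)), float(1 - expit(mu2 - z * se2)))

    lr_pos, lr_neg, dor = lr_from_sens_spec(sens, spec)

    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(
        [mu1, mu2], fit.vcov_fixed, size=mc_draws, method="cholesky"
    )
    s = expit(draws[:, 0])
    f = expit(draws[:, 1])
    lp = s / f
    ln = (1 - s) / (1 - f)
    lo, hi = (1 - level) / 2 * 100, (1 + level) / 2 * 100
    lr_pos_ci = tuple(np.percentile(lp, [lo, hi]))
    lr_neg_ci = tuple(np.percentile(ln, [lo, hi]))
    dor_ci = tuple(np.percentile(lp / ln, [lo, hi]))

    if transformed is not None:
        q_sens, i2_sens = cochran_q_i2(transformed, "sensitivity")
        q_spec, i2_spec = cochran_q_i2(transformed, "fpr")
    else:
        q_sens = i2_sens = q_spec = i2_spec = float("nan")

    rho = fit.rho_b
    return PooledSummary(
        sensitivity=sens,
        sensitivity_ci=sens_ci,
        specificity=spec,
        specificity_ci=spec_ci,
        lr_pos=float(lr_pos),
        lr_pos_ci=(float(lr_pos_ci[0]), float(lr_pos_ci[1])),
        lr_neg=float(lr_neg),
        lr_neg_ci=(float(lr_neg_ci[0]), float(lr_neg_ci[1])),
        dor=float(dor),
        dor_ci=(float(dor_ci[0]), float(dor_ci[1])),
        q_sens=q_sens,
        i2_sens=i2_sens,
        q_spec=q_spec,
        i2_spec=i2_spec,
        threshold_correlation=rho,
        threshold_correlation_vs_spec=-rho if math.isfinite(rho) else rho,
        mc_draws=mc_draws,
        seed=seed,
    )
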