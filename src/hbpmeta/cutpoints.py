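"""Multiple-cutoff meta-analytic model and decision-threshold extraction.

Studies dichotomise the biomarker at different cutoffs c_i.  Treating each
study's (cutoff, specificity) and (cutoff, 1 - sensitivity) pairs as noisy
evaluations of the group-wise biomarker CDFs, the model fits two weighted
logistic-linear lines on a transformed cutoff scale f(c):

    logit(specificity_i)      = a_nd + b_nd f(c_i)   (non-diseased CDF)
    logit(1 - sensitivity_i)  = a_d  + b_d  f(c_i)   (diseased CDF)

by weighted least squares (default weights: group sample sizes).  Three
transforms f (identity, log, sqrt) compete on a combined AIC from the joint
weighted Gaussian likelihood of both lines.  The fitted curves yield the
Youden-optimal cutoff (grid + local refinement, cluster-bootstrap CI),
continuous LR+/LR- curves, and the rule-in / rule-out cutoffs where LR+
crosses 10 and LR- crosses 0.1.

With one cutoff per study (this corpus), study-level random effects are
unidentifiable, so the default is fixed-effects WLS.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.special import expit

from .bivariate import InsufficientDataError
from .io_model import StudyDataset, apply_continuity_correction

__all__ = [
    "CutpointFit",
    "ThresholdReport",
    "TRANSFORMS",
    "fit_cutpoint_model",
    "select_transform",
    "predict_accuracy",
    "optimal_cutoff_youden",
    "bootstrap_cutoff_ci",
    "lr_curves",
    "find_lr_thresholds",
    "threshold_report",
]

TRANSFORMS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "identity": lambda c: np.asarray(c, dtype=float),
    "log": lambda c: np.log(c),
    "sqrt": lambda c: np.sqrt(c),
}

MIN_CUTOFF_STUDIES = 3


@dataclass(frozen=True)
class CutpointFit:
    """Two-line WLS fit on one cutoff transform."""

    transform: str
    a_d: float  # intercept, diseased line (logit(1-sens))
    b_d: float  # slope, diseased line
    a_nd: float  # intercept, non-diseased line (logit spec)
    b_nd: float  # slope, non-diseased line
    aic: float
    weighting: str
    included_studies: tuple[str, ...]
    cutoff_range: tuple[float, float]  # observed cutoffs
    aic_by_transform: dict = field(default_factory=dict)
    tie_note: str = ""

    @property
    def k(self) -> int:
        return len(self.included_studies)


@dataclass(frozen=True)
class ThresholdReport:
    """Youden-optimal and LR-based decision thresholds (ng/mL)."""

    youden_cutoff: float
    youden_value: float
    sens_at_opt: float
    spec_at_opt: float
    bootstrap_ci: tuple[float, float] | None
    bootstrap_B: int
    bootstrap_failures: int
    bootstrap_seed: int
    rule_in_cutoff: float | None  # LR+ crosses 10; None = not achieved on grid
    rule_out_cutoff: float | None  # LR- crosses 0.1
    lr_pos_target: float
    lr_neg_target: float
    grid: tuple[float, float, int]  # lo, hi, n of evaluation grid
    multiplicity_note: str = ""
    unstable_bootstrap: bool = False


def _study_arrays(dataset: StudyDataset, correction: float) -> tuple[np.ndarray, ...]:
    ds = dataset.with_cutoffs()
    corrected = apply_continuity_correction(ds, value=correction)
    c, y_d, y_nd, w_d, w_nd, ids = [], [], [], [], [], []
    for r in corrected.records:
        tp, fp, fn, tn = r.effective_counts()
        c.append(r.cutoff)
        y_d.append(math.log(fn / tp))  # logit(1 - sens)
        y_nd.append(math.log(tn / fp))  # logit(spec)
        w_d.append(r.n_diseased)
        w_nd.append(r.n_nondiseased)
        ids.append(r.study_id)
    return (
        np.asarray(c, dtype=float),
        np.asarray(y_d),
        np.asarray(y_nd),
        np.asarray(w_d, dtype=float),
        np.asarray(w_nd, dtype=float),
        np.asarray(ids, dtype=object),
    )


def _wls_line(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float, float]:
    """Closed-form weighted least squares; returns (a, b, weighted RSS)."""
    W = np.sum(w)
    xbar = np.sum(w * x) / W
    ybar = np.sum(w * y) / W
    sxx = np.sum(w * (x - xbar) ** 2)
    if sxx <= 0:
        raise ValueError("cutoffs are all equal: slope unidentifiable")
    b = np.sum(w * (x - xbar) * (y - ybar)) / sxx
    a = ybar - b * xbar
    rss = float(np.sum(w * (y - a - b * x) ** 2))
    return float(a), float(b), rss


def _weighted_gaussian_aic(rss: np.ndarray, w: np.ndarray, n: int, n_params: int) -> float:
    """AIC of a weighted Gaussian line: y_i ~ N(a + b x_i, s^2 / w_i)."""
    sigma2 = float(np.sum(rss)) / n  # rss already weighted
    ll = -0.5 * n * (math.log(2 * math.pi) + 1 + math.log(sigma2)) + 0.5 * float(
        np.sum(np.log(w))
    )
    return -2.0 * ll + 2.0 * n_params


def fit_cutpoint_model(
    dataset: StudyDataset,
    transform: str = "log",
    *,
    correction: float = 0.5,
    weighting: str = "sample-size",
) -> CutpointFit:
    """Fit the two-line model on one transform; combined AIC for comparison."""
    if transform not in TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}; choose from {sorted(TRANSFORMS)}")
    c, y_d, y_nd, w_d, w_nd, ids = _study_arrays(dataset, correction)
    k = len(c)
    if k < MIN_CUTOFF_STUDIES:
        raise InsufficientDataError(
            f"cutpoint model needs >= {MIN_CUTOFF_STUDIES} studies with cutoffs, got {k}"
        )
    if np.allclose(c, c[0]):
        raise ValueError("all cutoffs equal: slope unidentifiable")
    if weighting == "sample-size":
        wd, wnd = w_d, w_nd
    elif weighting == "equal":
        wd = np.ones(k)
        wnd = np.ones(k)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    x = TRANSFORMS[transform](c)
    a_d, b_d, rss_d = _wls_line(x, y_d, wd)
    a_nd, b_nd, rss_nd = _wls_line(x, y_nd, wnd)
    # joint two-line likelihood: shared structure, 6 parameters
    # (2 intercepts, 2 slopes, 2 error scales)
    sigma_d2 = rss_d / k
    sigma_nd2 = rss_nd / k
    ll = (
        -0.5 * k * (math.log(2 * math.pi) + 1 + math.log(sigma_d2))
        + 0.5 * float(np.sum(np.log(wd)))
        - 0.5 * k * (math.log(2 * math.pi) + 1 + math.log(sigma_nd2))
        + 0.5 * float(np.sum(np.log(wnd)))
    )
    aic = -2.0 * ll + 2.0 * 6
    return CutpointFit(
        transform=transform,
        a_d=a_d,
        b_d=b_d,
        a_nd=a_nd,
        b_nd=b_nd,
        aic=float(aic),
        weighting=weighting,
        included_studies=tuple(str(i) for i in ids),
        cutoff_range=(float(np.min(c)), float(np.max(c))),
    )


def select_transform(
    dataset: StudyDataset,
    *,
    correction: float = 0.5,
    weighting: str = "sample-size",
) -> CutpointFit:
    """Fit identity/log/sqrt transforms; keep the minimum combined AIC.

    Ties (within 1e-9) break toward the log transform, the natural choice
    for a positive concentration scale.
    """
    fits = {
        name: fit_cutpoint_model(dataset, name, correction=correction, weighting=weighting)
        for name in TRANSFORMS
    }
    aics = {name: f.aic for name, f in fits.items()}
    best_aic = min(aics.values())
    tied = [name for name, a in aics.items() if a <= best_aic + 1e-9]
    chosen = "log" if "log" in tied else tied[0]
    note = f"AIC tie among {tied}; log preferred" if len(tied) > 1 else ""
    return replace(fits[chosen], aic_by_transform=dict(aics), tie_note=note)


def predict_accuracy(
    fit: CutpointFit, c: float | np.ndarray, *, warn_extrapolation: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """(sensitivity, specificity) predicted at cutoff(s) c."""
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr <= 0):
        raise ValueError("cutoffs must be positive")
    lo, hi = fit.cutoff_range
    if warn_extrapolation and (np.any(c_arr < lo) or np.any(c_arr > hi)):
        warnings.warn(
            f"prediction outside the observed cutoff range [{lo:.3g}, {hi:.3g}] "
            "is a statistical extrapolation"
        )
    x = TRANSFORMS[fit.transform](c_arr)
    sens = 1.0 - expit(fit.a_d + fit.b_d * x)
    spec = expit(fit.a_nd + fit.b_nd * x)
    return sens, spec


def _default_grid(fit: CutpointFit, n: int = 2000) -> np.ndarray:
    # evaluation extends beyond observed cutoffs (0.5*cmin .. 1.2*cmax),
    # mirroring how boundary LR extrema are reported by cutoff-model software
    lo, hi = fit.cutoff_range
    return np.geomspace(0.5 * lo, 1.2 * hi, n)


def optimal_cutoff_youden(
    fit: CutpointFit,
    *,
    grid: np.ndarray | None = None,
    n_grid: int = 2000,
) -> tuple[float, float, float, float]:
    """Maximize J(c) = sens(c) + spec(c) - 1 (grid scan + local refinement).

    Returns (c*, J*, sens(c*), spec(c*)).  Raises if J <= 0 everywhere
    (the marker carries no information on the evaluated range).
    """
    g = _default_grid(fit, n_grid) if grid is None else np.asarray(grid, dtype=float)
    sens, spec = predict_accuracy(fit, g, warn_extrapolation=False)
    J = sens + spec - 1.0
    i = int(np.argmax(J))
    if J[i] <= 0:
        raise ValueError("Youden index non-positive on the whole grid: no useful optimum")
    lo = g[max(i - 1, 0)]
    hi = g[min(i + 1, len(g) - 1)]

    def neg_j(lc: float) -> float:
        s, sp = predict_accuracy(fit, math.exp(lc), warn_extrapolation=False)
        return -(float(s) + float(sp) - 1.0)

    res = minimize_scalar(
        neg_j, bounds=(math.log(lo), math.log(hi)), method="bounded",
        options={"xatol": 1e-12},
    )
    c_star = float(math.exp(res.x))
    s_star, sp_star = predict_accuracy(fit, c_star, warn_extrapolation=False)
    return c_star, float(s_star + sp_star - 1.0), float(s_star), float(sp_star)


def bootstrap_cutoff_ci(
    dataset: StudyDataset,
    transform: str,
    *,
    B: int = 1000,
    seed: int = 0,
    correction: float = 0.5,
    weighting: str = "sample-size",
    level: float = 0.95,
) -> tuple[tuple[float, float], int]:
    """Cluster-bootstrap percentile CI for the Youden-optimal cutoff.

    Studies (clusters) are resampled with replacement, the chosen transform
    is refit, and the optimum recomputed; failed refits (e.g. all resampled
    cutoffs equal) are dropped and counted.
    """
    ds = dataset.with_cutoffs()
    rng = np.random.default_rng(seed)
    estimates, failures = [], 0
    records = ds.records
    k = len(records)
    for _ in range(B):
        idx = rng.integers(0, k, size=k)
        resampled = tuple(
            replace(records[j], study_id=f"{records[j].study_id}#{pos}")
            for pos, j in enumerate(idx)
        )
        try:
            bfit = fit_cutpoint_model(
                StudyDataset(records=resampled, provenance="bootstrap"),
                transform,
                correction=correction,
                weighting=weighting,
            )
            c_star, _, _, _ = optimal_cutoff_youden(bfit)
            estimates.append(c_star)
        except (ValueError, InsufficientDataError):
            failures += 1
    if failures > 0.2 * B:
        warnings.warn(f"unstable bootstrap: {failures}/{B} resamples failed to refit")
    if not estimates:
        raise RuntimeError("all bootstrap resamples failed")
    lo, hi = np.percentile(estimates, [(1 - level) / 2 * 100, (1 + level) / 2 * 100])
    return (float(lo), float(hi)), failures


def lr_curves(
    fit: CutpointFit,
    grid: np.ndarray | None = None,
    *,
    n_grid: int = 2000,
) -> dict[str, np.ndarray]:
    """Continuous LR+ and LR- curves over the evaluation grid.

    The region outside the observed cutoff range is flagged extrapolated.
    """
    g = _default_grid(fit, n_grid) if grid is None else np.asarray(grid, dtype=float)
    sens, spec = predict_accuracy(fit, g, warn_extrapolation=False)
    lr_pos = sens / (1.0 - spec)
    lr_neg = (1.0 - sens) / spec
    lo, hi = fit.cutoff_range
    return {
        "cutoff": g,
        "sens": sens,
        "spec": spec,
        "lr_pos": lr_pos,
        "lr_neg": lr_neg,
        "extrapolated": (g < lo) | (g > hi),
    }


def _crossings(
    fit: CutpointFit, g: np.ndarray, values: np.ndarray, target: float, which: str
) -> list[float]:
    """Roots of curve(c) = target, bracketed on the grid then refined."""

    def f(c: float) -> float:
        s, sp = predict_accuracy(fit, c, warn_extrapolation=False)
        if which == "lr_pos":
            return float(s / (1 - sp)) - target
        return float((1 - s) / sp) - target

    diff = values - target
    roots = []
    sign = np.sign(diff)
    for i in range(len(g) - 1):
        if sign[i] == 0:
            roots.append(float(g[i]))
        elif sign[i] * sign[i + 1] < 0:
            roots.append(float(brentq(f, g[i], g[i + 1], xtol=1e-10)))
    if sign[-1] == 0:
        roots.append(float(g[-1]))
    return roots


def find_lr_thresholds(
    fit: CutpointFit,
    *,
    lr_pos_target: float = 10.0,
    lr_neg_target: float = 0.1,
    grid: np.ndarray | None = None,
    n_grid: int = 2000,
    youden_cutoff: float | None = None,
) -> tuple[float | None, float | None, str]:
    """Rule-in / rule-out cutoffs from the LR curves.

    Rule-in: cutoff where LR+ crosses ``lr_pos_target``; rule-out: cutoff
    where LR- crosses ``lr_neg_target``.  If the target is met on the whole
    grid, the corresponding grid edge is returned; if never met, None
    ("not achieved on grid").  With multiple crossings the one nearest the
    Youden optimum is chosen and the multiplicity noted.
    """
    g = _default_grid(fit, n_grid) if grid is None else np.asarray(grid, dtype=float)
    curves = lr_curves(fit, g)
    notes = []
    if youden_cutoff is None:
        try:
            youden_cutoff = optimal_cutoff_youden(fit, grid=g)[0]
        except ValueError:
            youden_cutoff = float(np.sqrt(g[0] * g[-1]))

    def pick(roots: list[float], label: str) -> float | None:
        if not roots:
            return None
        if len(roots) > 1:
            notes.append(f"{label}: {len(roots)} crossings {np.round(roots, 2).tolist()}")
            return min(roots, key=lambda c: abs(math.log(c / youden_cutoff)))
        return roots[0]

    rp = curves["lr_pos"]
    if np.all(rp >= lr_pos_target):
        rule_in: float | None = float(g[0])
        notes.append("LR+ target met over the entire grid; rule-in at lower grid edge")
    else:
        rule_in = pick(_crossings(fit, g, rp, lr_pos_target, "lr_pos"), "LR+")
        if rule_in is None:
            notes.append("LR+ target not achieved on grid")

    rn = curves["lr_neg"]
    if np.all(rn <= lr_neg_target):
        rule_out: float | None = float(g[-1])
        notes.append("LR- target met over the entire grid; rule-out at upper grid edge")
    else:
        rule_out = pick(_crossings(fit, g, rn, lr_neg_target, "lr_neg"), "LR-")
        if rule_out is None:
            notes.append("LR- target not achieved on grid")
    return rule_in, rule_out, "; ".join(notes)


def threshold_report(
    dataset: StudyDataset,
    *,
    transform: str | None = None,
    lr_pos_target: float = 10.0,
    lr_neg_target: float = 0.1,
    B: int = 1000,
    seed: int = 0,
    correction: float = 0.5,
    n_grid: int = 2000,
) -> tuple[ThresholdReport, CutpointFit]:
    """End-to-end cutoff analysis: select transform, optimum, CI, thresholds."""
    if transform is None:
        fit = select_transform(dataset, correction=correction)
    else:
        fit = fit_cutpoint_model(dataset, transform, correction=correction)
    c_star, j_star, s_star, sp_star = optimal_cutoff_youden(fit, n_grid=n_grid)
    ci, failures = bootstrap_cutoff_ci(
        dataset, fit.transform, B=B, seed=seed, correction=correction
    )
    rule_in, rule_out, note = find_lr_thresholds(
        fit,
        lr_pos_target=lr_pos_target,
        lr_neg_target=lr_neg_target,
        n_grid=n_grid,
        youden_cutoff=c_star,
    )
    g = _default_grid(fit, n_grid)
    report = ThresholdReport(
        youden_cutoff=c_star,
        youden_value=j_star,
        sens_at_opt=s_star,
        spec_at_opt=sp_star,
        bootstrap_ci=ci,
        bootstrap_B=B,
        bootstrap_failures=failures,
        bootstrap_seed=seed,
        rule_in_cutoff=rule_in,
        rule_out_cutoff=rule_out,
        lr_pos_target=lr_pos_target,
        lr_neg_target=lr_neg_target,
        grid=(float(g[0]), float(g[-1]), n_grid),
        multiplicity_note=note,
        unstable_bootstrap=failures > 0.2 * B,
    )
    return report, fit
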