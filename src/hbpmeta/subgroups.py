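"""Subgroup bivariate fits and univariable metaregression.

Subgroups are refit independently (REML) per covariate level; levels with
fewer than three studies are skipped, not modeled.  Metaregression adds one
covariate at a time to both mean components of the bivariate model and
compares ML (not REML) log-likelihoods with a chi-square likelihood-ratio
test on 2 x (levels - 1) degrees of freedom; ML is required because REML
log-likelihoods are not comparable across fixed-effect structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .bivariate import (
    BivariateFit,
    PooledSummary,
    fit_bivariate_ml,
    fit_bivariate_reml,
    pooled_summary,
)
from .io_model import StudyDataset, transform_dataset

__all__ = ["SubgroupLevel", "SubgroupResult", "MetaregResult", "fit_subgroups", "metaregression"]

MIN_STUDIES_PER_SUBGROUP = 3


@dataclass(frozen=True)
class SubgroupLevel:
    level: str
    k: int
    n_total: int
    fit: BivariateFit | None
    summary: PooledSummary | None
    skipped: bool
    skip_reason: str = ""


@dataclass(frozen=True)
class SubgroupResult:
    variable: str
    levels: tuple[SubgroupLevel, ...]
    notes: str = ""


@dataclass(frozen=True)
class MetaregResult:
    covariate: str
    lrt_statistic: float
    df: int
    p_value: float
    ml_loglik_null: float
    ml_loglik_full: float
    levels: tuple[str, ...] = field(default_factory=tuple)


def fit_subgroups(
    dataset: StudyDataset,
    variable: str,
    *,
    missing_level: str = "unreported",
    mc_draws: int = 100_000,
    seed: int = 0,
    correction: float = 0.5,
) -> SubgroupResult:
    """Independent bivariate REML fit per covariate level (k >= 3 only)."""
    labels = dataset.covariate_levels(variable, missing=missing_level)
    out = []
    for level in sorted(set(labels)):
        sub = dataset.subset(lambda r: r.covariates.get(variable, missing_level) == level)
        n_total = sum(r.n for r in sub.records)
        if sub.k < MIN_STUDIES_PER_SUBGROUP:
            out.append(
                SubgroupLevel(
                    level=level,
                    k=sub.k,
                    n_total=n_total,
                    fit=None,
                    summary=None,
                    skipped=True,
                    skip_reason=f"only {sub.k} studies (< {MIN_STUDIES_PER_SUBGROUP})",
                )
            )
            continue
        fit = fit_bivariate_reml(sub, correction=correction, seed=seed)
        transformed = transform_dataset(sub, correction=correction)
        summ = pooled_summary(fit, transformed, mc_draws=mc_draws, seed=seed)
        out.append(
            SubgroupLevel(
                level=level, k=sub.k, n_total=n_total, fit=fit, summary=summ, skipped=False
            )
        )
    notes = ""
    if all(lv.skipped for lv in out):
        notes = "no level reached the minimum of 3 studies; no subgroup model fitted"
    return SubgroupResult(variable=variable, levels=tuple(out), notes=notes)


def metaregression(
    dataset: StudyDataset,
    covariate: str,
    *,
    missing_level: str = "unreported",
    correction: float = 0.5,
    seed: int = 0,
    n_random_starts: int = 5,
) -> MetaregResult:
    """Univariable metaregression with a chi-square likelihood-ratio test.

    The covariate enters both the logit-sensitivity and logit-FPR means
    (df = 2 per contrast).  Null and full models are refit by ML so the
    log-likelihoods are comparable.
    """
    labels = dataset.covariate_levels(covariate, missing=missing_level)
    levels = sorted(set(labels))
    if len(levels) < 2:
        # degenerate design: full model equals null model
        null = fit_bivariate_ml(dataset, correction=correction, seed=seed,
                                n_random_starts=n_random_starts)
        return MetaregResult(
            covariate=covariate,
            lrt_statistic=0.0,
            df=0,
            p_value=1.0,
            ml_loglik_null=null.loglik,
            ml_loglik_full=null.loglik,
            levels=tuple(levels),
        )
    counts = {lv: labels.count(lv) for lv in levels}
    empty = [lv for lv, c in counts.items() if c == 0]
    if empty:
        raise ValueError(f"covariate {covariate!r}: empty level(s) {empty}")

    k = dataset.k
    X_full = np.ones((k, len(levels)))
    for j, lv in enumerate(levels[1:], start=1):
        X_full[:, j] = [1.0 if lab == lv else 0.0 for lab in labels]
    rank = np.linalg.matrix_rank(X_full)
    if rank < X_full.shape[1]:
        raise ValueError(f"covariate {covariate!r}: singular design (separated levels)")

    null = fit_bivariate_ml(dataset, correction=correction, seed=seed,
                            n_random_starts=n_random_starts)
    full = fit_bivariate_ml(dataset, X=X_full, correction=correction, seed=seed,
                            n_random_starts=n_random_starts)
    stat = max(0.0, 2.0 * (full.loglik - null.loglik))
    df = 2 * (len(levels) - 1)
    p = float(chi2.sf(stat, df)) if df > 0 else 1.0
    return MetaregResult(
        covariate=covariate,
        lrt_statistic=float(stat),
        df=df,
        p_value=p,
        ml_loglik_null=float(null.loglik),
        ml_loglik_full=float(full.loglik),
        levels=tuple(levels),
    )
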