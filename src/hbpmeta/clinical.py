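"""Clinical-utility computations: Fagan updating, Deeks' test, decision zones.

Fagan post-test probabilities are Bayes updates on the odds scale
(post-odds = pre-odds x LR).  Deeks' funnel asymmetry test regresses
ln DOR on 1/sqrt(effective sample size) with ESS weights and tests the
slope against zero with a t reference on k-2 df, flagging asymmetry at
p < 0.10.  Zone classification maps a measured HBP concentration onto the
rule-out / gray / rule-in bands of a ThresholdReport.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .bivariate import InsufficientDataError, PooledSummary
from .io_model import StudyDataset, apply_continuity_correction

__all__ = [
    "FaganRow",
    "FaganTable",
    "DeeksResult",
    "post_test_probability",
    "fagan_table",
    "deeks_test",
    "classify_measurement",
    "round_percent",
]

DEEKS_ALPHA = 0.10


def round_percent(p: float) -> int:
    """Probability -> whole percent, rounding half-up (display convention)."""
    return int(Decimal(p * 100).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def post_test_probability(pretest: float, lr: float) -> float:
    """Bayes update of a pretest probability through a likelihood ratio."""
    if not 0 < pretest < 1:
        raise ValueError("pretest probability must be strictly inside (0,1)")
    if not lr > 0:
        raise ValueError("likelihood ratio must be positive")
    odds = pretest / (1 - pretest) * lr
    return odds / (1 + odds)


@dataclass(frozen=True)
class FaganRow:
    pretest: float
    post_positive: float
    post_negative: float

    @property
    def display(self) -> tuple[int, int, int]:
        return (
            round_percent(self.pretest),
            round_percent(self.post_positive),
            round_percent(self.post_negative),
        )


@dataclass(frozen=True)
class FaganTable:
    rows: tuple[FaganRow, ...]
    lr_pos: float
    lr_neg: float


def fagan_table(
    summary: PooledSummary | tuple[float, float],
    pretests: Sequence[float] = (0.25, 0.50, 0.75),
) -> FaganTable:
    """Post-test probabilities after positive/negative results at each pretest."""
    if isinstance(summary, PooledSummary):
        lr_pos, lr_neg = summary.lr_pos, summary.lr_neg
    else:
        lr_pos, lr_neg = summary
    rows = tuple(
        FaganRow(
            pretest=p,
            post_positive=post_test_probability(p, lr_pos),
            post_negative=post_test_probability(p, lr_neg),
        )
        for p in pretests
    )
    return FaganTable(rows=rows, lr_pos=lr_pos, lr_neg=lr_neg)


@dataclass(frozen=True)
class DeeksResult:
    slope: float
    intercept: float
    slope_se: float
    p_value: float
    ess: tuple[float, ...]
    ln_dor: tuple[float, ...]
    asymmetry: bool
    alpha: float = DEEKS_ALPHA


def deeks_test(
    dataset: StudyDataset,
    *,
    correction: float = 0.5,
    alpha: float = DEEKS_ALPHA,
) -> DeeksResult:
    """Deeks' funnel-plot asymmetry test for small-study effects.

    ESS_i = 4 n1 n2 / (n1 + n2); WLS of ln DOR on 1/sqrt(ESS) with weights
    ESS; two-sided t test (k-2 df) on the slope.
    """
    if dataset.k < 3:
        raise InsufficientDataError("Deeks' test needs at least 3 studies")
    corrected = apply_continuity_correction(dataset, value=correction)
    ess, ln_dor = [], []
    for r in corrected.records:
        tp, fp, fn, tn = r.effective_counts()
        n1, n2 = r.n_diseased, r.n_nondiseased
        ess.append(4.0 * n1 * n2 / (n1 + n2))
        ln_dor.append(math.log((tp * tn) / (fp * fn)))
    ess_arr = np.asarray(ess)
    x = 1.0 / np.sqrt(ess_arr)
    if np.ptp(x) == 0:
        raise ValueError("effective sample size identical in every study; "
                         "funnel regression slope is unidentifiable")
    X = sm.add_constant(x)
    res = sm.WLS(np.asarray(ln_dor), X, weights=ess_arr).fit()
    slope = float(res.params[1])
    p = float(res.pvalues[1])  # t reference with k-2 df
    return DeeksResult(
        slope=slope,
        intercept=float(res.params[0]),
        slope_se=float(res.bse[1]),
        p_value=p,
        ess=tuple(float(e) for e in ess),
        ln_dor=tuple(float(d) for d in ln_dor),
        asymmetry=bool(p < alpha),
        alpha=alpha,
    )


def classify_measurement(value: float, rule_out: float, rule_in: float) -> str:
    """Map a measured concentration onto decision zones.

    value <= rule_out -> "rule-out"; value >= rule_in -> "rule-in";
    otherwise "gray".  Boundaries are inclusive on their own side.
    """
    if not value > 0:
        raise ValueError("measurement must be positive")
    if not rule_out < rule_in:
        raise ValueError("thresholds must be ordered: rule_out < rule_in")
    if value <= rule_out:
        return "rule-out"
    if value >= rule_in:
        return "rule-in"
    return "gray"
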