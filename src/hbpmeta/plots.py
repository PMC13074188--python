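"""Figure rendering: SROC plane, Deeks funnel, Fagan bars, LR curves.

Vector output only; all plotting is optional and never load-bearing for
the statistics.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy.special import expit

from .bivariate import BivariateFit
from .io_model import TransformedStudy
from .sroc import compute_sroc


def plot_sroc(
    fit: BivariateFit,
    transformed: Sequence[TransformedStudy],
    path: str | Path,
) -> None:
    """SROC plane: per-study circles (area ~ sample size), curve, regions."""
    res = compute_sroc(fit)
    fig, ax = plt.subplots(figsize=(5.5, 5.5))
    fpr = [float(expit(t.y2)) for t in transformed]
    tpr = [float(expit(t.y1)) for t in transformed]
    sizes = [20 + (t.n_diseased + t.n_nondiseased) / 4 for t in transformed]
    ax.scatter(fpr, tpr, s=sizes, facecolors="none", edgecolors="steelblue", label="studies")
    ax.plot(res.curve[:, 0], res.curve[:, 1], "k-", lw=1.2, label="SROC curve")
    ax.plot(*res.summary_point, "D", color="firebrick", ms=8, label="summary point")
    ax.plot(res.confidence_region[:, 0], res.confidence_region[:, 1], "-",
            color="firebrick", lw=1, label="95% confidence region")
    ax.plot(res.prediction_region[:, 0], res.prediction_region[:, 1], "--",
            color="firebrick", lw=1, label="95% prediction region")
    ax.plot([0, 1], [0, 1], color="0.6", lw=0.8)
    ax.set(xlim=(0, 1), ylim=(0, 1), xlabel="False positive rate",
           ylabel="True positive rate (sensitivity)")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_deeks(deeks: dict, path: str | Path) -> None:
    """Deeks funnel: ln DOR against 1/sqrt(ESS) with the fitted line."""
    ess = np.asarray(deeks["ess"])
    ln_dor = np.asarray(deeks["ln_dor"])
    x = 1.0 / np.sqrt(ess)
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    ax.scatter(ln_dor, x, facecolors="none", edgecolors="steelblue")
    xx = np.linspace(x.min(), x.max(), 50)
    ax.plot(deeks["intercept"] + deeks["slope"] * xx, xx, "r--",
            label=f"slope p = {deeks['p_value']:.2f}")
    ax.invert_yaxis()
    ax.set(xlabel="ln DOR", ylabel="1 / sqrt(ESS)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_fagan(fagan: dict, path: str | Path) -> None:
    """Pre- vs post-test probability fan for the pooled LRs."""
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    for row in fagan["rows"]:
        p = row["pretest"]
        ax.plot([0, 1], [p, row["post_positive"]], "-", color="steelblue")
        ax.plot([0, 1], [p, row["post_negative"]], "--", color="firebrick")
    ax.set(xticks=[0, 1], xticklabels=["pretest", "post-test"],
           ylabel="probability", ylim=(0, 1),
           title=f"LR+ = {fagan['lr_pos']:.2f}, LR- = {fagan['lr_neg']:.3f}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_lr_curves(curves: dict, report: dict, path: str | Path) -> None:
    """LR+/LR- curves with Youden line and rule-in/rule-out markers."""
    g = np.asarray(curves["cutoff"])
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.plot(g, curves["lr_pos"], color="steelblue", label="LR+")
    ax.plot(g, curves["lr_neg"], color="firebrick", label="LR-")
    ax.axhline(report["lr_pos_target"], ls=":", color="steelblue", lw=0.8)
    ax.axhline(report["lr_neg_target"], ls=":", color="firebrick", lw=0.8)
    ax.axvline(report["youden_cutoff"], ls="--", color="seagreen",
               label=f"Youden optimum {report['youden_cutoff']:.1f}")
    for key, marker in (("rule_in_cutoff", "x"), ("rule_out_cutoff", "+")):
        if report.get(key) is not None:
            ax.axvline(report[key], color="0.4", lw=0.8)
    ax.set_yscale("log")
    ax.set(xlabel="cutoff (ng/mL)", ylabel="likelihood ratio")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
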