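"""Report assembly: run every analysis stage and serialize the results.

The pipeline executes io -> bivariate pooling -> SROC -> subgroups and
metaregression -> clinical utility (Fagan, Deeks) -> cutoff modeling, and
writes a machine-readable JSON bundle plus a subgroup-table CSV and
(optionally) figures.  Every stochastic stage records its seed so a rerun
from the emitted configuration reproduces each number exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bivariate import fit_bivariate_reml, pooled_summary
from .clinical import deeks_test, fagan_table
from .cutpoints import lr_curves, threshold_report
from .io_model import StudyDataset, read_studies, transform_dataset, write_studies
from .sroc import compute_sroc
from .subgroups import fit_subgroups, metaregression
from .synthetic import SimulationConfig, published_corpus_config, simulate_dataset

__all__ = ["RunConfig", "run_pipeline", "load_config"]

STAGES = ("fit", "sroc", "subgroups", "metareg", "utility", "cutoffs")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    input_path: str | None = None
    simulate: bool = False
    sim_config: SimulationConfig | None = None
    stages: tuple[str, ...] = STAGES
    seed: int = 0
    mc_draws: int = 100_000
    bootstrap_B: int = 1000
    lr_pos_target: float = 10.0
    lr_neg_target: float = 0.1
    pretests: tuple[float, ...] = (0.25, 0.50, 0.75)
    covariates: tuple[str, ...] = ()
    correction: float = 0.5
    out_dir: str = "results"
    plots: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.lr_neg_target < 1 < self.lr_pos_target):
            raise ValueError("need lr_neg_target < 1 < lr_pos_target, both positive")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from YAML or JSON."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    sim = raw.pop("sim_config", None)
    cfg = RunConfig(
        **{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()},
        sim_config=SimulationConfig(**sim) if sim else None,
    )
    return cfg


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _subgroup_table(results: dict[str, Any]) -> pd.DataFrame:
    rows = []
    overall = results.get("fit", {}).get("summary")
    if overall:
        rows.append(_table_row("Overall (all studies)", results["fit"]["k"],
                               results["fit"]["n_total"], overall))
    for var, res in results.get("subgroups", {}).items():
        for lv in res["levels"]:
            label = f"{var}: {lv['level']}"
            if lv["skipped"]:
                rows.append({"analysis": label, "k": lv["k"], "N": lv["n_total"],
                             "note": lv["skip_reason"]})
            else:
                rows.append(_table_row(label, lv["k"], lv["n_total"], lv["summary"]))
    return pd.DataFrame(rows)


def _table_row(label: str, k: int, n: int, s: dict) -> dict:
    return {
        "analysis": label,
        "k": k,
        "N": n,
        "sensitivity": round(s["sensitivity"], 3),
        "sens_ci": f"({s['sensitivity_ci'][0]:.3f}-{s['sensitivity_ci'][1]:.3f})",
        "specificity": round(s["specificity"], 3),
        "spec_ci": f"({s['specificity_ci'][0]:.3f}-{s['specificity_ci'][1]:.3f})",
        "lr_pos": round(s["lr_pos"], 2),
        "lr_neg": round(s["lr_neg"], 3),
        "dor": round(s["dor"], 1),
    }


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the configured stages; return (and write) the results bundle.

    Stage failures are captured in a manifest rather than aborting the whole
    run; the bundle's ``failures`` entry lists them.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    results: dict[str, Any] = {}
    failures: dict[str, str] = {}
    timings: dict[str, float] = {}

    # ---- input ----
    if config.simulate or config.input_path is None:
        sim_cfg = config.sim_config or published_corpus_config(seed=config.seed)
        sim = simulate_dataset(sim_cfg)
        dataset = sim.dataset
        results["simulation"] = {
            "config": _jsonable(sim_cfg),
            "true_sens": list(sim.true_sens),
            "true_spec": list(sim.true_spec),
        }
        write_studies(dataset, out_dir / "simulated_studies.csv")
    else:
        dataset = read_studies(config.input_path)

    results["dataset"] = {
        "k": dataset.k,
        "n_total": sum(r.n for r in dataset.records),
        "provenance": dataset.provenance,
    }
    transformed = transform_dataset(dataset, correction=config.correction)

    summary = None
    fit = None
    if "fit" in config.stages:
        t = time.time()
        try:
            fit = fit_bivariate_reml(dataset, correction=config.correction, seed=config.seed)
            summary = pooled_summary(
                fit, transformed, mc_draws=config.mc_draws, seed=config.seed
            )
            results["fit"] = {
                "k": dataset.k,
                "n_total": results["dataset"]["n_total"],
                "mu": fit.mu.tolist(),
                "sigma_between": fit.sigma_between.tolist(),
                "vcov_fixed": fit.vcov_fixed.tolist(),
                "reml_loglik": fit.loglik,
                "converged": fit.converged,
                "summary": _jsonable(summary),
            }
        except Exception as e:  # noqa: BLE001 - stage isolation is the contract
            failures["fit"] = repr(e)
        timings["fit"] = time.time() - t

    if "sroc" in config.stages and fit is not None:
        t = time.time()
        try:
            obs_fpr = [float(np.exp(s.y2) / (1 + np.exp(s.y2))) for s in transformed]
            res = compute_sroc(fit, fpr_range=(min(obs_fpr), max(obs_fpr)))
            results["sroc"] = _jsonable(res)
        except Exception as e:  # noqa: BLE001
            failures["sroc"] = repr(e)
        timings["sroc"] = time.time() - t

    if "subgroups" in config.stages and config.covariates:
        t = time.time()
        results["subgroups"] = {}
        for var in config.covariates:
            try:
                res = fit_subgroups(
                    dataset, var, mc_draws=config.mc_draws, seed=config.seed,
                    correction=config.correction,
                )
                results["subgroups"][var] = _jsonable(res)
            except Exception as e:  # noqa: BLE001
                failures[f"subgroups:{var}"] = repr(e)
        timings["subgroups"] = time.time() - t

    if "metareg" in config.stages and config.covariates:
        t = time.time()
        results["metareg"] = {}
        for var in config.covariates:
            try:
                res = metaregression(dataset, var, correction=config.correction,
                                     seed=config.seed)
                results["metareg"][var] = _jsonable(res)
            except Exception as e:  # noqa: BLE001
                failures[f"metareg:{var}"] = repr(e)
        timings["metareg"] = time.time() - t

    if "utility" in config.stages:
        t = time.time()
        try:
            if summary is not None:
                ft = fagan_table(summary, pretests=config.pretests)
                results["fagan"] = {
                    "lr_pos": ft.lr_pos,
                    "lr_neg": ft.lr_neg,
                    "rows": [
                        {
                            "pretest": r.pretest,
                            "post_positive": r.post_positive,
                            "post_negative": r.post_negative,
                            "display_percent": list(r.display),
                        }
                        for r in ft.rows
                    ],
                }
            deeks = deeks_test(dataset, correction=config.correction)
            results["deeks"] = _jsonable(deeks)
        except Exception as e:  # noqa: BLE001
            failures["utility"] = repr(e)
        timings["utility"] = time.time() - t

    if "cutoffs" in config.stages:
        t = time.time()
        n_with_cutoff = dataset.with_cutoffs().k
        if n_with_cutoff < 3:
            failures["cutoffs"] = (
                f"skipped: only {n_with_cutoff} studies carry cutoffs (need >= 3)"
            )
        else:
            try:
                report, cfit = threshold_report(
                    dataset,
                    lr_pos_target=config.lr_pos_target,
                    lr_neg_target=config.lr_neg_target,
                    B=config.bootstrap_B,
                    seed=config.seed,
                    correction=config.correction,
                )
                results["cutoffs"] = {
                    "fit": _jsonable(cfit),
                    "report": _jsonable(report),
                }
            except Exception as e:  # noqa: BLE001
                failures["cutoffs"] = repr(e)
        timings["cutoffs"] = time.time() - t

    cfg_json = json.dumps(_jsonable(config), sort_keys=True)
    bundle = {
        "package_version": __version__,
        "config": _jsonable(config),
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
        "seed": config.seed,
        "results": results,
        "failures": failures,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "elapsed_s": round(time.time() - t0, 3),
    }
    (out_dir / "report.json").write_text(json.dumps(_jsonable(bundle), indent=2))
    table = _subgroup_table(results)
    if not table.empty:
        table.to_csv(out_dir / "summary_table.csv", index=False)

    if config.plots:
        try:
            from . import plots

            if fit is not None and "sroc" in results:
                plots.plot_sroc(fit, transformed, out_dir / "sroc.svg")
            if "deeks" in results:
                plots.plot_deeks(results["deeks"], out_dir / "deeks_funnel.svg")
            if "fagan" in results:
                plots.plot_fagan(results["fagan"], out_dir / "fagan.svg")
            if "cutoffs" in results and fit is not None:
                from .cutpoints import CutpointFit

                cf = results["cutoffs"]["fit"]
                cfit2 = CutpointFit(**{
                    k: (tuple(v) if isinstance(v, list) else v) for k, v in cf.items()
                })
                plots.plot_lr_curves(
                    lr_curves(cfit2),
                    results["cutoffs"]["report"],
                    out_dir / "lr_curves.svg",
                )
        except Exception as e:  # noqa: BLE001
            failures["plots"] = repr(e)

    return bundle
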