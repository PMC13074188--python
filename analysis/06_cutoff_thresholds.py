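"""Multiple-cutoff model: Youden optimum and rule-in/rule-out thresholds.

Selects the cutoff transform by combined AIC, maximizes the Youden index
over the fitted accuracy curves (cluster-bootstrap CI), derives continuous
LR curves, extracts the LR+ >= 10 / LR- <= 0.1 decision thresholds, and
classifies a few example HBP concentrations into the resulting zones.

    python analysis/06_cutoff_thresholds.py [--seed 1] [--out results]
"""

import argparse
import json
from pathlib import Path

from hbpmeta.clinical import classify_measurement
from hbpmeta.cutpoints import lr_curves, threshold_report
from hbpmeta.io_model import read_studies
from hbpmeta.pipeline import _jsonable
from hbpmeta.plots import plot_lr_curves


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--bootstrap", type=int, default=1000)
    args = ap.parse_args()

    table = args.out / "simulated_studies.csv"
    if not table.exists():
        raise SystemExit(f"{table} not found - run analysis/01_simulate_corpus.py first")
    ds = read_studies(table)

    report, fit = threshold_report(ds, B=args.bootstrap, seed=args.seed)
    payload = {"fit": _jsonable(fit), "report": _jsonable(report)}
    (args.out / "cutoff_thresholds.json").write_text(json.dumps(payload, indent=2))
    plot_lr_curves(_jsonable(lr_curves(fit)), _jsonable(report),
                   args.out / "lr_curves.svg")

    print(f"transform selected: {fit.transform} "
          f"(AICs: { {k: round(v, 1) for k, v in fit.aic_by_transform.items()} })")
    print(f"Youden-optimal cutoff {report.youden_cutoff:.1f} ng/mL "
          f"(J = {report.youden_value:.3f}; sens {report.sens_at_opt:.3f}, "
          f"spec {report.spec_at_opt:.3f}); 95% bootstrap CI "
          f"{report.bootstrap_ci[0]:.1f}-{report.bootstrap_ci[1]:.1f} ng/mL "
          f"({report.bootstrap_failures} failed refits)")
    ri, ro = report.rule_in_cutoff, report.rule_out_cutoff
    print(f"rule-in (LR+ >= {report.lr_pos_target:g}): "
          f"{'not achieved' if ri is None else f'{ri:.1f} ng/mL'}; "
          f"rule-out (LR- <= {report.lr_neg_target:g}): "
          f"{'not achieved' if ro is None else f'{ro:.1f} ng/mL'}")
    if ri is not None and ro is not None:
        print(f"gray zone: {ro:.1f}-{ri:.1f} ng/mL")
        for value in (0.8 * ro, 0.5 * (ro + ri), 1.2 * ri):
            zone = classify_measurement(value, rule_out=ro, rule_in=ri)
            print(f"  HBP {value:.1f} ng/mL -> {zone}")


if __name__ == "__main__":
    main()
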