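"""Clinical utility: Fagan post-test updating and Deeks' asymmetry test.

    python analysis/05_clinical_utility.py [--seed 1] [--out results]
"""

import argparse
import json
from pathlib import Path

from hbpmeta.bivariate import fit_bivariate_reml, pooled_summary
from hbpmeta.clinical import deeks_test, fagan_table, round_percent
from hbpmeta.io_model import read_studies, transform_dataset
from hbpmeta.pipeline import _jsonable
from hbpmeta.plots import plot_deeks, plot_fagan


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    table = args.out / "simulated_studies.csv"
    if not table.exists():
        raise SystemExit(f"{table} not found - run analysis/01_simulate_corpus.py first")
    ds = read_studies(table)
    fit = fit_bivariate_reml(ds, seed=args.seed)
    summary = pooled_summary(fit, transform_dataset(ds), seed=args.seed)

    fagan = fagan_table(summary)
    deeks = deeks_test(ds)
    payload = {"fagan": _jsonable(fagan), "deeks": _jsonable(deeks)}
    (args.out / "clinical_utility.json").write_text(json.dumps(payload, indent=2))
    plot_fagan({"rows": [{"pretest": r.pretest, "post_positive": r.post_positive,
                          "post_negative": r.post_negative} for r in fagan.rows],
                "lr_pos": fagan.lr_pos, "lr_neg": fagan.lr_neg},
               args.out / "fagan.svg")
    plot_deeks(_jsonable(deeks), args.out / "deeks_funnel.svg")

    print(f"pooled LR+ {fagan.lr_pos:.2f}, LR- {fagan.lr_neg:.3f}")
    for r in fagan.rows:
        print(f"  pretest {round_percent(r.pretest)}%: positive result -> "
              f"{round_percent(r.post_positive)}%, negative -> "
              f"{round_percent(r.post_negative)}%")
    print(f"Deeks funnel asymmetry: slope {deeks.slope:.2f} "
          f"(p = {deeks.p_value:.2f}; alpha 0.10) -> "
          f"{'asymmetry flagged' if deeks.asymmetry else 'no evidence of small-study bias'}")


if __name__ == "__main__":
    main()
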