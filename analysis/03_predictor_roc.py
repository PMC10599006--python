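#!/usr/bin/env python
"""Score every single predictor by ROC at 100% specificity.

For GWR, mean whole-brain ADC and each ADC-PercentValue threshold:
DeLong AUC with CI, the FPR-0 cutoff, confusion counts, diagnostic metrics
with exact CIs, and the paired DeLong comparison against GWR as the
reference predictor.  Writes the report table and prints the headline rows.
"""

import json
from pathlib import Path

import pandas as pd

from neuroadc import CohortConfig, run_pipeline

OUTDIR = Path(__file__).resolve().parents[1] / "results" / "run"


def main() -> None:
    if not (OUTDIR / "adc_metrics.csv").exists():
        raise SystemExit("run analysis/02_quantify_adc.py first")
    run_pipeline(CohortConfig(), OUTDIR, stages=("analyze",))
    report = pd.read_csv(OUTDIR / "predictor_report.csv")
    print(f"predictor report -> {OUTDIR / 'predictor_report.csv'}")
    cols = ["predictor", "cutoff", "auc", "band", "sensitivity", "specificity"]
    show = report[report.predictor.isin(["gwr", "mean_whole_brain_adc", "pv_600"])]
    print(show[cols].to_string(index=False))
    full = json.loads((OUTDIR / "predictor_report.json").read_text())
    best = max(full["predictors"].items(), key=lambda kv: kv[1]["auc"])
    print(f"best single predictor: {best[0]} (AUC {best[1]['auc']:.2f}, "
          f"{best[1]['band']})")


if __name__ == "__main__":
    main()
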