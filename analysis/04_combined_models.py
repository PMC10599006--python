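#!/usr/bin/env python
"""Fit and compare the combined prognostic models.

Backward-selected logistic models over PLR absence + serum NSE, alone and
augmented with one imaging metric (mean whole-brain ADC, ADC-PercentValue
600 or 650); each model's linear predictor is scored by ROC at 100%
specificity and compared with the clinical baseline by the paired DeLong
test.
"""

import json
from pathlib import Path

import pandas as pd

from neuroadc import CohortConfig, run_pipeline

OUTDIR = Path(__file__).resolve().parents[1] / "results" / "run"


def main() -> None:
    if not (OUTDIR / "adc_metrics.csv").exists():
        raise SystemExit("run analysis/02_quantify_adc.py first")
    run_pipeline(CohortConfig(), OUTDIR, stages=("report",))
    report = pd.read_csv(OUTDIR / "model_report.csv")
    print(f"model report -> {OUTDIR / 'model_report.csv'}")
    print(report.to_string(index=False))
    full = json.loads((OUTDIR / "model_report.json").read_text())
    screen = full["univariable_screen"]
    print(f"univariable screen (P<{screen['alpha_in']}):",
          ", ".join(screen["selected"]) or "none")
    if full.get("model_flags"):
        print("flagged models:", full["model_flags"])


if __name__ == "__main__":
    main()
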