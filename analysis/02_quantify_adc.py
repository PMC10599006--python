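#!/usr/bin/env python
"""Quantify every patient's ADC volume.

Reads the NIfTI volumes written by 01_simulate_cohort.py, computes the
mean whole-brain ADC and the ADC-PercentValue sweep (250..1150 step 50)
per patient, and summarises the group medians — the quantity whose
published interquartile bands the generator is calibrated against.
"""

from pathlib import Path

import pandas as pd

from neuroadc import CohortConfig, run_pipeline

OUTDIR = Path(__file__).resolve().parents[1] / "results" / "run"


def main() -> None:
    if not (OUTDIR / "volumes").exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    run_pipeline(CohortConfig(), OUTDIR, stages=("quantify",))
    metrics = pd.read_csv(OUTDIR / "adc_metrics.csv")
    cov = pd.read_csv(OUTDIR / "cohort_covariates.csv")
    table = cov.merge(metrics, on="patient_id")
    med = table.groupby("outcome")["mean_whole_brain_adc"].median()
    print(f"quantified {len(metrics)} patients -> {OUTDIR / 'adc_metrics.csv'}")
    print("median mean whole-brain ADC (x10^-6 mm^2/s):")
    print(f"  good outcome: {med['good']:.1f}   poor outcome: {med['poor']:.1f}")
    pv600 = table.groupby("outcome")["pv_600"].median()
    print(f"median %voxels with ADC <= 600: good {pv600['good']:.1f}%, "
          f"poor {pv600['poor']:.1f}%")


if __name__ == "__main__":
    main()
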