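"""Pipeline orchestration: simulate -> quantify -> analyze -> report.

Each stage is a pure function of its declared on-disk inputs, so any stage
can be re-run in isolation from the previous stage's outputs.  A run
manifest (config snapshot, seed, per-file SHA-256 digests, timestamps) is
written last so a run is auditable and byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .adc import DEFAULT_THRESHOLDS, ADCVolume, compute_metrics
from .cohort import CohortConfig, generate_cohort, write_cohort
from .gwr import add_gwr_column
from .stats import (
    HIGHER_IS_POOR,
    LOWER_IS_POOR,
    PredictorSeries,
    SeparationError,
    analyze_predictor,
    combined_model_roc,
    delong_paired_test,
    fit_multivariable_backward,
    univariable_screen,
)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _metric_cell(m) -> str:
    if m is None:
        return ""
    return f"{m.estimate:.0f} ({m.ci_low:.0f}-{m.ci_high:.0f})"


# ----------------------------------------------------------------- stages


def stage_simulate(config: CohortConfig, outdir: Path) -> list[Path]:
    """Generate the synthetic cohort and write volumes + covariates + config."""
    patients = generate_cohort(config)
    paths = write_cohort(patients, config, outdir)
    out = [paths["covariates"], paths["config"]]
    out += sorted(paths["volumes"].glob("*.nii.gz"))
    return out


def stage_quantify(
    outdir: Path,
    thresholds: tuple[int, ...] = DEFAULT_THRESHOLDS,
    boundary: str = "le",
) -> list[Path]:
    """Read each patient's NIfTI volume+mask and write the per-patient
    imaging metrics table (CSV) and a JSON provenance record."""
    voldir = Path(outdir) / "volumes"
    adc_files = sorted(voldir.glob("*_adc.nii.gz"))
    if not adc_files:
        raise StageError("quantify: no ADC volumes found under volumes/")
    rows = []
    for adc_path in adc_files:
        pid = adc_path.name.replace("_adc.nii.gz", "")
        mask_path = voldir / f"{pid}_mask.nii.gz"
        volume = ADCVolume.from_nifti(adc_path, mask_path if mask_path.exists() else None)
        metrics = compute_metrics(volume, thresholds=thresholds, boundary=boundary,
                                  allow_rule_based=not mask_path.exists())
        row = {"patient_id": pid, "mean_whole_brain_adc": metrics.mean_whole_brain_adc}
        row.update({f"pv_{t}": v for t, v in metrics.percent_below.items()})
        rows.append(row)
    table = pd.DataFrame(rows)
    metrics_path = Path(outdir) / "adc_metrics.csv"
    table.to_csv(metrics_path, index=False, float_format="%.6f")
    prov_path = Path(outdir) / "adc_metrics_provenance.json"
    prov_path.write_text(json.dumps({
        "thresholds": list(thresholds),
        "boundary": boundary,
        "window": [200.0, 2000.0],
        "n_patients": len(rows),
    }, indent=2))
    return [metrics_path, prov_path]


def _load_analysis_table(outdir: Path) -> pd.DataFrame:
    cov = pd.read_csv(Path(outdir) / "cohort_covariates.csv")
    metrics = pd.read_csv(Path(outdir) / "adc_metrics.csv")
    table = cov.merge(metrics, on="patient_id", validate="one_to_one")
    return add_gwr_column(table)


def stage_analyze(outdir: Path, reference: str = "gwr") -> list[Path]:
    """Single-predictor ROC report: one row per predictor (GWR, mean
    whole-brain ADC, each ADC-PercentValue threshold) with the FPR-0
    cutoff, AUC and CI, diagnostic metrics with exact CIs, confusion
    counts, and the paired DeLong p-value against the reference predictor."""
    table = _load_analysis_table(Path(outdir))
    outcomes = table["outcome"].to_numpy()
    predictors = [PredictorSeries(table["gwr"], LOWER_IS_POOR, "gwr"),
                  PredictorSeries(table["mean_whole_brain_adc"], LOWER_IS_POOR,
                                  "mean_whole_brain_adc")]
    predictors += [
        PredictorSeries(table[c], HIGHER_IS_POOR, c)
        for c in table.columns if c.startswith("pv_")
    ]
    by_name = {p.name: p for p in predictors}
    if reference not in by_name:
        raise StageError(f"analyze: unknown reference predictor {reference!r}")
    rows, full = [], {}
    for series in predictors:
        roc = analyze_predictor(series, outcomes)
        if series.name == reference:
            p_cmp = None
        else:
            p_cmp = delong_paired_test(series, by_name[reference], outcomes).p_value
        m = roc.metrics
        rows.append({
            "predictor": series.name,
            "cutoff": roc.cutoff.label,
            "auc": round(roc.auc, 2),
            "auc_ci": f"{roc.auc_ci[0]:.2f}-{roc.auc_ci[1]:.2f}",
            "band": roc.band,
            "sensitivity": _metric_cell(m["sensitivity"]),
            "specificity": _metric_cell(m["specificity"]),
            "ppv": _metric_cell(m["ppv"]),
            "npv": _metric_cell(m["npv"]),
            "tp": roc.cutoff.confusion.tp, "fp": roc.cutoff.confusion.fp,
            "tn": roc.cutoff.confusion.tn, "fn": roc.cutoff.confusion.fn,
            "delong_p_vs_reference": "" if p_cmp is None else f"{p_cmp:.4f}",
        })
        full[series.name] = {
            "auc": roc.auc, "auc_se": roc.auc_se, "auc_ci": list(roc.auc_ci),
            "cutoff": roc.cutoff.cutoff, "operator": roc.cutoff.operator,
            "degenerate_cutoff": roc.cutoff.degenerate,
            "confusion": dataclasses.asdict(roc.cutoff.confusion),
            "metrics": {k: (None if v is None else dataclasses.asdict(v))
                        for k, v in m.items()},
            "band": roc.band,
            "delong_p_vs_reference": p_cmp,
        }
    report_path = Path(outdir) / "predictor_report.csv"
    pd.DataFrame(rows).to_csv(report_path, index=False)
    json_path = Path(outdir) / "predictor_report.json"
    json_path.write_text(json.dumps({"reference": reference, "predictors": full}, indent=2))
    return [report_path, json_path]


#: the four combined prediction models scored against each other: a
#: clinical baseline (PLR + NSE) and the baseline plus one imaging metric
COMBINED_MODELS = {
    "plr_nse": ["plr_absent", "nse_ng_ml"],
    "plr_nse_mean_adc": ["plr_absent", "nse_ng_ml", "mean_whole_brain_adc"],
    "plr_nse_pv600": ["plr_absent", "nse_ng_ml", "pv_600"],
    "plr_nse_pv650": ["plr_absent", "nse_ng_ml", "pv_650"],
}


def stage_report(outdir: Path, alpha_in: float = 0.1, alpha_out: float = 0.05) -> list[Path]:
    """Combined-model report: univariable screen, backward-selected
    multivariable logistic models, odds ratios with CIs, and the ROC of
    each model's linear predictor, plus the paired DeLong comparison of the
    imaging-augmented models against the clinical baseline."""
    table = _load_analysis_table(Path(outdir))
    table["plr_absent"] = 1 - table["plr_present"]
    outcomes = table["outcome"].to_numpy()

    screen_cols = [c for c in ("plr_absent", "nse_ng_ml", "gwr", "mean_whole_brain_adc")
                   if c in table.columns]
    selected, flags = univariable_screen(table[screen_cols], outcomes, alpha_in=alpha_in)

    models, rocs, model_flags = {}, {}, {}
    for name, terms in COMBINED_MODELS.items():
        missing = [t for t in terms if t not in table.columns]
        if missing:
            continue
        try:
            model = fit_multivariable_backward(table[terms], outcomes, alpha_out=alpha_out)
        except SeparationError:
            # small cohorts can be perfectly separated by a strong
            # predictor; report the flag instead of a spurious fit
            model_flags[name] = "separation"
            continue
        models[name] = model
        rocs[name] = combined_model_roc(model, outcomes, name=name)

    baseline = "plr_nse"
    report = {"univariable_screen": {"alpha_in": alpha_in, "selected": selected,
                                     "flags": flags},
              "alpha_out": alpha_out, "model_flags": model_flags, "models": {}}
    rows = []
    for name, model in models.items():
        roc = rocs[name]
        if name != baseline and baseline in models:
            cmp_p = delong_paired_test(
                PredictorSeries(model.linear_predictor, HIGHER_IS_POOR, name),
                PredictorSeries(models[baseline].linear_predictor, HIGHER_IS_POOR, baseline),
                outcomes,
            ).p_value
        else:
            cmp_p = None
        sens = roc.metrics["sensitivity"]
        report["models"][name] = {
            "terms": model.terms,
            "eliminated": model.eliminated,
            "odds_ratios": {t: {"or": model.odds_ratios[t], "ci": list(model.or_ci[t]),
                                "p": model.p_values[t]} for t in model.terms},
            "auc": roc.auc, "auc_ci": list(roc.auc_ci), "band": roc.band,
            "sensitivity_at_fpr0": None if sens is None else sens.estimate,
            "delong_p_vs_baseline": cmp_p,
        }
        rows.append({
            "model": name, "terms": "+".join(model.terms) or "(intercept)",
            "auc": round(roc.auc, 2),
            "auc_ci": f"{roc.auc_ci[0]:.2f}-{roc.auc_ci[1]:.2f}",
            "sensitivity_at_fpr0": _metric_cell(sens),
            "delong_p_vs_baseline": "" if cmp_p is None else f"{cmp_p:.4f}",
        })
    model_csv = Path(outdir) / "model_report.csv"
    pd.DataFrame(rows).to_csv(model_csv, index=False)
    model_json = Path(outdir) / "model_report.json"
    model_json.write_text(json.dumps(report, indent=2, default=float))
    return [model_csv, model_json]


STAGES = ("simulate", "quantify", "analyze", "report")


def run_pipeline(
    config: CohortConfig | str | Path,
    outdir,
    stages: tuple[str, ...] = STAGES,
    seed: int | None = None,
    boundary: str = "le",
    thresholds: tuple[int, ...] = DEFAULT_THRESHOLDS,
) -> dict:
    """Run the requested stages in order and write the run manifest.

    ``config`` may be a CohortConfig or a path to its YAML form; ``seed``
    overrides the config seed.  Returns the manifest dict (also written to
    ``outdir/manifest.json``).  A stage failure raises StageError naming
    the stage; outputs of completed stages are preserved.
    """
    if not isinstance(config, CohortConfig):
        config = CohortConfig.load(config)
    if seed is not None:
        config = dataclasses.replace(config, seed=int(seed))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise StageError(f"unknown stages: {unknown}")

    manifest = {
        "tool": "neuroadc",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "boundary": boundary,
        "thresholds": list(thresholds),
        "stages": {},
    }
    for stage in STAGES:
        if stage not in stages:
            continue
        t0 = time.time()
        try:
            if stage == "simulate":
                outputs = stage_simulate(config, outdir)
            elif stage == "quantify":
                outputs = stage_quantify(outdir, thresholds=thresholds, boundary=boundary)
            elif stage == "analyze":
                outputs = stage_analyze(outdir)
            else:
                outputs = stage_report(outdir)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {
            "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in outputs},
            "elapsed_s": round(time.time() - t0, 3),
        }
    manifest["completed_at"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return manifest
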