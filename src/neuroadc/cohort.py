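"""Synthetic cohort generator: ADC phantom volumes plus clinical covariates.

Emulates the statistical structure of an early post-cardiac-arrest cohort
dichotomised into good (CPC 1-2) and poor (CPC 3-5) neurological outcome:

* an ellipsoidal three-compartment brain phantom (parenchyma / interior CSF
  / extracranial background) per patient, with a single contiguous low-ADC
  lesion occupying an outcome-dependent fraction of the parenchyma;
* pupillary light reflex (Bernoulli per group), log-normal serum NSE, and
  CT region-of-interest attenuations calibrated so the grey/white-matter
  ratio has the configured group medians.

Covariates are conditionally independent given the outcome; predictors are
coupled only through the outcome label, which is how the downstream
logistic combination models them.  Default calibration targets group
medians near 788 vs 739 x10^-6 mm^2/s for mean whole-brain ADC, PLR
presence 88% vs 38%, NSE medians 23.8 vs 44.0 ng/ml and GWR medians
1.27 vs 1.21.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .adc import LABEL_CSF, LABEL_EXTRACRANIAL, LABEL_PARENCHYMA, ADCVolume

GOOD = "good"
POOR = "poor"


class CohortConfigError(ValueError):
    """Raised for non-finite or out-of-range configuration values; the
    message names the offending field."""


@dataclass
class GroupROIParams:
    """Mean/sd of CT ROI attenuations (HU) for one outcome group."""

    mean_p: float
    mean_cn: float
    mean_pic: float
    mean_cc: float
    sd: float = 1.2


@dataclass
class CohortConfig:
    """Full specification of a synthetic cohort.

    ADC quantities are in 10^-6 mm^2/s.  Lesion-fraction distributions are
    Beta(a, b) on [0, 1]: the poor group is skewed toward substantial
    lesion loads, the good group is concentrated near zero.  The CSF mean
    sits above 2000 so CSF voxels self-exclude under the fluid/artefact
    filter even when a mask is not applied.
    """

    n_patients: int = 131
    prevalence_poor: float = 74 / 131
    seed: int = 20231025
    volume_shape: tuple[int, int, int] = (48, 48, 36)
    voxel_size_mm: tuple[float, float, float] = (3.6, 3.6, 4.0)
    parenchyma_adc_mean_good: float = 790.0
    parenchyma_adc_mean_poor: float = 785.0
    parenchyma_adc_sd: float = 90.0
    lesion_fraction_dist_good: tuple[float, float] = (1.0, 60.0)
    lesion_fraction_dist_poor: tuple[float, float] = (2.0, 10.0)
    lesion_adc_mean: float = 450.0
    csf_adc_mean: float = 2600.0
    csf_fraction: float = 0.04
    plr_present_prob_good: float = 0.88
    plr_present_prob_poor: float = 0.38
    nse_logmean_good: float = math.log(23.8)
    nse_logmean_poor: float = math.log(44.0)
    nse_logsd: float = 0.5
    gwr_roi_params: dict[str, GroupROIParams] = field(
        default_factory=lambda: {
            GOOD: GroupROIParams(35.0, 35.0, 27.5, 27.5),
            POOR: GroupROIParams(33.3, 33.3, 27.5, 27.5),
        }
    )

    def validate(self) -> None:
        def _finite(name, value):
            if not np.all(np.isfinite(value)):
                raise CohortConfigError(f"{name} must be finite, got {value!r}")

        if self.n_patients < 1:
            raise CohortConfigError(f"n_patients must be >= 1, got {self.n_patients}")
        for name in ("prevalence_poor", "plr_present_prob_good", "plr_present_prob_poor"):
            p = getattr(self, name)
            _finite(name, p)
            if not 0.0 <= p <= 1.0:
                raise CohortConfigError(f"{name} must be in [0, 1], got {p}")
        if len(self.volume_shape) != 3 or any(int(s) < 4 for s in self.volume_shape):
            raise CohortConfigError(f"volume_shape must be 3 ints >= 4, got {self.volume_shape}")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise CohortConfigError(f"voxel_size_mm must be positive, got {self.voxel_size_mm}")
        for name in (
            "parenchyma_adc_mean_good",
            "parenchyma_adc_mean_poor",
            "parenchyma_adc_sd",
            "lesion_adc_mean",
            "csf_adc_mean",
            "nse_logsd",
        ):
            v = getattr(self, name)
            _finite(name, v)
            if name != "nse_logsd" and v < 0:
                raise CohortConfigError(f"{name} must be non-negative, got {v}")
        _finite("nse_logmean_good", self.nse_logmean_good)
        _finite("nse_logmean_poor", self.nse_logmean_poor)
        if self.csf_adc_mean <= 2000:
            raise CohortConfigError(
                f"csf_adc_mean must exceed 2000 so CSF self-excludes, got {self.csf_adc_mean}"
            )
        if self.lesion_adc_mean >= min(
            self.parenchyma_adc_mean_good, self.parenchyma_adc_mean_poor
        ):
            raise CohortConfigError(
                "lesion_adc_mean must be below both parenchyma means, got "
                f"{self.lesion_adc_mean}"
            )
        if not 0.0 <= self.csf_fraction < 0.5:
            raise CohortConfigError(f"csf_fraction must be in [0, 0.5), got {self.csf_fraction}")
        for name in ("lesion_fraction_dist_good", "lesion_fraction_dist_poor"):
            a, b = getattr(self, name)
            _finite(name, [a, b])
            if a <= 0 or b <= 0:
                raise CohortConfigError(f"{name} Beta parameters must be positive, got {(a, b)}")

    # ------------------------------------------------------------- helpers
    def parenchyma_mean(self, outcome: str) -> float:
        return (
            self.parenchyma_adc_mean_good if outcome == GOOD else self.parenchyma_adc_mean_poor
        )

    def lesion_fraction_params(self, outcome: str) -> tuple[float, float]:
        return (
            self.lesion_fraction_dist_good if outcome == GOOD else self.lesion_fraction_dist_poor
        )

    def expected_mean_adc(self, outcome: str) -> float:
        """Closed-form expectation of the noise-free mixture mean ADC:
        (1 - E[f]) * parenchyma_mean + E[f] * lesion_mean with
        E[f] = a / (a + b) for the group's Beta lesion-fraction law."""
        a, b = self.lesion_fraction_params(outcome)
        ef = a / (a + b)
        return (1.0 - ef) * self.parenchyma_mean(outcome) + ef * self.lesion_adc_mean

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gwr_roi_params"] = {k: dataclasses.asdict(v) for k, v in self.gwr_roi_params.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "gwr_roi_params" in d:
            d["gwr_roi_params"] = {
                k: GroupROIParams(**v) if isinstance(v, dict) else v
                for k, v in d["gwr_roi_params"].items()
            }
        for key in ("volume_shape", "voxel_size_mm", "lesion_fraction_dist_good",
                    "lesion_fraction_dist_poor"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "CohortConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class PatientTruth:
    """Ground-truth record for one synthetic patient (recovery tests)."""

    patient_id: str
    outcome: str
    lesion_fraction: float
    plr_present: bool
    nse_ng_ml: float
    roi_hu: dict[str, float]


@dataclass
class Patient:
    truth: PatientTruth
    volume: ADCVolume

    @property
    def patient_id(self) -> str:
        return self.truth.patient_id


def _brain_geometry(config: CohortConfig) -> tuple[np.ndarray, np.ndarray]:
    """Shared phantom geometry: mask labels and parenchyma voxel coordinates.

    An ellipsoidal brain filling ~84% of each half-extent, with two
    ventricle-like interior CSF ellipsoids.  Geometry is identical across
    patients; only intensities and the lesion differ.
    """
    shape = tuple(int(s) for s in config.volume_shape)
    zyx = np.indices(shape, dtype=float)
    center = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    semi = 0.42 * np.asarray(shape, dtype=float)
    norm = sum(((zyx[i] - center[i]) / semi[i]) ** 2 for i in range(3))
    brain = norm <= 1.0

    mask = np.full(shape, LABEL_EXTRACRANIAL, dtype=int)
    mask[brain] = LABEL_PARENCHYMA

    if config.csf_fraction > 0:
        # two lateral-ventricle-like ellipsoids, scaled to csf_fraction of brain
        scale = (config.csf_fraction / 2.0) ** (1.0 / 3.0)
        for side in (-1.0, 1.0):
            c = center + np.array([0.0, side * 0.18 * shape[1], 0.0])
            s = semi * scale * np.array([1.2, 0.8, 1.0])
            n = sum(((zyx[i] - c[i]) / s[i]) ** 2 for i in range(3))
            mask[(n <= 1.0) & brain] = LABEL_CSF

    par_coords = np.argwhere(mask == LABEL_PARENCHYMA)
    return mask, par_coords


def _carve_lesion(
    mask: np.ndarray,
    par_coords: np.ndarray,
    lesion_fraction: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Boolean lesion map: the ``lesion_fraction`` of parenchymal voxels
    nearest (Euclidean, in voxel index space) to a random parenchymal seed
    voxel — a contiguous, roughly spherical region clipped at the brain
    boundary."""
    lesion = np.zeros(mask.shape, dtype=bool)
    n_lesion = int(round(lesion_fraction * len(par_coords)))
    if n_lesion == 0:
        return lesion
    seed_idx = rng.integers(len(par_coords))
    d2 = ((par_coords - par_coords[seed_idx]) ** 2).sum(axis=1)
    chosen = par_coords[np.argsort(d2, kind="stable")[:n_lesion]]
    lesion[tuple(chosen.T)] = True
    return lesion


def generate_volume(
    outcome: str,
    lesion_fraction: float,
    config: CohortConfig,
    rng: np.random.Generator,
    geometry: tuple[np.ndarray, np.ndarray] | None = None,
) -> ADCVolume:
    """One patient's ADC phantom: parenchyma at the group mean, CSF above
    2000, contiguous lesion at the lesion mean, additive Gaussian voxel
    noise truncated at zero, and an exact tissue-label mask."""
    if geometry is None:
        geometry = _brain_geometry(config)
    mask, par_coords = geometry
    values = np.zeros(mask.shape, dtype=float)
    values[mask == LABEL_PARENCHYMA] = config.parenchyma_mean(outcome)
    values[mask == LABEL_CSF] = config.csf_adc_mean
    lesion = _carve_lesion(mask, par_coords, lesion_fraction, rng)
    values[lesion] = config.lesion_adc_mean
    values += rng.normal(0.0, config.parenchyma_adc_sd, size=values.shape)
    np.clip(values, 0.0, None, out=values)
    return ADCVolume(values=values, voxel_size_mm=tuple(config.voxel_size_mm), mask=mask.copy())


def generate_covariates(
    outcome: str, config: CohortConfig, rng: np.random.Generator
) -> tuple[bool, float, dict[str, float]]:
    """Clinical covariates for one patient: PLR presence, serum NSE (ng/ml,
    log-normal so the group median is exp(log-mean)), and the four CT ROI
    attenuations (HU) whose ratio forms the GWR."""
    if outcome not in (GOOD, POOR):
        raise CohortConfigError(f"outcome must be 'good' or 'poor', got {outcome!r}")
    p_plr = (
        config.plr_present_prob_good if outcome == GOOD else config.plr_present_prob_poor
    )
    plr_present = bool(rng.random() < p_plr)
    logmean = config.nse_logmean_good if outcome == GOOD else config.nse_logmean_poor
    nse = float(np.exp(rng.normal(logmean, config.nse_logsd)))
    roi = config.gwr_roi_params[outcome]
    roi_hu = {
        "hu_p": float(rng.normal(roi.mean_p, roi.sd)),
        "hu_cn": float(rng.normal(roi.mean_cn, roi.sd)),
        "hu_pic": float(rng.normal(roi.mean_pic, roi.sd)),
        "hu_cc": float(rng.normal(roi.mean_cc, roi.sd)),
    }
    return plr_present, nse, roi_hu


def generate_cohort(config: CohortConfig) -> list[Patient]:
    """Generate the full synthetic cohort, reproducibly from ``config.seed``.

    Outcomes are Bernoulli(prevalence_poor) per patient; each patient gets
    an ADC phantom volume plus clinical covariates drawn conditionally on
    the outcome.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    geometry = _brain_geometry(config)
    patients: list[Patient] = []
    for i in range(config.n_patients):
        outcome = POOR if rng.random() < config.prevalence_poor else GOOD
        a, b = config.lesion_fraction_params(outcome)
        lesion_fraction = float(rng.beta(a, b))
        volume = generate_volume(outcome, lesion_fraction, config, rng, geometry)
        plr, nse, roi_hu = generate_covariates(outcome, config, rng)
        truth = PatientTruth(
            patient_id=f"P{i:04d}",
            outcome=outcome,
            lesion_fraction=lesion_fraction,
            plr_present=plr,
            nse_ng_ml=nse,
            roi_hu=roi_hu,
        )
        patients.append(Patient(truth=truth, volume=volume))
    return patients


def covariate_table(patients: list[Patient]) -> pd.DataFrame:
    """Cohort covariate table, one row per patient."""
    rows = []
    for p in patients:
        t = p.truth
        rows.append(
            {
                "patient_id": t.patient_id,
                "outcome": t.outcome,
                "plr_present": int(t.plr_present),
                "nse_ng_ml": t.nse_ng_ml,
                **t.roi_hu,
            }
        )
    return pd.DataFrame(rows)


def write_cohort(patients: list[Patient], config: CohortConfig, outdir) -> dict[str, Path]:
    """Write NIfTI volumes+masks, the covariate table (CSV) and the config
    (YAML, seed included) to ``outdir``; returns the paths written."""
    outdir = Path(outdir)
    voldir = outdir / "volumes"
    voldir.mkdir(parents=True, exist_ok=True)
    for p in patients:
        p.volume.to_nifti(
            voldir / f"{p.patient_id}_adc.nii.gz",
            mask_path=voldir / f"{p.patient_id}_mask.nii.gz",
        )
    table_path = outdir / "cohort_covariates.csv"
    covariate_table(patients).to_csv(table_path, index=False)
    config_path = outdir / "cohort_config.yaml"
    config.save(config_path)
    return {"volumes": voldir, "covariates": table_path, "config": config_path}
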