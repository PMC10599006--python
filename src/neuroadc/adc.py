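"""Voxel-based quantification of apparent-diffusion-coefficient (ADC) maps.

The imaging predictors computed here are the ones used for early
neuroprognostication after cardiac arrest: the mean whole-brain ADC and the
ADC-PercentValue — the percentage of parenchymal voxels whose ADC
(in 10^-6 mm^2/s) lies between 200 and a sweep of thresholds, relative to
all voxels in the 200–2000 analysis window.  Voxels above 2000 are excluded
up front to suppress CSF, artefact and noise contributions.

All metrics are voxel-count based: anisotropic voxels are not resampled and
no volume weighting is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

try:  # nibabel is only needed for file I/O
    import nibabel as nib
except ImportError:  # pragma: no cover
    nib = None

# mask label conventions
LABEL_EXTRACRANIAL = 0
LABEL_PARENCHYMA = 1
LABEL_CSF = 2

#: analysis window in 10^-6 mm^2/s; values above the upper edge are treated
#: as fluid/artefact and removed before any metric is computed
ADC_WINDOW = (200.0, 2000.0)

#: threshold sweep grid in 10^-6 mm^2/s.  Thresholds are stepped by 50 from
#: 200 to 1200, but the reported grid starts at 250 (a 200 threshold counts
#: only exact-200 voxels and is degenerate) and ends at 1150.
DEFAULT_THRESHOLDS = tuple(range(250, 1200, 50))


class InputError(ValueError):
    """Raised when an input violates an operation's contract."""


class DegenerateInputError(InputError):
    """Raised when exclusions leave nothing to compute a metric from."""


@dataclass
class ADCVolume:
    """A 3-D ADC map with voxel geometry and an optional tissue-label mask.

    Parameters
    ----------
    values
        3-D array of ADC values in 10^-6 mm^2/s; finite and non-negative.
    voxel_size_mm
        Physical voxel edge lengths (mm).
    mask
        Optional integer label volume, same shape as ``values``, with
        0 = extracranial, 1 = brain parenchyma, 2 = CSF.
    """

    values: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise InputError("values must be a 3-D array")
        if not np.all(np.isfinite(self.values)):
            raise InputError("ADC values must be finite")
        if np.any(self.values < 0):
            raise InputError("ADC values must be non-negative")
        if len(self.voxel_size_mm) != 3 or any(s <= 0 for s in self.voxel_size_mm):
            raise InputError("voxel_size_mm must be three positive reals")
        if self.mask is not None:
            self.mask = np.asarray(self.mask)
            if self.mask.shape != self.values.shape:
                raise InputError("mask shape must match values shape")

    # ------------------------------------------------------------------ I/O
    def to_nifti(self, path, mask_path=None) -> None:
        """Write the ADC values (and mask, if any) as NIfTI files."""
        affine = np.diag(list(self.voxel_size_mm) + [1.0])
        nib.save(nib.Nifti1Image(self.values.astype(np.float32), affine), str(path))
        if mask_path is not None and self.mask is not None:
            nib.save(
                nib.Nifti1Image(self.mask.astype(np.int16), affine), str(mask_path)
            )

    @classmethod
    def from_nifti(cls, path, mask_path=None) -> "ADCVolume":
        img = nib.load(str(path))
        values = np.asarray(img.dataobj, dtype=float)
        voxel = tuple(float(z) for z in img.header.get_zooms()[:3])
        mask = None
        if mask_path is not None:
            mask = np.asarray(nib.load(str(mask_path)).dataobj).astype(int)
        return cls(values=values, voxel_size_mm=voxel, mask=mask)


@dataclass
class VoxelSample:
    """Parenchymal ADC values after exclusions.

    ``adc_values`` holds every retained parenchymal value (all <= 2000);
    ``n_total_in_denominator`` counts the subset inside the closed
    [200, 2000] analysis window — the denominator of every
    ADC-PercentValue.  Bookkeeping counts of what was removed are kept so
    that retained + excluded + non-parenchyma = total.
    """

    adc_values: np.ndarray
    n_total_in_denominator: int
    n_excluded_high: int = 0
    n_non_parenchyma: int = 0

    def __post_init__(self) -> None:
        self.adc_values = np.asarray(self.adc_values, dtype=float).ravel()

    @property
    def n_retained(self) -> int:
        return int(self.adc_values.size)


@dataclass
class ADCMetrics:
    """Per-patient imaging predictors: mean whole-brain ADC and the
    percentage of voxels below each threshold on the sweep grid."""

    mean_whole_brain_adc: float
    percent_below: dict[int, float]
    n_denominator: int = 0
    boundary: str = "le"
    window: tuple[float, float] = ADC_WINDOW
    thresholds: tuple[int, ...] = field(default_factory=lambda: DEFAULT_THRESHOLDS)


def rule_based_mask(
    values: np.ndarray,
    tissue_range: tuple[float, float] = (200.0, 1500.0),
    closing_iterations: int = 2,
) -> np.ndarray:
    """Fallback parenchyma masker for volumes shipped without a mask.

    Keeps the largest connected component of voxels in a plausible tissue
    intensity range and closes small holes morphologically.  This is a
    deliberately simple stand-in for a semi-automatic skull-stripping
    workflow; volumes from the synthetic cohort carry an exact mask and do
    not use it.
    """
    from scipy import ndimage

    candidate = (values >= tissue_range[0]) & (values <= tissue_range[1])
    labels, n = ndimage.label(candidate)
    if n == 0:
        raise DegenerateInputError("no voxels in the plausible tissue range")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    largest = 1 + int(np.argmax(sizes))
    brain = labels == largest
    if closing_iterations:
        brain = ndimage.binary_closing(brain, iterations=closing_iterations)
    mask = np.zeros(values.shape, dtype=int)
    mask[brain] = LABEL_PARENCHYMA
    return mask


def extract_parenchyma(
    volume: ADCVolume,
    allow_rule_based: bool = False,
    window: tuple[float, float] = ADC_WINDOW,
) -> VoxelSample:
    """Select parenchymal voxels and apply the >2000 exclusion.

    Voxels labelled CSF or extracranial by the mask are dropped first; of
    the remaining parenchymal voxels, those above the upper window edge
    (fluid/artefact) are removed.  The denominator count is the number of
    retained values inside the closed analysis window.
    """
    if volume.mask is not None:
        mask = volume.mask
    elif allow_rule_based:
        mask = rule_based_mask(volume.values)
    else:
        raise InputError(
            "volume has no mask; pass allow_rule_based=True to enable the "
            "rule-based fallback masker"
        )
    lo, hi = window
    flat = volume.values.ravel()
    parenchyma = mask.ravel() == LABEL_PARENCHYMA
    n_non_parenchyma = int(flat.size - parenchyma.sum())
    par_values = flat[parenchyma]
    high = par_values > hi
    retained = par_values[~high]
    n_denominator = int(np.count_nonzero((retained >= lo) & (retained <= hi)))
    if retained.size == 0 or n_denominator == 0:
        raise DegenerateInputError(
            "no parenchymal voxels remain in the analysis window after exclusions"
        )
    return VoxelSample(
        adc_values=retained,
        n_total_in_denominator=n_denominator,
        n_excluded_high=int(high.sum()),
        n_non_parenchyma=n_non_parenchyma,
    )


def percent_below(
    sample: VoxelSample,
    threshold: float,
    boundary: str = "le",
    window: tuple[float, float] = ADC_WINDOW,
) -> float:
    """ADC-PercentValue at one threshold.

    Returns ``100 * |{v : 200 <= v <= t}| / |{v : 200 <= v <= 2000}|``.
    ``boundary='lt'`` switches the numerator to a strict ``< t`` reading of
    "below threshold"; the default inclusive convention follows the
    closed-summation form of the defining ratio.
    """
    lo, hi = window
    if not (lo <= threshold <= 1150):
        raise InputError(f"threshold {threshold} outside the sweep range [{lo}, 1150]")
    if boundary not in ("le", "lt"):
        raise InputError("boundary must be 'le' or 'lt'")
    v = sample.adc_values
    denom = np.count_nonzero((v >= lo) & (v <= hi))
    if denom == 0:
        raise DegenerateInputError("zero voxels in the analysis window")
    if boundary == "le":
        numer = np.count_nonzero((v >= lo) & (v <= threshold))
    else:
        numer = np.count_nonzero((v >= lo) & (v < threshold))
    return 100.0 * numer / denom


def threshold_sweep(
    sample: VoxelSample,
    thresholds: tuple[int, ...] = DEFAULT_THRESHOLDS,
    boundary: str = "le",
    window: tuple[float, float] = ADC_WINDOW,
) -> dict[int, float]:
    """ADC-PercentValue at every threshold on the sweep grid.

    Computed from one pass over the sample via a cumulative count, which is
    exactly equivalent to independent per-threshold counting (tested).
    Result is non-decreasing in the threshold.
    """
    lo, hi = window
    v = sample.adc_values
    in_window = (v >= lo) & (v <= hi)
    denom = int(np.count_nonzero(in_window))
    if denom == 0:
        raise DegenerateInputError("zero voxels in the analysis window")
    vv = np.sort(v[in_window])
    thr = np.asarray(thresholds, dtype=float)
    if np.any(thr < lo) or np.any(thr > 1150):
        raise InputError("thresholds must lie within [200, 1150]")
    side = "right" if boundary == "le" else "left"
    counts = np.searchsorted(vv, thr, side=side)
    return {int(t): 100.0 * c / denom for t, c in zip(thresholds, counts)}


def mean_whole_brain(
    sample: VoxelSample,
    window: tuple[float, float] = ADC_WINDOW,
    include_below_window: bool = False,
) -> float:
    """Mean whole-brain ADC: the average retained parenchymal ADC value.

    By default the mean is taken over the same closed [200, 2000] window
    used for the ADC-PercentValue denominator.  With
    ``include_below_window=True`` values below 200 are kept (only the >2000
    exclusion applies) — both readings of "the entire brain volume" are
    supported since only the upper exclusion is stated explicitly.
    """
    lo, hi = window
    v = sample.adc_values
    if include_below_window:
        kept = v[v <= hi]
    else:
        kept = v[(v >= lo) & (v <= hi)]
    if kept.size == 0:
        raise DegenerateInputError("zero retained voxels for mean whole-brain ADC")
    return float(kept.mean())


def compute_metrics(
    volume: ADCVolume,
    thresholds: tuple[int, ...] = DEFAULT_THRESHOLDS,
    boundary: str = "le",
    allow_rule_based: bool = False,
    include_below_window: bool = False,
) -> ADCMetrics:
    """Full per-patient quantification: parenchyma extraction, mean
    whole-brain ADC, and the ADC-PercentValue sweep."""
    sample = extract_parenchyma(volume, allow_rule_based=allow_rule_based)
    return ADCMetrics(
        mean_whole_brain_adc=mean_whole_brain(
            sample, include_below_window=include_below_window
        ),
        percent_below=threshold_sweep(sample, thresholds=thresholds, boundary=boundary),
        n_denominator=sample.n_total_in_denominator,
        boundary=boundary,
        thresholds=tuple(thresholds),
    )
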