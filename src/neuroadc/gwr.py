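"""Grey/white-matter ratio (GWR) from CT region-of-interest attenuations.

GWR = (putamen + caudate nucleus) / (posterior limb of the internal
capsule + corpus callosum), all mean Hounsfield units measured in small
circular ROIs at the level of the basal ganglia.  A low GWR reflects loss
of grey–white differentiation from cytotoxic oedema.  ROI means are inputs
here — no CT image processing is performed, matching a manual circular-ROI
workflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .adc import InputError

#: plausibility band (mm^2) for the circular ROI area, when provided
ROI_AREA_BAND_MM2 = (5.0, 20.0)


@dataclass
class CTROIMeasurement:
    """Mean attenuation (HU) of the four prognostic ROIs.

    hu_p: putamen; hu_cn: caudate nucleus; hu_pic: posterior limb of the
    internal capsule; hu_cc: corpus callosum.  ``roi_area_mm2``, when
    given, is checked against a plausibility band around the typical
    9–12 mm^2 circular ROI.
    """

    hu_p: float
    hu_cn: float
    hu_pic: float
    hu_cc: float
    roi_area_mm2: float | None = None

    def __post_init__(self) -> None:
        for name in ("hu_p", "hu_cn", "hu_pic", "hu_cc"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise InputError(f"{name} must be finite, got {v!r}")
        if self.hu_pic + self.hu_cc == 0:
            raise InputError("white-matter denominator hu_pic + hu_cc must be non-zero")
        if self.roi_area_mm2 is not None:
            lo, hi = ROI_AREA_BAND_MM2
            if not (lo <= self.roi_area_mm2 <= hi):
                raise InputError(
                    f"roi_area_mm2 {self.roi_area_mm2} outside the plausibility band "
                    f"[{lo}, {hi}]"
                )


def average_bilateral(left: float, right: float) -> float:
    """Pre-average paired left/right ROI measurements for one structure.

    Whether bilateral ROIs should be averaged is an interpretation; this
    helper makes the choice explicit at the call site.
    """
    if not (math.isfinite(left) and math.isfinite(right)):
        raise InputError("bilateral ROI values must be finite")
    return (left + right) / 2.0


def compute_gwr(m: CTROIMeasurement) -> float:
    """(P + CN) / (PIC + CC), dimensionless."""
    return (m.hu_p + m.hu_cn) / (m.hu_pic + m.hu_cc)


def add_gwr_column(table: pd.DataFrame) -> pd.DataFrame:
    """Append a ``gwr`` column computed from the hu_p/hu_cn/hu_pic/hu_cc
    columns of a cohort covariate table."""
    required = ["hu_p", "hu_cn", "hu_pic", "hu_cc"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise InputError(f"covariate table missing ROI columns: {missing}")
    out = table.copy()
    out["gwr"] = [
        compute_gwr(CTROIMeasurement(r.hu_p, r.hu_cn, r.hu_pic, r.hu_cc))
        for r in table[required].itertuples()
    ]
    return out
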