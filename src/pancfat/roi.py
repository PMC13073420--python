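"""ROI-level aggregation of fat fractions to regions and subjects.

Protocol: per pancreatic region (caput, corpus, cauda) 9 ROIs are
placed on 3 slices, 3 ROIs per slice, each 40-60 mm^2 (80-100 mm^2 for
phantom vials).  A region's fat fraction is the arithmetic mean of its
ROI values; the whole-pancreas fat fraction is the mean of the three
region values; the within-subject heterogeneity index is

    dFF = max(region FFs) - min(region FFs).

All fat fractions at this level are on the percent scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .signal_model import EchoPair, EchoSeries

__all__ = [
    "PANCREAS_REGIONS",
    "ROIS_PER_REGION",
    "RoiMeasurement",
    "SubjectPancreasProfile",
    "RoiProtocolError",
    "region_ff",
    "delta_ff",
    "subject_profile",
]

PANCREAS_REGIONS = ("caput", "corpus", "cauda")
ROIS_PER_REGION = 9

_PANCREAS_AREA = (40.0, 60.0)
_PHANTOM_AREA = (80.0, 100.0)


class RoiProtocolError(ValueError):
    """ROI input violating the measurement protocol."""


@dataclass
class RoiMeasurement:
    """One region-of-interest measurement.

    ``region`` is a pancreatic region name or ``"vial"`` for phantom
    ROIs.  ``ff_calculated`` / ``ff_calibrated`` (percent) are filled by
    the quantification pipeline after inversion and calibration.
    """

    roi_id: str
    region: str
    layer: int
    area: float | None = None
    pair: EchoPair | None = None
    series: EchoSeries | None = None
    ff_calculated: float | None = None
    ff_calibrated: float | None = None

    def __post_init__(self) -> None:
        if self.layer not in (1, 2, 3):
            raise RoiProtocolError(
                f"ROI {self.roi_id}: layer must be 1, 2 or 3, got {self.layer}"
            )
        if self.region not in PANCREAS_REGIONS and self.region != "vial":
            raise RoiProtocolError(
                f"ROI {self.roi_id}: unknown region {self.region!r}; expected "
                f"one of {PANCREAS_REGIONS + ('vial',)}"
            )
        if self.area is not None:
            lo, hi = _PHANTOM_AREA if self.region == "vial" else _PANCREAS_AREA
            if not lo <= self.area <= hi:
                raise RoiProtocolError(
                    f"ROI {self.roi_id} ({self.region}): area {self.area} mm^2 "
                    f"outside protocol range [{lo}, {hi}]"
                )

    def best_ff_percent(self) -> float:
        """Calibrated FF (%) when available, else the calculated FF."""
        if self.ff_calibrated is not None:
            return self.ff_calibrated
        if self.ff_calculated is not None:
            return self.ff_calculated
        raise RoiProtocolError(
            f"ROI {self.roi_id}: no fat fraction computed yet"
        )


@dataclass
class SubjectPancreasProfile:
    """Per-subject regional fat fractions and derived summary values.

    ``ff_whole`` is the mean of the three region values and ``delta_ff``
    their max-min spread; both are recomputed at construction so the
    invariants hold regardless of how the object was populated.
    """

    subject_id: str
    age: float
    group: str
    ff_caput: float
    ff_corpus: float
    ff_cauda: float
    abstinence: str = "none"
    ff_whole: float = field(init=False)
    delta_ff: float = field(init=False)

    def __post_init__(self) -> None:
        regions = (self.ff_caput, self.ff_corpus, self.ff_cauda)
        self.ff_whole = float(np.mean(regions))
        self.delta_ff = float(max(regions) - min(regions))

    @property
    def region_ffs(self) -> dict[str, float]:
        return {
            "caput": self.ff_caput,
            "corpus": self.ff_corpus,
            "cauda": self.ff_cauda,
        }


def region_ff(
    rois: Iterable[RoiMeasurement], strict: bool = True
) -> float:
    """Mean fat fraction (%) of one region's ROIs.

    In strict mode (default) exactly 9 ROIs from a single region are
    required; lenient mode averages whatever is available (>= 1) with a
    warning.
    """
    rois = list(rois)
    if not rois:
        raise RoiProtocolError("region_ff: empty ROI collection")
    regions = {r.region for r in rois}
    if len(regions) > 1:
        raise RoiProtocolError(
            f"region_ff: ROIs mix regions {sorted(regions)}; aggregate one "
            "region at a time"
        )
    if len(rois) != ROIS_PER_REGION:
        msg = (
            f"region {rois[0].region!r}: expected {ROIS_PER_REGION} ROIs "
            f"(3 layers x 3), got {len(rois)}"
        )
        if strict:
            raise RoiProtocolError(msg)
        warnings.warn(msg + "; averaging available ROIs", stacklevel=2)
    return float(np.mean([r.best_ff_percent() for r in rois]))


def delta_ff(region_values: Mapping[str, float]) -> float:
    """Heterogeneity index: max - min over the regional fat fractions."""
    vals = list(region_values.values())
    if not vals:
        raise RoiProtocolError("delta_ff: no region values")
    return float(max(vals) - min(vals))


def subject_profile(
    region_ffs: Mapping[str, float],
    subject_id: str,
    age: float,
    group: str,
    abstinence: str = "none",
) -> SubjectPancreasProfile:
    """Build a subject profile from the three regional fat fractions."""
    missing = [r for r in PANCREAS_REGIONS if r not in region_ffs]
    if missing:
        raise RoiProtocolError(
            f"subject {subject_id}: missing region(s) {missing}"
        )
    return SubjectPancreasProfile(
        subject_id=subject_id,
        age=age,
        group=group,
        abstinence=abstinence,
        ff_caput=float(region_ffs["caput"]),
        ff_corpus=float(region_ffs["corpus"]),
        ff_cauda=float(region_ffs["cauda"]),
    )
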