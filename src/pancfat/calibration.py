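"""Phantom calibration of calculated fat fractions.

A series of fat-water emulsion vials of known concentration (0-14% in
1% steps) is scanned with the same dual-echo protocol as the pancreas.
The corrected two-point estimator still carries a systematic offset and
gain error relative to the true fat concentration (T1-weighting bias,
emulsion composition), so the measured (``calculated``) fat fractions
are mapped to actual fat fractions by ordinary least squares:

    actual = slope * calculated + intercept

with ``actual`` as the response.  The phantom's actual concentrations
are error-free by construction, which makes this an inverse-calibration
regression: the fit is applied afterwards to pancreatic ROI values to
express them on the actual-concentration scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
from scipy import stats

if TYPE_CHECKING:  # pragma: no cover
    from .roi import RoiMeasurement

__all__ = [
    "PhantomVial",
    "CalibrationModel",
    "CalibratedValue",
    "CalibrationError",
    "fit_calibration",
    "fit_calibration_xy",
    "apply_calibration",
]


class CalibrationError(ValueError):
    """Degenerate calibration input (too few points, zero variance...)."""


@dataclass
class PhantomVial:
    """One fat-water phantom vial with its ROI measurements.

    ``actual_ff`` is the fat concentration used as the regression
    response (percent).  ``nominal_ff`` records the dilution level the
    vial was mixed to; in synthetic phantoms the two may differ by the
    mixing scatter.  ``calculated_ff`` is the mean corrected fat
    fraction over the vial's ROIs (percent); in the standard protocol a
    vial carries 9 ROIs (3 layers x 3 ROIs).
    """

    vial_id: str
    actual_ff: float
    calculated_ff: float | None = None
    nominal_ff: float | None = None
    roi_measurements: list["RoiMeasurement"] = field(default_factory=list)

    def __post_init__(self) -> None:
        # nominal dilution levels lie in [0, 30]; the realized response
        # of a synthetic 0% vial may dip slightly below zero
        if not -5 <= self.actual_ff <= 30:
            raise CalibrationError(
                f"actual_ff must be in [-5, 30] %, got {self.actual_ff}"
            )
        if self.nominal_ff is not None and not 0 <= self.nominal_ff <= 30:
            raise CalibrationError(
                f"nominal_ff must be in [0, 30] %, got {self.nominal_ff}"
            )

    def mean_calculated_ff(self) -> float:
        """Mean calculated FF (%) over the vial's ROIs, or the stored value."""
        if self.roi_measurements:
            vals = [r.best_ff_percent() for r in self.roi_measurements]
            return float(np.mean(vals))
        if self.calculated_ff is None:
            raise CalibrationError(
                f"vial {self.vial_id}: no ROIs and no calculated_ff"
            )
        return self.calculated_ff


@dataclass(frozen=True)
class CalibrationModel:
    """Linear map from calculated to actual fat fraction (percent scale)."""

    slope: float
    intercept: float
    r_squared: float
    pearson_r: float
    domain_low: float
    domain_high: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise CalibrationError("n_points must be >= 2")
        if self.domain_low >= self.domain_high:
            raise CalibrationError("domain_low must be < domain_high")

    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, source) -> "CalibrationModel":
        """Load a model from a JSON string or a file path."""
        text = str(source)
        if not text.lstrip().startswith("{"):
            with open(source) as fh:
                text = fh.read()
        return cls(**json.loads(text))

    @classmethod
    def identity(cls) -> "CalibrationModel":
        """Identity mapping over a wide domain (no calibration applied)."""
        return cls(
            slope=1.0, intercept=0.0, r_squared=1.0, pearson_r=1.0,
            domain_low=0.0, domain_high=100.0, n_points=2,
        )


@dataclass(frozen=True)
class CalibratedValue:
    """Calibrated fat fraction (%) plus extrapolation/clamping flags."""

    value: float
    raw_value: float
    extrapolated: bool = False
    clamped: bool = False


def fit_calibration_xy(
    calculated: Sequence[float], actual: Sequence[float]
) -> CalibrationModel:
    """OLS of actual (response) on calculated (predictor), percent scale."""
    x = np.asarray(calculated, dtype=float)
    y = np.asarray(actual, dtype=float)
    if x.size != y.size:
        raise CalibrationError("calculated and actual must have equal length")
    if np.unique(x).size < 3:
        raise CalibrationError(
            f"need >= 3 distinct calculated values, got {np.unique(x).size}"
        )
    if np.ptp(x) == 0:
        raise CalibrationError("zero variance in predictor")
    res = stats.linregress(x, y)
    return CalibrationModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        pearson_r=float(res.rvalue),
        domain_low=float(x.min()),
        domain_high=float(x.max()),
        n_points=int(x.size),
    )


def fit_calibration(vials: Iterable[PhantomVial]) -> CalibrationModel:
    """Fit the phantom calibration line from a collection of vials.

    Each vial contributes one point: (mean calculated FF over its ROIs,
    actual FF).  Requires at least three vials with distinct calculated
    values.
    """
    vials = list(vials)
    if len(vials) < 3:
        raise CalibrationError(f"need >= 3 vials, got {len(vials)}")
    x = [v.mean_calculated_ff() for v in vials]
    y = [v.actual_ff for v in vials]
    return fit_calibration_xy(x, y)


def apply_calibration(
    ff_calculated: float, model: CalibrationModel
) -> CalibratedValue:
    """Map a calculated FF (%) to the actual-concentration scale.

    Values outside the fitted domain are extrapolated but flagged;
    negative results are clamped to 0 with a ``clamped`` flag.  Flags
    never raise: the study itself applied its equation over a stated
    range wider than the phantom's actual concentrations.
    """
    raw = model.slope * ff_calculated + model.intercept
    extrapolated = not model.domain_low <= ff_calculated <= model.domain_high
    clamped = raw < 0
    return CalibratedValue(
        value=max(raw, 0.0),
        raw_value=raw,
        extrapolated=extrapolated,
        clamped=clamped,
    )
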