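"""Response model of the two-reagent photometric xylose assay.

The enzymatic assay reads NADH formation as an absorbance increase at
340 nm; the increase is proportional to the d-xylose concentration in
the sample.  Three computations live here:

* single-point calibration — concentration from a sample's absorbance
  change given one calibrator (3.75 mg/dL by default) and a water blank;
* linearity fitting — ordinary least squares of response on nominal
  concentration over the linear range, reporting slope ``a`` (AU·dL/mg),
  intercept ``y0`` (AU), R² and the residual standard deviation.  The
  residual SD is the dispersion figure the detection-limit formulas
  (``3·s/a`` and ``10·s/a``) consume: it is the only reading under which
  those formulas yield concentration units;
* on-board reagent stability — per-day recovery of control materials,
  reported both relative to the day-1 reading and relative to the
  assigned control value, against a configurable acceptance band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, InsufficientDataError, ValidationError

DEFAULT_CALIBRATOR_CONC = 3.75  # mg/dL, kit standard solution


@dataclass(frozen=True)
class CalibrationRecord:
    """Single-point calibration: one calibrator response and one blank."""

    calibrator_response: float
    blank_response: float = 0.0
    calibrator_conc: float = DEFAULT_CALIBRATOR_CONC

    def __post_init__(self) -> None:
        if self.calibrator_conc <= 0:
            raise ValidationError("calibrator concentration must be positive")
        if self.calibrator_response == self.blank_response:
            raise DegenerateInputError(
                "calibrator response equals blank response: calibration undefined"
            )
        if self.calibrator_response < self.blank_response:
            raise ValidationError(
                "calibrator response below blank response"
            )


@dataclass(frozen=True)
class LinearityResult:
    """OLS fit of response = a·conc + y0 over the linearity series.

    ``residual_sd`` (absorbance units) is the standard deviation of the
    fit residuals with n−2 degrees of freedom — the regression dispersion
    used by the LoD/LoQ formulas.
    """

    slope_a: float
    intercept_y0: float
    r_squared: float
    residual_sd: float
    conc_range: tuple[float, float]
    n: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValidationError("R² outside [0, 1]")
        if self.residual_sd < 0:
            raise ValidationError("residual SD must be non-negative")


def single_point_calibrate(
    sample_response: float, cal: CalibrationRecord
) -> float:
    """Concentration (mg/dL) from a sample's absorbance change.

    Linear interpolation through (blank, 0) and (calibrator response,
    calibrator concentration).  Sub-blank responses yield negative
    concentrations, returned as-is so the caller can flag them.
    """
    span = cal.calibrator_response - cal.blank_response
    return cal.calibrator_conc * (sample_response - cal.blank_response) / span


def fit_linearity(levels, responses) -> LinearityResult:
    """Fit the linearity series by ordinary least squares.

    Replicates enter the regression individually (no pre-averaging), so
    the residual degrees of freedom reflect every measured point.
    """
    x = np.asarray(levels, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("levels and responses differ in length")
    if len(np.unique(x)) < 3:
        raise InsufficientDataError("need at least 3 distinct concentration levels")
    if np.ptp(x) == 0:
        raise DegenerateInputError("all levels identical: rank-deficient design")
    fit = stats.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    dof = len(x) - 2
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof)) if dof > 0 else 0.0
    return LinearityResult(
        slope_a=float(fit.slope),
        intercept_y0=float(fit.intercept),
        r_squared=float(min(fit.rvalue**2, 1.0)),
        residual_sd=residual_sd,
        conc_range=(float(x.min()), float(x.max())),
        n=len(x),
    )


def stability_recovery(
    series: pd.DataFrame,
    assigned: dict[str, float] | None = None,
    band: tuple[float, float] = (85.0, 115.0),
) -> pd.DataFrame:
    """Per-day recovery of on-board reagent controls.

    ``series`` has columns ``day``, ``control_id``, ``measured_conc``.
    Two recovery definitions are reported for every day: percent of the
    day-1 reading, and (when ``assigned`` provides the control's assigned
    concentration) percent of the assigned value.  ``within_band`` flags
    each day against the acceptance band (default 85–115% of day 1).
    """
    required = {"day", "control_id", "measured_conc"}
    if not required.issubset(series.columns):
        raise ValidationError(f"stability series needs columns {sorted(required)}")
    if len(series) == 0:
        raise InsufficientDataError("empty stability series")
    lo, hi = band
    out = []
    for control, grp in series.groupby("control_id", sort=False):
        grp = grp.sort_values("day")
        days = grp["day"].to_numpy()
        if np.any(np.diff(days) <= 0):
            raise ValidationError(
                f"days not strictly increasing for control {control!r}"
            )
        conc = grp["measured_conc"].to_numpy(dtype=float)
        day1 = conc[0]
        if day1 == 0:
            raise DegenerateInputError(
                f"day-1 value of control {control!r} is zero: recovery undefined"
            )
        rec_day1 = 100.0 * conc / day1
        rec_assigned = (
            100.0 * conc / assigned[control]
            if assigned and control in assigned
            else np.full_like(conc, np.nan)
        )
        out.append(
            pd.DataFrame(
                {
                    "control_id": control,
                    "day": days,
                    "measured_conc": conc,
                    "recovery_vs_day1_pct": rec_day1,
                    "recovery_vs_assigned_pct": rec_assigned,
                    "within_band": (rec_day1 >= lo) & (rec_day1 <= hi),
                }
            )
        )
    return pd.concat(out, ignore_index=True)
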