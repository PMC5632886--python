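"""Paired method-comparison statistics.

Given per-patient totals measured by the reference method (x, the
manual colorimetric assay) and the candidate method (y, the enzymatic
assay), this module provides:

* Deming regression, unweighted or iteratively reweighted.  Deming
  regression allows measurement error on both axes; ``lam`` is the
  ratio of the y-method to the x-method error variances (1 = equal
  errors).  The weighted variant assigns each pair the weight
  1/level², with the level taken as the average of the projected
  (fitted) x and y at the current parameters — the standard choice when
  imprecision is proportional to concentration.  Confidence intervals
  come from the leave-one-out jackknife with a t quantile, which is
  deterministic.
* Bland-Altman agreement in absolute units (mg) or with differences
  expressed as a percentage of the pair average.  The difference is
  always candidate − reference, so a candidate reading below the
  reference gives a negative bias.
* Pearson product-moment correlation with its two-sided p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InsufficientDataError, ValidationError
from .study_data import PairedComparisonTable

MAX_ITER = 100
REL_TOL = 1e-10


@dataclass(frozen=True)
class DemingResult:
    slope: float
    intercept: float
    slope_ci95: tuple[float, float]
    intercept_ci95: tuple[float, float]
    lam: float
    n: int
    weighted: bool
    converged: bool
    iterations: int


@dataclass(frozen=True)
class BlandAltmanResult:
    mode: Literal["absolute", "percent_of_average"]
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int


def _pairs_xy(pairs) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pairs, PairedComparisonTable):
        return pairs.method_a, pairs.method_b
    x, y = pairs
    return np.asarray(x, dtype=float), np.asarray(y, dtype=float)


def _deming_closed_form(
    x: np.ndarray, y: np.ndarray, lam: float, w: np.ndarray
) -> tuple[float, float]:
    """Weighted Deming point estimate for fixed weights.

    Minimises sum_i w_i (y_i − b0 − b1 x_i)² / (lam + b1²), the profile
    likelihood of the errors-in-both-variables model with error-variance
    ratio lam = Var(e_y)/Var(e_x).
    """
    wsum = w.sum()
    xbar = (w * x).sum() / wsum
    ybar = (w * y).sum() / wsum
    sxx = (w * (x - xbar) ** 2).sum()
    syy = (w * (y - ybar) ** 2).sum()
    sxy = (w * (x - xbar) * (y - ybar)).sum()
    if sxy == 0:
        if syy == lam * sxx:
            raise DegenerateInputError("Deming slope undefined (no covariance)")
        slope = 0.0 if syy < lam * sxx else np.inf
        raise DegenerateInputError("Deming slope degenerate for uncorrelated data")
    slope = (syy - lam * sxx + np.hypot(syy - lam * sxx, 2 * np.sqrt(lam) * sxy)) / (
        2 * sxy
    )
    intercept = ybar - slope * xbar
    return float(slope), float(intercept)


def _fitted_levels(
    x: np.ndarray, y: np.ndarray, b0: float, b1: float, lam: float
) -> np.ndarray:
    """Average of projected x and y for each pair at the current line.

    The projection is the Deming estimate of the latent true value:
    x_hat = x + lam·b1·(y − b0 − b1 x)/(lam + b1²); y_hat = b0 + b1·x_hat.
    """
    resid = y - b0 - b1 * x
    x_hat = x + lam * b1 * resid / (lam + b1**2)
    y_hat = b0 + b1 * x_hat
    return (x_hat + y_hat) / 2.0


def _deming_point(
    x: np.ndarray, y: np.ndarray, lam: float, weighted: bool
) -> tuple[float, float, bool, int]:
    w = np.ones_like(x)
    slope, intercept = _deming_closed_form(x, y, lam, w)
    if not weighted:
        return slope, intercept, True, 1
    for it in range(1, MAX_ITER + 1):
        d = _fitted_levels(x, y, intercept, slope, lam)
        if np.any(d <= 0):
            raise ValidationError(
                "non-positive fitted level in weighted mode; "
                "weighted Deming requires positive measurements"
            )
        w = 1.0 / d**2
        new_slope, new_intercept = _deming_closed_form(x, y, lam, w)
        delta = max(
            abs(new_slope - slope) / max(abs(slope), 1e-300),
            abs(new_intercept - intercept) / max(abs(intercept), 1e-12),
        )
        slope, intercept = new_slope, new_intercept
        if delta < REL_TOL:
            return slope, intercept, True, it
    return slope, intercept, False, MAX_ITER


def weighted_deming(
    pairs, lam: float = 1.0, weighted: bool = True
) -> DemingResult:
    """Deming regression of candidate (y) on reference (x) totals.

    ``lam`` is the error-variance ratio Var(e_y)/Var(e_x); ``weighted``
    selects the iteratively reweighted fit (weights 1/level²) or the
    plain unweighted fit for sensitivity analysis.  Non-convergence of
    the reweighting loop is flagged on the result, not raised.
    """
    x, y = _pairs_xy(pairs)
    n = len(x)
    if n < 3:
        raise InsufficientDataError("Deming regression needs n >= 3 pairs")
    if lam <= 0:
        raise ValidationError("error-variance ratio lam must be positive")
    if weighted and (np.any(x <= 0) or np.any(y <= 0)):
        raise ValidationError(
            "weighted Deming requires strictly positive totals on both methods"
        )
    slope, intercept, converged, iters = _deming_point(x, y, lam, weighted)

    # leave-one-out jackknife CIs
    idx = np.arange(n)
    slopes = np.empty(n)
    intercepts = np.empty(n)
    for i in range(n):
        keep = idx != i
        s_i, b_i, _, _ = _deming_point(x[keep], y[keep], lam, weighted)
        slopes[i] = s_i
        intercepts[i] = b_i
    t_crit = stats.t.ppf(0.975, df=n - 2)
    se_slope = np.sqrt((n - 1) / n * ((slopes - slopes.mean()) ** 2).sum())
    se_int = np.sqrt((n - 1) / n * ((intercepts - intercepts.mean()) ** 2).sum())
    return DemingResult(
        slope=slope,
        intercept=intercept,
        slope_ci95=(slope - t_crit * se_slope, slope + t_crit * se_slope),
        intercept_ci95=(intercept - t_crit * se_int, intercept + t_crit * se_int),
        lam=lam,
        n=n,
        weighted=weighted,
        converged=converged,
        iterations=iters,
    )


def bland_altman(
    pairs, mode: Literal["absolute", "percent_of_average"] = "absolute"
) -> BlandAltmanResult:
    """Bland-Altman agreement statistics, candidate − reference.

    In ``percent_of_average`` mode each difference is expressed as a
    percentage of the average of the two measurements, which makes a
    constant absolute bias shrink with increasing level.
    """
    x, y = _pairs_xy(pairs)
    n = len(x)
    if n < 2:
        raise InsufficientDataError("Bland-Altman needs n >= 2 pairs")
    diff = y - x
    if mode == "percent_of_average":
        avg = (x + y) / 2.0
        if np.any(avg <= 0):
            bad = list(np.nonzero(avg <= 0)[0])
            raise ValidationError(
                f"non-positive pair average in percent mode at rows {bad}"
            )
        diff = 100.0 * diff / avg
    elif mode != "absolute":
        raise ValidationError(f"unknown Bland-Altman mode {mode!r}")
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltmanResult(
        mode=mode,
        bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        n=n,
    )


def pearson(pairs) -> tuple[float, float]:
    """Pearson correlation between the two methods with two-sided p-value."""
    x, y = _pairs_xy(pairs)
    if len(x) < 3:
        raise InsufficientDataError("Pearson correlation needs n >= 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
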