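"""Detection-capability estimators: LoB, LoD, LoQ, LLoQ, selectivity.

Conventions:

* LoB = mean + 1.645·SD of a blank series (sample SD, n−1).  When
  several blank solutions are measured separately (e.g. water and
  buffer), each yields its own LoB and the method LoB is the maximum —
  the conservative combination.
* LoD = 3·s/a and LoQ = 10·s/a, where ``s`` is the residual SD of the
  linearity regression (absorbance units) and ``a`` its slope
  (AU·dL/mg), so both limits come out in mg/dL.  The multiplier 3 (not
  3.3) is deliberate.
* LLoQ = lowest nominal level whose imprecision (CV%) and absolute
  inaccuracy are both within the acceptance threshold, 20% inclusive —
  a level sitting exactly at 20.0% passes.
* Selectivity: a basal (analyte-free) sample passes when its mean
  signal is below 20% of the LLoQ.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .assay_response import LinearityResult
from .errors import InsufficientDataError, ValidationError

LOB_Z = 1.645  # one-sided 95th percentile of the standard normal
LOD_MULTIPLIER = 3.0
LOQ_MULTIPLIER = 10.0
LLOQ_THRESHOLD_PCT = 20.0
SELECTIVITY_FRACTION = 0.20


@dataclass(frozen=True)
class DetectionLimits:
    lob: float
    lod: float
    loq: float
    lloq: float | None = None

    def __post_init__(self) -> None:
        for name in ("lob", "lod", "loq"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.lod > self.loq:
            raise ValidationError("LoD must not exceed LoQ")


def estimate_lob(blanks) -> float:
    """Limit of blank from one blank series: mean + 1.645·SD (n−1 SD)."""
    x = np.asarray(blanks, dtype=float)
    if x.size < 2:
        raise InsufficientDataError("LoB needs at least 2 blank measurements")
    return float(x.mean() + LOB_Z * x.std(ddof=1))


def method_lob(blank_series: Mapping[str, Sequence[float]]) -> tuple[float, dict]:
    """Method LoB over several blank solutions: the maximum per-series LoB."""
    if not blank_series:
        raise InsufficientDataError("no blank series provided")
    per_series = {name: estimate_lob(vals) for name, vals in blank_series.items()}
    return max(per_series.values()), per_series


def estimate_lod_loq(fit: LinearityResult) -> tuple[float, float]:
    """LoD and LoQ (mg/dL) from the linearity regression parameters."""
    if fit.slope_a <= 0:
        raise ValidationError("linearity slope must be positive")
    lod = LOD_MULTIPLIER * fit.residual_sd / fit.slope_a
    loq = LOQ_MULTIPLIER * fit.residual_sd / fit.slope_a
    return float(lod), float(loq)


def determine_lloq(
    level_results: Iterable, threshold_pct: float = LLOQ_THRESHOLD_PCT
) -> float | None:
    """Lowest nominal level with CV% and |inaccuracy|% ≤ threshold.

    ``level_results`` is an iterable of per-level summaries exposing
    ``nominal_conc``, ``cv_pct`` and ``inaccuracy_pct`` (attributes or
    mapping keys).  Returns None when no level qualifies (the LLoQ is
    then undetermined, not zero).
    """

    def get(item, key):
        if isinstance(item, Mapping):
            return float(item[key])
        return float(getattr(item, key))

    results = list(level_results)
    if not results:
        raise InsufficientDataError("no level summaries supplied")
    passing = [
        get(r, "nominal_conc")
        for r in results
        if get(r, "cv_pct") <= threshold_pct
        and abs(get(r, "inaccuracy_pct")) <= threshold_pct
    ]
    return min(passing) if passing else None


def selectivity_check(
    basal_means: Sequence[float],
    lloq: float | None,
    fraction: float = SELECTIVITY_FRACTION,
) -> tuple[list[bool], bool]:
    """Interference check on basal samples: mean signal < fraction·LLoQ."""
    if lloq is None:
        raise ValidationError("selectivity requires a determined LLoQ")
    threshold = fraction * lloq
    per_sample = [float(m) < threshold for m in basal_means]
    return per_sample, all(per_sample)
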