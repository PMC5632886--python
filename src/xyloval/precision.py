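"""Imprecision and inaccuracy: within-run, between-run, total; carry-over.

Within-run statistics are plain replicate mean/SD at a level; CV% uses
the mean as denominator, inaccuracy% the nominal concentration.  The
between-run decomposition is a one-way random-effects ANOVA with run
(day) as the grouping factor: the within-run variance is the pooled
within-day variance, the between-run variance component is
max(0, (MS_between − MS_within)/n0) with n0 the effective replicates
per day, and the total CV is the root-sum-of-squares of the two
components, all expressed relative to the grand mean.

Carry-over on an analyzer is estimated from an alternating high/low
sample sequence as the fraction of the high signal contaminating a low
sample: 100·(mean(L after H) − mean(L after L)) / (mean(H) − mean(L
after L)).  Both sequence designs used in practice — blocks of low
replicates followed by high replicates, and repeated H,L couplets —
contain the required patterns and are parsed identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InsufficientDataError, ValidationError
from .study_data import ReplicateTable


@dataclass(frozen=True)
class PrecisionSummary:
    """Replicate summary at one level: mean, SD, CV%, inaccuracy%."""

    analyzer: str
    level_id: str
    nominal_conc: float
    n: int
    mean: float
    sd: float
    cv_pct: float
    inaccuracy_pct: float


@dataclass(frozen=True)
class VarianceComponents:
    within_run_cv_pct: float
    between_run_cv_pct: float
    total_cv_pct: float

    def __post_init__(self) -> None:
        if min(self.within_run_cv_pct, self.between_run_cv_pct) < 0:
            raise ValidationError("CV components must be non-negative")


@dataclass(frozen=True)
class CarryoverResult:
    carryover_pct: float
    n_low_after_high: int
    n_low_after_low: int
    n_high: int


def _extract_values(replicates) -> np.ndarray:
    if isinstance(replicates, ReplicateTable):
        return replicates.df["value"].to_numpy(dtype=float)
    return np.asarray(replicates, dtype=float)


def summary_from_moments(
    mean: float,
    sd: float,
    nominal: float,
    n: int,
    analyzer: str = "",
    level_id: str = "",
) -> PrecisionSummary:
    """Build a summary from already-computed moments (e.g. a published table)."""
    if nominal <= 0:
        raise ValidationError("nominal concentration must be positive")
    if mean == 0:
        raise DegenerateInputError("zero mean: CV undefined")
    return PrecisionSummary(
        analyzer=analyzer,
        level_id=level_id,
        nominal_conc=float(nominal),
        n=int(n),
        mean=float(mean),
        sd=float(sd),
        cv_pct=100.0 * sd / mean,
        inaccuracy_pct=100.0 * abs(mean - nominal) / nominal,
    )


def within_run_stats(
    replicates,
    nominal: float,
    analyzer: str = "",
    level_id: str = "",
) -> PrecisionSummary:
    """Within-run precision (CV%) and accuracy (inaccuracy%) at one level."""
    x = _extract_values(replicates)
    if x.size < 2:
        raise InsufficientDataError("within-run statistics need n >= 2")
    return summary_from_moments(
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)),
        nominal=nominal,
        n=int(x.size),
        analyzer=analyzer,
        level_id=level_id,
    )


def between_run_stats(day_replicates) -> VarianceComponents:
    """One-way random-effects ANOVA decomposition across runs (days).

    ``day_replicates`` is a :class:`ReplicateTable` (grouped by its
    ``run_id`` column) or a DataFrame with ``run_id`` and ``value``.
    """
    df = (
        day_replicates.df
        if isinstance(day_replicates, ReplicateTable)
        else pd.DataFrame(day_replicates)
    )
    groups = [g["value"].to_numpy(dtype=float) for _, g in df.groupby("run_id")]
    k = len(groups)
    if k < 2:
        raise InsufficientDataError("between-run decomposition needs >= 2 runs")
    sizes = np.array([len(g) for g in groups])
    if not np.any(sizes >= 2):
        raise InsufficientDataError("at least one run needs >= 2 replicates")
    n_total = int(sizes.sum())
    grand = float(np.concatenate(groups).mean())
    if grand == 0:
        raise DegenerateInputError("grand mean is zero: CV undefined")

    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ms_within = ss_within / (n_total - k)
    ms_between = ss_between / (k - 1)
    # effective replicates per run (reduces to the common size when balanced)
    n0 = (n_total - (sizes**2).sum() / n_total) / (k - 1)

    var_within = ms_within
    var_between = max(0.0, (ms_between - ms_within) / n0)
    cv_within = 100.0 * np.sqrt(var_within) / grand
    cv_between = 100.0 * np.sqrt(var_between) / grand
    cv_total = float(np.hypot(cv_within, cv_between))
    return VarianceComponents(
        within_run_cv_pct=float(cv_within),
        between_run_cv_pct=float(cv_between),
        total_cv_pct=cv_total,
    )


def carryover(sequence) -> CarryoverResult:
    """Carry-over percentage from an ordered high/low measurement sequence.

    ``sequence`` is an iterable of ``(tag, value)`` pairs or a DataFrame
    with ``level_tag`` in {"H", "L"} and ``value`` columns, in assay
    order.
    """
    if isinstance(sequence, pd.DataFrame):
        tags = [str(t).upper() for t in sequence["level_tag"]]
        values = sequence["value"].to_numpy(dtype=float)
    else:
        pairs = list(sequence)
        tags = [str(t).upper() for t, _ in pairs]
        values = np.array([v for _, v in pairs], dtype=float)
    if any(t not in ("H", "L") for t in tags):
        raise ValidationError("level tags must be 'H' or 'L'")

    high = [v for t, v in zip(tags, values) if t == "H"]
    low_after_high = [
        values[i] for i in range(1, len(tags)) if tags[i] == "L" and tags[i - 1] == "H"
    ]
    low_after_low = [
        values[i] for i in range(1, len(tags)) if tags[i] == "L" and tags[i - 1] == "L"
    ]
    if not low_after_high:
        raise InsufficientDataError("sequence contains no L measurement after an H")
    if not low_after_low:
        raise InsufficientDataError("sequence contains no L measurement after an L")
    mean_h = float(np.mean(high))
    mean_lh = float(np.mean(low_after_high))
    mean_ll = float(np.mean(low_after_low))
    denom = mean_h - mean_ll
    if denom == 0:
        raise DegenerateInputError("high and low baselines coincide")
    return CarryoverResult(
        carryover_pct=100.0 * (mean_lh - mean_ll) / denom,
        n_low_after_high=len(low_after_high),
        n_low_after_low=len(low_after_low),
        n_high=len(high),
    )
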