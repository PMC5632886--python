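"""Seeded generators for every input table the pipeline consumes.

The generators emulate the statistical structure of an analytical
validation study of a urinary xylose assay, so that every stage of the
pipeline is testable without access to the original measurements:

* replicate series with separate within-run and between-run
  coefficients of variation (multiplicative noise — imprecision in this
  setting is proportional to concentration);
* linearity series, response = slope·conc + intercept + Gaussian noise
  in absorbance units;
* a paired patient cohort in which the candidate (enzymatic) method
  measures the true excreted xylose while the reference (colorimetric)
  method additionally picks up a positive interfering background drawn
  from a truncated Gaussian.  This reproduces the constant-bias
  signature seen when the two methods are compared: the absolute
  difference is independent of the level while the percentage
  difference shrinks as totals grow.

All generators are pure functions of (config, seed): identical inputs
give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .study_data import PairedComparisonTable, ReplicateTable


@dataclass(frozen=True)
class PrecisionSimConfig:
    """Replicate-series generator settings (concentrations in mg/dL)."""

    nominal_levels: tuple[float, ...] = (0.84, 5.443)
    within_cv_pct: float = 2.0
    between_cv_pct: float = 4.0
    n_runs: int = 20
    replicates_per_run: int = 2
    analyzer: str = "sim"
    matrix: str = "urine"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.within_cv_pct, self.between_cv_pct) < 0:
            raise ValidationError("CVs must be non-negative")
        if min(self.n_runs, self.replicates_per_run) < 1:
            raise ValidationError("counts must be >= 1")


@dataclass(frozen=True)
class CohortSimConfig:
    """Paired-cohort generator settings.

    True excreted xylose is drawn from class-conditional log-normal
    distributions (totals stay positive); the reference method adds a
    positive interfering background B ~ truncated Normal(background_mean,
    background_sd²) restricted to ``background_range``.  ``prevalence_hypo``
    is the fraction of hypolactasic (low-excretion) patients.  Both
    method readings carry multiplicative Gaussian noise with the given
    CVs and are floored at 0.
    """

    n_patients: int = 224
    prevalence_hypo: float = 0.5
    hypo_true_mean: float = 10.0
    hypo_true_sd: float = 6.0
    normo_true_mean: float = 60.0
    normo_true_sd: float = 25.0
    background_mean: float = 12.92
    background_sd: float = 5.26
    background_range: tuple[float, float] | None = (1.93, 22.64)
    measurement_cv_a_pct: float = 5.0  # reference (colorimetric) method
    measurement_cv_b_pct: float = 5.0  # candidate (enzymatic) method
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence_hypo <= 1.0:
            raise ValidationError("prevalence must be in [0, 1]")
        if min(
            self.hypo_true_sd,
            self.normo_true_sd,
            self.background_sd,
            self.measurement_cv_a_pct,
            self.measurement_cv_b_pct,
        ) < 0:
            raise ValidationError("SDs and CVs must be non-negative")
        if self.background_range is not None:
            lo, hi = self.background_range
            if lo >= hi:
                raise ValidationError("background range bounds must be ordered")
            if self.background_sd > 0:
                a = (lo - self.background_mean) / self.background_sd
                b = (hi - self.background_mean) / self.background_sd
                if a > 8 or b < -8:
                    raise ValidationError(
                        "background range excludes essentially all of the "
                        "Gaussian mass: truncation impossible"
                    )
            elif not lo <= self.background_mean <= hi:
                raise ValidationError(
                    "degenerate background (sd=0) outside its range"
                )


def simulate_replicates(cfg: PrecisionSimConfig) -> ReplicateTable:
    """Replicate table with per-run effects and within-run noise.

    value = nominal · (1 + run_effect + within_noise), floored at 0,
    with run_effect ~ N(0, between_cv²) shared across a run and
    within_noise ~ N(0, within_cv²) per replicate.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for nominal in cfg.nominal_levels:
        run_effects = rng.normal(0.0, cfg.between_cv_pct / 100.0, cfg.n_runs)
        for run in range(cfg.n_runs):
            eps = rng.normal(0.0, cfg.within_cv_pct / 100.0, cfg.replicates_per_run)
            values = np.maximum(0.0, nominal * (1.0 + run_effects[run] + eps))
            for rep, v in enumerate(values, start=1):
                rows.append(
                    {
                        "analyzer": cfg.analyzer,
                        "matrix": cfg.matrix,
                        "level_id": f"level_{nominal:g}",
                        "nominal_conc": nominal,
                        "run_id": f"run_{run + 1:02d}",
                        "replicate_index": rep,
                        "value": v,
                        "raw_response": np.nan,
                    }
                )
    return ReplicateTable(pd.DataFrame(rows))


def simulate_linearity(
    levels,
    slope: float,
    intercept: float = 0.0,
    noise_sd: float = 0.0,
    replicates: int = 3,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Linearity series: response = slope·level + intercept + N(0, noise_sd).

    Each level is measured ``replicates`` times; returns the replicated
    level vector and the matching responses.
    """
    if noise_sd < 0:
        raise ValidationError("noise SD must be non-negative")
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    x = np.repeat(np.asarray(levels, dtype=float), replicates)
    y = slope * x + intercept + rng.normal(0.0, noise_sd, x.size)
    return x, y


def simulate_blanks(
    n: int, mean: float = 0.02, sd: float = 0.01, seed: int = 0
) -> np.ndarray:
    """Blank measurement series (additive noise, floored at 0)."""
    if n < 1:
        raise ValidationError("need n >= 1 blanks")
    if sd < 0:
        raise ValidationError("SD must be non-negative")
    rng = np.random.default_rng(seed)
    return np.maximum(0.0, rng.normal(mean, sd, n))


def _lognormal(rng, mean: float, sd: float, size: int) -> np.ndarray:
    """Log-normal draws moment-matched to the requested mean and SD."""
    if sd == 0:
        return np.full(size, mean)
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def _background(rng, cfg: CohortSimConfig, size: int) -> np.ndarray:
    if cfg.background_sd == 0:
        return np.full(size, cfg.background_mean)
    if cfg.background_range is None:
        return rng.normal(cfg.background_mean, cfg.background_sd, size)
    lo, hi = cfg.background_range
    a = (lo - cfg.background_mean) / cfg.background_sd
    b = (hi - cfg.background_mean) / cfg.background_sd
    return stats.truncnorm.rvs(
        a, b, loc=cfg.background_mean, scale=cfg.background_sd,
        size=size, random_state=rng,
    )


def simulate_paired_cohort(cfg: CohortSimConfig) -> PairedComparisonTable:
    """Paired per-patient totals for the reference and candidate methods.

    Per patient: draw the true excreted amount T from the
    class-conditional log-normal; the candidate reads T·(1 + e_b) and
    the reference reads (T + B)·(1 + e_a) with B the interfering
    background.  Both readings are floored at 0.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    is_hypo = rng.random(n) < cfg.prevalence_hypo
    true = np.where(
        is_hypo,
        _lognormal(rng, cfg.hypo_true_mean, cfg.hypo_true_sd, n),
        _lognormal(rng, cfg.normo_true_mean, cfg.normo_true_sd, n),
    )
    background = _background(rng, cfg, n)
    noise_a = rng.normal(0.0, cfg.measurement_cv_a_pct / 100.0, n)
    noise_b = rng.normal(0.0, cfg.measurement_cv_b_pct / 100.0, n)
    method_a = np.maximum(0.0, (true + background) * (1.0 + noise_a))
    method_b = np.maximum(0.0, true * (1.0 + noise_b))
    df = pd.DataFrame(
        {
            "patient_id": [str(i + 1) for i in range(n)],
            "method_a_total": method_a,
            "method_b_total": method_b,
            "reference_label": pd.Series([None] * n, dtype=object),
            "adjudicated_label": pd.Series([None] * n, dtype=object),
        }
    )
    return PairedComparisonTable(df)
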