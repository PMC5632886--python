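"""Diagnostic classification, ROC cut-off transfer, kappa, adjudication.

The reference colorimetric method carries an established decision
threshold on the cumulated urinary xylose total: a patient excreting
strictly less than the cut-off (37.87 mg by default) is classified
hypolactasic.  Because the candidate enzymatic method reads
systematically lower (it is free of the colorimetric background), its
own cut-off must be derived, which is done by treating the reference
classification as truth and finding the candidate threshold on the ROC
curve that maximises Youden's J.  Agreement between the two binary
classifications is quantified by Cohen's kappa, and individual
discordant patients can be adjudicated against external clinical
follow-up, replacing the reference label for those patients only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, ValidationError
from .study_data import LACTASE_LABELS, PairedComparisonTable

HYPO, NORMO = LACTASE_LABELS
DEFAULT_REFERENCE_CUTOFF = 37.87  # mg, reference-method decision threshold


@dataclass(frozen=True)
class CutoffPolicy:
    """Decision thresholds for the two methods.

    ``candidate_cutoff`` may be supplied directly or left None to be
    derived from the ROC transfer.  Classification is strict: a total
    strictly below the cut-off means hypolactasic.
    """

    reference_cutoff: float = DEFAULT_REFERENCE_CUTOFF
    candidate_cutoff: float | None = None
    rule: str = "value strictly below cut-off -> hypolactasic"

    def __post_init__(self) -> None:
        if self.reference_cutoff <= 0:
            raise ValidationError("reference cut-off must be positive")
        if self.candidate_cutoff is not None and self.candidate_cutoff <= 0:
            raise ValidationError("candidate cut-off must be positive")


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    auc_ci95: tuple[float, float]
    selected_cutoff: float
    selection_rule: str
    youden_j: float
    n_positive: int
    n_negative: int


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    se: float
    ci95: tuple[float, float]
    contingency: np.ndarray  # 2x2 counts, rows = rater a, cols = rater b
    n: int
    status: str = "ok"  # "undefined" when chance agreement is 1


@dataclass(frozen=True)
class DiscrepancyReport:
    discordant_ids: list[str]
    overrides_applied: list[tuple[str, str, str]]  # (id, new_label, reason)


def classify(totals, cutoff: float) -> list[str]:
    """Binary classification of xylose totals at a cut-off (strict <)."""
    if cutoff <= 0:
        raise ValidationError("cut-off must be positive")
    arr = np.asarray(totals, dtype=float)
    return [HYPO if t < cutoff else NORMO for t in arr]


def reference_labels(pairs: PairedComparisonTable, policy: CutoffPolicy) -> list[str]:
    """Reference classification, honouring per-patient adjudications."""
    labels = classify(pairs.method_a, policy.reference_cutoff)
    adj = pairs.df["adjudicated_label"].tolist()
    return [a if a is not None else lab for a, lab in zip(adj, labels)]


# ---------------------------------------------------------------------------
# ROC


def _roc_curve(scores_pos: np.ndarray, scores_neg: np.ndarray):
    """Empirical ROC for a 'low score = positive' marker.

    Thresholds at midpoints between adjacent sorted unique scores plus
    ±inf sentinels; sensitivity = P(score < t | positive), specificity =
    P(score >= t | negative).
    """
    uniq = np.unique(np.concatenate([scores_pos, scores_neg]))
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if len(uniq) > 1 else np.array([])
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    sens = np.array([(scores_pos < t).mean() for t in thresholds])
    spec = np.array([(scores_neg >= t).mean() for t in thresholds])
    return thresholds, sens, spec


def _auc_trapezoid(sens: np.ndarray, spec: np.ndarray) -> float:
    fpr = 1.0 - spec
    order = np.argsort(fpr, kind="stable")
    return float(np.trapezoid(sens[order], fpr[order]))


def _delong_ci(scores_pos: np.ndarray, scores_neg: np.ndarray, auc: float):
    """DeLong 95% CI for the empirical AUC (low score = positive)."""
    # orient so that higher value means more diseased
    x = -scores_pos[:, None]
    y = -scores_neg[None, :]
    psi = np.where(x > y, 1.0, np.where(x == y, 0.5, 0.0))
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    m, n = len(v10), len(v01)
    var = 0.0
    if m > 1:
        var += v10.var(ddof=1) / m
    if n > 1:
        var += v01.var(ddof=1) / n
    half = 1.96 * np.sqrt(var)
    return (max(0.0, auc - half), min(1.0, auc + half))


def roc_transfer(pairs: PairedComparisonTable, policy: CutoffPolicy) -> RocResult:
    """Derive the candidate method's cut-off from the reference labels.

    Labels come from :func:`reference_labels` (reference classification
    with any adjudications applied); the candidate totals are the
    scores.  The selected cut-off maximises Youden's J = sensitivity +
    specificity − 1, breaking ties toward the lower threshold.
    """
    labels = np.array(reference_labels(pairs, policy))
    scores = pairs.method_b
    pos = scores[labels == HYPO]
    neg = scores[labels == NORMO]
    if len(pos) == 0 or len(neg) == 0:
        raise DegenerateInputError(
            "reference classification contains a single class: ROC undefined"
        )
    thresholds, sens, spec = _roc_curve(pos, neg)
    auc = _auc_trapezoid(sens, spec)
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # argmax returns the first (lowest threshold) tie
    return RocResult(
        thresholds=thresholds,
        sensitivities=sens,
        specificities=spec,
        auc=auc,
        auc_ci95=_delong_ci(pos, neg, auc),
        selected_cutoff=float(thresholds[best]),
        selection_rule="max Youden J, ties -> lower threshold",
        youden_j=float(j[best]),
        n_positive=len(pos),
        n_negative=len(neg),
    )


# ---------------------------------------------------------------------------
# kappa


def cohens_kappa(labels_a: Sequence[str], labels_b: Sequence[str]) -> KappaResult:
    """Cohen's kappa for two binary classifications of the same subjects.

    The asymptotic standard error sqrt(p_o(1−p_o)/(n(1−p_e)²)) gives the
    95% CI.  When both raters assign one identical constant label,
    chance agreement is 1 and kappa is undefined; the result carries
    status "undefined" with NaN estimates instead of raising.
    """
    a = list(labels_a)
    b = list(labels_b)
    if len(a) != len(b):
        raise ValidationError("label lists differ in length")
    n = len(a)
    if n < 1:
        raise ValidationError("need at least one subject")
    cats = sorted(set(a) | set(b))
    if len(cats) > 2:
        raise ValidationError(f"expected binary labels, got {cats}")
    if len(cats) == 1:
        cats = cats + ["__other__"]
    idx = {c: i for i, c in enumerate(cats)}
    table = np.zeros((2, 2))
    for la, lb in zip(a, b):
        table[idx[la], idx[lb]] += 1
    p_o = np.trace(table) / n
    p_e = float((table.sum(axis=1) / n) @ (table.sum(axis=0) / n))
    if p_e >= 1.0:
        return KappaResult(
            kappa=float("nan"),
            se=float("nan"),
            ci95=(float("nan"), float("nan")),
            contingency=table,
            n=n,
            status="undefined",
        )
    kappa = (p_o - p_e) / (1.0 - p_e)
    se = float(np.sqrt(p_o * (1.0 - p_o) / (n * (1.0 - p_e) ** 2)))
    return KappaResult(
        kappa=float(kappa),
        se=se,
        ci95=(kappa - 1.96 * se, kappa + 1.96 * se),
        contingency=table,
        n=n,
    )


# ---------------------------------------------------------------------------
# adjudication


def adjudicate(
    pairs: PairedComparisonTable,
    policy: CutoffPolicy,
    overrides: Sequence[tuple[str, str]] | Sequence[tuple[str, str, str]] = (),
) -> tuple[PairedComparisonTable, DiscrepancyReport]:
    """List discordant patients and apply per-patient label overrides.

    A patient is discordant when the reference classification (method a
    at the reference cut-off) and the candidate classification (method b
    at the candidate cut-off) disagree.  Overrides — typically from
    clinical follow-up — replace the reference label for the listed
    patient ids only; the corrected table feeds :func:`roc_transfer`
    and :func:`cohens_kappa` reruns.
    """
    if policy.candidate_cutoff is None:
        raise ValidationError("adjudication requires a candidate cut-off")
    ref = reference_labels(pairs, policy)
    cand = classify(pairs.method_b, policy.candidate_cutoff)
    ids = pairs.df["patient_id"].tolist()
    discordant = [i for i, (r, c) in zip(ids, zip(ref, cand)) if r != c]

    df = pairs.df.copy()
    applied: list[tuple[str, str, str]] = []
    known = set(ids)
    for entry in overrides:
        pid, label, *rest = entry
        reason = rest[0] if rest else ""
        if pid not in known:
            raise ValidationError(f"override for unknown patient_id {pid!r}")
        if label not in LACTASE_LABELS:
            raise ValidationError(f"override label {label!r} not in {LACTASE_LABELS}")
        df.loc[df["patient_id"] == pid, "adjudicated_label"] = label
        applied.append((pid, label, reason))
    return PairedComparisonTable(df), DiscrepancyReport(
        discordant_ids=discordant, overrides_applied=applied
    )
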