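"""Diagnostic-accuracy and rater-agreement statistics for visual stain scoring.

Implements the evaluation layer of the screening study: pooled confusion
matrices over observers, the five standard 2x2 performance metrics
(sensitivity, specificity, PPV, NPV, accuracy), Fleiss' kappa for intra- and
inter-observer agreement, the ROC/AUC-based visual limit of detection, the
readout-time rule, and the reducing-agent formulation selection criterion.

Score tables are tidy DataFrames with columns ``observer_id, stain_id,
replicate, call, true_hbs_percent``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ValidationError

# ---------------------------------------------------------------------------
# Genotype truth schemes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenotypeScheme:
    """Three-class truth labeling from %HbS.

    Normal (HbAA) blood carries no HbS; sickle cell trait (HbAS) is
    characterized by 10–40% HbS; sickle cell anemia (HbSS) by more than 40%.
    """

    labels: tuple[str, str, str] = ("AA", "AS", "SS")
    trait_lower: float = 10.0
    trait_upper: float = 40.0

    def truth_label(self, hbs_percent: float) -> str:
        if hbs_percent < self.trait_lower:
            return self.labels[0]
        if hbs_percent > self.trait_upper:
            return self.labels[2]
        return self.labels[1]


@dataclass(frozen=True)
class BinaryScheme:
    """Binary truth labeling: positive iff %HbS >= positive_threshold."""

    positive_threshold: float
    labels: tuple[str, str] = ("negative", "positive")

    def truth_label(self, hbs_percent: float) -> str:
        return self.labels[1] if hbs_percent >= self.positive_threshold else self.labels[0]


THREE_CLASS_SCHEME = GenotypeScheme()
#: "HbAA vs rest" screening task: any HbS at or above 10% counts positive.
AA_VS_REST_SCHEME = BinaryScheme(positive_threshold=10.0)
#: "HbSS vs rest" screening task: HbS at or above 80% (characteristic of SCA).
SS_VS_REST_SCHEME = BinaryScheme(positive_threshold=80.0)


# ---------------------------------------------------------------------------
# Confusion matrix and binary metrics
# ---------------------------------------------------------------------------


@dataclass
class ConfusionMatrix:
    """K x K pooled tally; rows are true classes, columns predicted classes."""

    counts: np.ndarray
    class_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_labels)
        if counts.shape != (k, k):
            raise ValidationError("counts must be K x K for K labels")
        if np.any(counts < 0):
            raise ValidationError("counts must be non-negative")
        if counts.sum() == 0:
            raise ValidationError("confusion matrix is empty")
        self.counts = counts

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class DiagnosticMetrics:
    """The five performance quantities plus the 2x2 cells they derive from.

    A metric with a zero denominator is ``None`` and its name is listed in
    ``undefined`` rather than being coerced to 0.
    """

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float | None
    tp: int
    fp: int
    tn: int
    fn: int
    undefined: tuple[str, ...] = ()

    def as_percents(self, ndigits: int = 1) -> dict[str, float | None]:
        """Metrics on the 0–100 scale, rounded for reporting."""
        out = {}
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            value = getattr(self, name)
            out[name] = None if value is None else round(100.0 * value, ndigits)
        return out


def validate_score_table(scores: pd.DataFrame, labels: Iterable[str] | None = None) -> None:
    """Check structural invariants of a score table."""
    required = {"observer_id", "stain_id", "replicate", "call"}
    missing = required - set(scores.columns)
    if missing:
        raise ValidationError(f"score table missing columns: {sorted(missing)}")
    if scores.empty:
        raise ValidationError("score table is empty")
    if scores.duplicated(["observer_id", "stain_id", "replicate"]).any():
        raise ValidationError("duplicate (observer, stain, replicate) records")
    if labels is not None:
        bad = set(scores["call"]) - set(labels)
        if bad:
            raise ValidationError(f"calls outside the declared label set: {sorted(bad)}")


def confusion_matrix(
    scores: pd.DataFrame, scheme: GenotypeScheme | BinaryScheme
) -> ConfusionMatrix:
    """Pooled confusion matrix over all observers and replicates.

    Truth labels are derived from ``true_hbs_percent`` via the scheme; every
    record contributes one count, so the total equals the number of records
    (e.g. 185 stains x 3 observers = 555 scores).
    """
    validate_score_table(scores, scheme.labels)
    if "true_hbs_percent" not in scores.columns:
        raise ValidationError("score table lacks true_hbs_percent")
    if scores["true_hbs_percent"].isna().any():
        raise ValidationError("true_hbs_percent contains missing values")
    labels = tuple(scheme.labels)
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    truths = scores["true_hbs_percent"].map(scheme.truth_label)
    for truth, call in zip(truths, scores["call"]):
        counts[index[truth], index[call]] += 1
    return ConfusionMatrix(counts=counts, class_labels=labels)


def binary_metrics(
    cm: ConfusionMatrix, positive_class_set: Iterable[str]
) -> DiagnosticMetrics:
    """Collapse a K x K matrix to 2x2 and apply the five metric formulas.

    Sensitivity = TP/(TP+FN), specificity = TN/(FP+TN), PPV = TP/(TP+FP),
    NPV = TN/(TN+FN), accuracy = (TP+TN)/(TP+FP+TN+FN).
    """
    positives = set(positive_class_set)
    labels = set(cm.class_labels)
    if not positives or not positives < labels:
        raise ValidationError("positive set must be a non-empty proper subset of labels")
    pos_idx = [i for i, lab in enumerate(cm.class_labels) if lab in positives]
    neg_idx = [i for i, lab in enumerate(cm.class_labels) if lab not in positives]
    c = cm.counts
    tp = int(c[np.ix_(pos_idx, pos_idx)].sum())
    fn = int(c[np.ix_(pos_idx, neg_idx)].sum())
    fp = int(c[np.ix_(neg_idx, pos_idx)].sum())
    tn = int(c[np.ix_(neg_idx, neg_idx)].sum())

    undefined: list[str] = []

    def ratio(name: str, num: int, den: int) -> float | None:
        if den == 0:
            undefined.append(name)
            return None
        return num / den

    return DiagnosticMetrics(
        sensitivity=ratio("sensitivity", tp, tp + fn),
        specificity=ratio("specificity", tn, fp + tn),
        ppv=ratio("ppv", tp, tp + fp),
        npv=ratio("npv", tn, tn + fn),
        accuracy=ratio("accuracy", tp + tn, tp + fp + tn + fn),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        undefined=tuple(undefined),
    )


def consistent_binary_counts(
    sensitivity: float,
    specificity: float,
    ppv: float,
    npv: float,
    accuracy: float,
    total: int,
    ndigits: int = 1,
) -> tuple[int, int, int, int]:
    """Integer search for (TP, FP, TN, FN) consistent with reported metrics.

    Metrics are given on the percent scale as printed (e.g. 92.8); a cell
    assignment matches when every defined metric rounds to the printed value
    at ``ndigits`` decimals.  Returns the first match scanning positives
    count upward; raises if no assignment with the given total exists.
    """
    target = (sensitivity, specificity, ppv, npv, accuracy)
    for n_pos in range(1, total):
        n_neg = total - n_pos
        for tp in range(n_pos + 1):
            fn = n_pos - tp
            if round(100.0 * tp / n_pos, ndigits) != round(target[0], ndigits):
                continue
            for tn in range(n_neg + 1):
                fp = n_neg - tn
                if round(100.0 * tn / n_neg, ndigits) != round(target[1], ndigits):
                    continue
                if tp + fp > 0 and round(100.0 * tp / (tp + fp), ndigits) != round(
                    target[2], ndigits
                ):
                    continue
                if tn + fn > 0 and round(100.0 * tn / (tn + fn), ndigits) != round(
                    target[3], ndigits
                ):
                    continue
                if round(100.0 * (tp + tn) / total, ndigits) != round(target[4], ndigits):
                    continue
                return tp, fp, tn, fn
    raise ValidationError("no integer 2x2 matrix is consistent with the reported metrics")


# ---------------------------------------------------------------------------
# Fleiss' kappa
# ---------------------------------------------------------------------------


def fleiss_kappa_from_counts(counts: np.ndarray) -> float:
    """Fleiss' kappa from an N-subject x K-category rating-count matrix.

    Each subject must be rated the same number of times n >= 2.  With
    P_i = (sum_j n_ij^2 - n) / (n(n-1)) and p_j the pooled category
    proportions, kappa = (mean(P_i) - sum p_j^2) / (1 - sum p_j^2).  Perfect
    agreement on a single category (chance agreement 1) is reported as 1.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if counts.ndim != 2 or counts.shape[0] < 1:
        raise ValidationError("counts must be N x K")
    n_ratings = counts.sum(axis=1)
    if np.any(n_ratings < 2):
        raise ValidationError("each subject needs at least 2 ratings")
    if not np.all(n_ratings == n_ratings[0]):
        raise ValidationError("every subject must be rated the same number of times")
    n = float(n_ratings[0])
    p_subject = (np.sum(counts**2, axis=1) - n) / (n * (n - 1.0))
    p_bar = float(p_subject.mean())
    p_cat = counts.sum(axis=0) / counts.sum()
    p_e = float(np.sum(p_cat**2))
    if p_e == 1.0:
        return 1.0
    return (p_bar - p_e) / (1.0 - p_e)


def fleiss_kappa(
    scores: pd.DataFrame,
    subject_col: str = "stain_id",
    rating_col: str = "call",
) -> float:
    """Fleiss' kappa for a tidy table of categorical ratings.

    For inter-observer agreement each stain is a subject and the observers
    are the raters; for intra-observer agreement restrict the table to one
    observer and the replicate readings act as the raters.
    """
    if scores.empty:
        raise ValidationError("empty score table")
    table = pd.crosstab(scores[subject_col], scores[rating_col])
    return fleiss_kappa_from_counts(table.to_numpy())


def intra_observer_kappas(scores: pd.DataFrame) -> dict[str, float]:
    """Per-observer Fleiss' kappa over replicate readings of each stain."""
    validate_score_table(scores)
    out = {}
    for observer, group in scores.groupby("observer_id", sort=True):
        out[str(observer)] = fleiss_kappa(group)
    return out


@dataclass(frozen=True)
class AgreementSummary:
    """Mean and population standard deviation of per-observer kappas."""

    mean: float
    sd: float

    @property
    def rounded(self) -> tuple[float, float]:
        return round(self.mean, 2), round(self.sd, 2)


def agreement_summary(kappas: Sequence[float]) -> AgreementSummary:
    """Summarize per-observer kappas as mean +/- population SD (divisor n)."""
    values = np.asarray(list(kappas), dtype=np.float64)
    if values.size < 2:
        raise ValidationError("need at least 2 kappa values")
    return AgreementSummary(mean=float(values.mean()), sd=float(values.std(ddof=0)))


# ---------------------------------------------------------------------------
# ROC-based limit of detection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LodResult:
    """Chosen LOD and per-candidate AUC (None where the truth was single-class)."""

    lod_percent: float
    auc_by_candidate: dict[float, float | None]

    @property
    def excluded(self) -> tuple[float, ...]:
        return tuple(c for c, a in self.auc_by_candidate.items() if a is None)


def one_point_auc(calls_positive: np.ndarray, truth_positive: np.ndarray) -> float | None:
    """AUC of a single binary operating point: (sensitivity + specificity)/2.

    Returns None if the truth is single-class (sensitivity or specificity
    undefined).
    """
    calls_positive = np.asarray(calls_positive, bool)
    truth_positive = np.asarray(truth_positive, bool)
    n_pos = int(truth_positive.sum())
    n_neg = int((~truth_positive).sum())
    if n_pos == 0 or n_neg == 0:
        return None
    sens = calls_positive[truth_positive].sum() / n_pos
    spec = (~calls_positive[~truth_positive]).sum() / n_neg
    return float((sens + spec) / 2.0)


def lod_by_roc(
    binary_scores: pd.DataFrame,
    candidate_lods: Sequence[float],
    positive_label: str = "positive",
) -> LodResult:
    """Visual limit of detection as the candidate %HbS cutoff maximizing AUC.

    For each candidate c the truth is %HbS >= c and the calls are the fixed
    visual binary scores; the AUC of this single operating point is
    (sensitivity + specificity)/2.  Ties break toward the lowest candidate
    (the LOD is the *lowest* detectable percentage); single-class candidates
    are excluded.
    """
    if len(candidate_lods) == 0:
        raise ValidationError("candidate LOD list is empty")
    validate_score_table(binary_scores)
    if "true_hbs_percent" not in binary_scores.columns:
        raise ValidationError("score table lacks true_hbs_percent")
    calls = (binary_scores["call"] == positive_label).to_numpy()
    hbs = binary_scores["true_hbs_percent"].to_numpy(dtype=np.float64)

    auc_map: dict[float, float | None] = {}
    for c in candidate_lods:
        auc_map[float(c)] = one_point_auc(calls, hbs >= c)
    defined = {c: a for c, a in auc_map.items() if a is not None}
    if not defined:
        raise DegenerateInputError("every candidate produced a single-class truth")
    best_auc = max(defined.values())
    lod = min(c for c, a in defined.items() if a == best_auc)
    return LodResult(lod_percent=lod, auc_by_candidate=auc_map)


# ---------------------------------------------------------------------------
# Readout time
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReadoutResult:
    """Per-class stable drying times and the total test time."""

    per_class_minutes: dict[str, float | None]
    incubation_minutes: float
    total_minutes: float | None

    @property
    def unstable_classes(self) -> tuple[str, ...]:
        return tuple(c for c, t in self.per_class_minutes.items() if t is None)


def readout_time(
    timed_scores: pd.DataFrame,
    incubation_minutes: float = 10.0,
) -> ReadoutResult:
    """Earliest reliable readout time from per-minute scoring of drying stains.

    ``timed_scores`` columns: ``minute, observer_id, class_label, correct``.
    For each class the stable time is the smallest recorded minute from
    which *every* observer scores correctly at that and all later minutes; a
    class that is never uniformly correct through the end of the window has
    no stable readout and the total is undefined (None).

    Total = incubation + max over classes of the stable drying time.
    """
    required = {"minute", "observer_id", "class_label", "correct"}
    missing = required - set(timed_scores.columns)
    if missing:
        raise ValidationError(f"timed score table missing columns: {sorted(missing)}")
    if timed_scores.empty:
        raise ValidationError("timed score table is empty")

    per_class: dict[str, float | None] = {}
    for cls, group in timed_scores.groupby("class_label", sort=True):
        ok_by_minute = group.groupby("minute")["correct"].all().sort_index()
        minutes = ok_by_minute.index.to_numpy(dtype=np.float64)
        ok = ok_by_minute.to_numpy(dtype=bool)
        # suffix_all_correct[i] == True iff correct from minutes[i] onward
        suffix = np.logical_and.accumulate(ok[::-1])[::-1]
        stable = minutes[suffix][0] if suffix.any() else None
        per_class[str(cls)] = None if stable is None else float(stable)

    if any(t is None for t in per_class.values()):
        total = None
    else:
        total = incubation_minutes + max(per_class.values())  # type: ignore[type-var]
    return ReadoutResult(
        per_class_minutes=per_class,
        incubation_minutes=incubation_minutes,
        total_minutes=total,
    )


# ---------------------------------------------------------------------------
# Formulation selection
# ---------------------------------------------------------------------------


def select_formulation(
    s_index_curves: Mapping[str, Mapping[float, float]],
    tol: float = 1e-9,
) -> str:
    """Choose the reducing-agent formulation from S-index vs %HbS curves.

    Lexicographic criterion: maximize the S-index separation S(20) − S(0)
    between HbS-free and 20% HbS samples; break ties by the most gradual
    change over 20–40% HbS, i.e. minimize |S(40) − S(20)|.  Remaining ties
    break alphabetically for determinism.
    """
    if not s_index_curves:
        raise ValidationError("no candidate curves")
    scored = []
    for name in sorted(s_index_curves):
        curve = s_index_curves[name]
        missing = {0.0, 20.0, 40.0} - {float(k) for k in curve}
        if missing:
            raise ValidationError(f"curve {name!r} missing %HbS grid points {sorted(missing)}")
        curve = {float(k): v for k, v in curve.items()}
        separation = curve[20.0] - curve[0.0]
        gradualness = abs(curve[40.0] - curve[20.0])
        scored.append((name, separation, gradualness))
    best_sep = max(s for _, s, _ in scored)
    contenders = [(name, grad) for name, sep, grad in scored if best_sep - sep <= tol]
    contenders.sort(key=lambda t: (t[1], t[0]))
    return contenders[0][0]
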