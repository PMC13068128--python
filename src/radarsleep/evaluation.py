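"""Evaluation: per-participant metrics, cohort summaries, correlations.

Metrics follow the per-participant protocol: a confusion matrix per
participant, six metrics derived from it (accuracy, F1, multiclass MCC,
precision, recall, specificity), and cohort aggregation as median with
interquartile range.  Precision/recall/F1/specificity use support-weighted
one-vs-rest averaging — the averaging mode under which recall is identical
to accuracy.  MCC uses the Gorodkin multiclass generalization, which
reduces exactly to the familiar binary formula on 2x2 matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hypnogram import Hypnogram, LabelScheme, get_scheme

__all__ = [
    "ConfusionMatrix",
    "ParticipantMetrics",
    "CohortSummary",
    "confusion_matrix",
    "participant_metrics",
    "cohort_summary",
    "cross_modal_correlation",
    "multiclass_mcc",
    "nn_recovery_mae_ms",
    "breath_count_error",
]


# ---------------------------------------------------------------------------
# confusion matrix


@dataclass
class ConfusionMatrix:
    """Integer counts with rows = true class, columns = predicted class."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square over the class list")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_percentages(self) -> np.ndarray:
        """Row-normalized percentages; rows with zero support are NaN."""
        sums = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(sums > 0, 100.0 * self.counts / sums, np.nan)

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.classes != other.classes:
            raise ValueError("cannot pool confusion matrices over different classes")
        return ConfusionMatrix(self.classes, self.counts + other.counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes),
                            columns=list(self.classes))


def confusion_matrix(true: Hypnogram, pred: Hypnogram,
                     scheme: str | LabelScheme | None = None) -> ConfusionMatrix:
    """Count epoch-wise agreement between a reference and predicted hypnogram."""
    if len(true) != len(pred):
        raise ValueError("hypnograms differ in length")
    scheme = get_scheme(scheme) if scheme is not None else true.scheme
    if true.scheme.name != scheme.name or pred.scheme.name != scheme.name:
        raise ValueError("hypnograms must already be in the requested scheme")
    k = len(scheme.classes)
    lut = {c: i for i, c in enumerate(scheme.classes)}
    counts = np.zeros((k, k), dtype=np.int64)
    for t, p in zip(true.stages, pred.stages):
        counts[lut[t], lut[p]] += 1
    return ConfusionMatrix(scheme.classes, counts)


# ---------------------------------------------------------------------------
# metrics


def multiclass_mcc(counts: np.ndarray) -> float:
    """Gorodkin's multiclass Matthews correlation coefficient.

    ``(c*s - sum_k p_k t_k) / sqrt((s^2 - sum p_k^2)(s^2 - sum t_k^2))``
    with c = trace, s = total, t_k = row sums, p_k = column sums.  Returns
    0.0 when a denominator factor vanishes (all-one-class edge case).
    """
    C = np.asarray(counts, dtype=float)
    s = C.sum()
    if s == 0:
        raise ValueError("empty confusion matrix")
    c = np.trace(C)
    t = C.sum(axis=1)
    p = C.sum(axis=0)
    cov_tp = c * s - t @ p
    cov_tt = s * s - t @ t
    cov_pp = s * s - p @ p
    denom = np.sqrt(cov_tt * cov_pp)
    if denom == 0:
        return 0.0
    return float(cov_tp / denom)


@dataclass
class ParticipantMetrics:
    """The six per-participant metrics (percent scales except MCC)."""

    accuracy: float
    f1: float
    mcc: float
    precision: float
    recall: float
    specificity: float
    n_epochs: int = 0
    participant_id: str = ""

    def as_dict(self) -> dict[str, float]:
        return {"accuracy": self.accuracy, "f1": self.f1, "mcc": self.mcc,
                "precision": self.precision, "recall": self.recall,
                "specificity": self.specificity}


def participant_metrics(cm: ConfusionMatrix, participant_id: str = "",
                        average: str = "weighted") -> ParticipantMetrics:
    """Compute the metric set from one participant's confusion matrix.

    ``average`` is "weighted" (support-weighted one-vs-rest, default) or
    "macro".  Per-class precision with zero predicted support counts as 0
    (with a warning).  Under support weighting, recall equals accuracy by
    construction.
    """
    if average not in ("weighted", "macro"):
        raise ValueError("average must be 'weighted' or 'macro'")
    C = cm.counts.astype(float)
    total = C.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    k = C.shape[0]
    tp = np.diag(C)
    support = C.sum(axis=1)          # true count per class
    predicted = C.sum(axis=0)
    fp = predicted - tp
    fn = support - tp
    tn = total - tp - fp - fn

    with np.errstate(invalid="ignore", divide="ignore"):
        prec_c = np.where(predicted > 0, tp / predicted, 0.0)
        rec_c = np.where(support > 0, tp / support, 0.0)
        spec_c = np.where(tn + fp > 0, tn / (tn + fp), 0.0)
        f1_c = np.where(prec_c + rec_c > 0, 2 * prec_c * rec_c / (prec_c + rec_c), 0.0)
    if np.any((predicted == 0) & (support > 0)):
        warnings.warn("class with zero predicted support: precision counted as 0",
                      stacklevel=2)

    if average == "weighted":
        w = support / total
    else:
        w = np.where(support > 0, 1.0, 0.0)
        w = w / max(w.sum(), 1.0)
    accuracy = float(tp.sum() / total)
    return ParticipantMetrics(
        accuracy=100.0 * accuracy,
        f1=100.0 * float(w @ f1_c),
        mcc=multiclass_mcc(C),
        precision=100.0 * float(w @ prec_c),
        recall=100.0 * float(w @ rec_c),
        specificity=100.0 * float(w @ spec_c),
        n_epochs=int(total),
        participant_id=participant_id,
    )


# ---------------------------------------------------------------------------
# cohort aggregation


@dataclass
class CohortSummary:
    """Median (IQR) of each metric across participants + pooled matrix."""

    label: str
    n_participants: int
    median: dict[str, float]
    iqr: dict[str, float]
    pooled_cm: ConfusionMatrix
    per_participant: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"metric": m, "median": self.median[m], "iqr": self.iqr[m]}
                for m in self.median]
        return pd.DataFrame(rows).assign(label=self.label)


def cohort_summary(metrics: list[ParticipantMetrics], cms: list[ConfusionMatrix],
                   label: str = "") -> CohortSummary:
    """Aggregate per-participant metrics to median with IQR (Q3 - Q1,
    linear-interpolation quantiles) and pool the confusion matrices."""
    if not metrics:
        raise ValueError("no participants to summarize")
    if len(cms) != len(metrics):
        raise ValueError("metrics and confusion matrices must align")
    table = pd.DataFrame([m.as_dict() | {"participant_id": m.participant_id}
                          for m in metrics])
    med, iqr = {}, {}
    for col in ("accuracy", "f1", "mcc", "precision", "recall", "specificity"):
        vals = table[col].to_numpy(dtype=float)
        med[col] = float(np.percentile(vals, 50))
        iqr[col] = float(np.percentile(vals, 75) - np.percentile(vals, 25))
    pooled = cms[0]
    for cm in cms[1:]:
        pooled = pooled + cm
    return CohortSummary(label, len(metrics), med, iqr, pooled, table)


# ---------------------------------------------------------------------------
# cross-modal feature correlation


def cross_modal_correlation(table_a: pd.DataFrame, table_b: pd.DataFrame,
                            feature_columns: list[str] | None = None,
                            min_epochs: int = 10) -> pd.DataFrame:
    """Participant-wise Pearson correlations between two modality tables.

    Both tables must share the participant/epoch grid.  Epochs flagged
    invalid in either table are excluded pairwise; features with fewer than
    ``min_epochs`` shared valid epochs or zero variance in either series
    get NaN.  Returns a tidy frame (participant_id, feature, r); cohort
    medians are ``result.groupby("feature")["r"].median()``.
    """
    from .features import FEATURE_COLUMNS
    cols = feature_columns or FEATURE_COLUMNS
    key = ["participant_id", "epoch_index"]
    merged = table_a.merge(table_b, on=key, suffixes=("_a", "_b"))
    if len(merged) == 0:
        raise ValueError("tables share no participant/epoch rows")
    rows = []
    for pid, grp in merged.groupby("participant_id"):
        ok_pair = grp["valid_a"].to_numpy(bool) & grp["valid_b"].to_numpy(bool)
        for feat in cols:
            a = grp[f"{feat}_a"].to_numpy(dtype=float)
            b = grp[f"{feat}_b"].to_numpy(dtype=float)
            ok = ok_pair & np.isfinite(a) & np.isfinite(b)
            r = np.nan
            if ok.sum() >= min_epochs:
                aa, bb = a[ok], b[ok]
                if np.std(aa) > 0 and np.std(bb) > 0:
                    r = float(np.corrcoef(aa, bb)[0, 1])
            rows.append({"participant_id": pid, "feature": feat, "r": r,
                         "n_epochs": int(ok.sum())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# recovery-error helpers (simulator ground truth vs pipeline output)


def _match_events(true_times: np.ndarray, est_times: np.ndarray,
                  tol_s: float) -> np.ndarray:
    """For each true event, the index of the nearest estimate within ``tol_s``
    (or -1).  Greedy nearest-neighbour matching on sorted times."""
    out = np.full(len(true_times), -1, dtype=int)
    if len(est_times) == 0:
        return out
    pos = np.searchsorted(est_times, true_times)
    for i, t in enumerate(true_times):
        best, best_d = -1, tol_s
        for j in (pos[i] - 1, pos[i]):
            if 0 <= j < len(est_times):
                d = abs(est_times[j] - t)
                if d <= best_d:
                    best, best_d = j, d
        out[i] = best
    return out


def nn_recovery_mae_ms(true_beats: np.ndarray, est_beats: np.ndarray,
                       tol_s: float = 0.2) -> float:
    """Mean absolute NN-interval error (ms) over consecutively matched beats."""
    m = _match_events(np.asarray(true_beats), np.asarray(est_beats), tol_s)
    errs = []
    for i in range(len(m) - 1):
        j0, j1 = m[i], m[i + 1]
        if j0 >= 0 and j1 > j0:
            nn_true = (true_beats[i + 1] - true_beats[i]) * 1000.0
            nn_est = (est_beats[j1] - est_beats[j0]) * 1000.0
            errs.append(abs(nn_est - nn_true))
    if not errs:
        return float("nan")
    return float(np.mean(errs))


def breath_count_error(true_breaths: np.ndarray, est_breaths: np.ndarray) -> float:
    """Relative breath-count error |n_est - n_true| / n_true."""
    n_true = len(true_breaths)
    if n_true == 0:
        raise ValueError("no true breaths")
    return abs(len(est_breaths) - n_true) / n_true
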