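"""Pixel -> image -> patient aggregation, evaluation metrics, and the
statistical comparisons used to contrast classifier arms.

Aggregation follows a strict-majority scheme: an image is called failing
when its probability exceeds 50% (strictly); the patient probability is the
fraction of failing image calls; the patient diagnosis is the majority vote
over the patient's images (strict, so a probability of exactly 0.5 under an
even image count resolves to non-failing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from .errors import DegenerateInputError, InvalidArgumentError, InvalidDataError
from .synthetic_data import is_failing_label

__all__ = [
    "PatientRecord",
    "MetricReport",
    "FoldAssignment",
    "image_prediction",
    "patient_probability",
    "patient_diagnosis",
    "build_patient_records",
    "confusion_metrics",
    "roc_auc",
    "cohens_kappa",
    "unpaired_ttest",
    "one_sample_ttest",
    "ks_compare",
    "ks_compare_roc",
    "crossval_split",
    "train_test_split_patients",
    "summarize_folds",
]


@dataclass
class PatientRecord:
    patient_id: str
    label: str
    image_probs: list[float]
    image_calls: list[bool] = field(default_factory=list)
    patient_prob: float = 0.0
    diagnosis: bool = False


@dataclass
class MetricReport:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    auc: float = float("nan")
    level: str = "image"
    fold_id: int | None = None

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "ppv": self.ppv, "auc": self.auc,
            "level": self.level, "fold_id": self.fold_id,
        }


@dataclass
class FoldAssignment:
    """Patient-level partition into folds, stratified by label."""

    folds: dict[str, int]

    def patients_in(self, fold: int) -> list[str]:
        return [p for p, f in self.folds.items() if f == fold]

    @property
    def n_folds(self) -> int:
        return len(set(self.folds.values()))


# ---------------------------------------------------------------------------
# aggregation


def image_prediction(prob: float, threshold: float = 0.5) -> bool:
    """Failing iff the image probability strictly exceeds the threshold."""
    if not 0.0 <= prob <= 1.0:
        raise InvalidArgumentError(f"probability {prob} outside [0, 1]")
    return bool(prob > threshold)


def patient_probability(image_calls) -> float:
    """Patient-level probability: the fraction of images called failing."""
    calls = list(image_calls)
    if not calls:
        raise DegenerateInputError("patient has no image calls")
    return float(np.mean([bool(c) for c in calls]))


def patient_diagnosis(patient_prob: float) -> bool:
    """Majority vote over a patient's images: failing iff strictly > 0.5.
    With 11 images per patient a tie cannot occur; with an even count a
    tie resolves to non-failing."""
    if not 0.0 <= patient_prob <= 1.0:
        raise InvalidArgumentError(f"patient probability {patient_prob} outside [0, 1]")
    return patient_prob > 0.5


def build_patient_records(
    image_probs: pd.DataFrame, labels: dict[str, str], threshold: float = 0.5
) -> list[PatientRecord]:
    """Assemble PatientRecords from a (patient_id, probability) table."""
    records = []
    for pid, grp in image_probs.groupby("patient_id", sort=True):
        probs = [float(v) for v in grp["probability"]]
        calls = [image_prediction(v, threshold) for v in probs]
        pprob = patient_probability(calls)
        records.append(
            PatientRecord(
                patient_id=str(pid),
                label=labels[str(pid)],
                image_probs=probs,
                image_calls=calls,
                patient_prob=pprob,
                diagnosis=patient_diagnosis(pprob),
            )
        )
    return records


# ---------------------------------------------------------------------------
# metrics


def confusion_metrics(calls, truths, positive_class=True, level: str = "image",
                      fold_id: int | None = None) -> MetricReport:
    """Confusion counts plus accuracy / sensitivity / specificity / PPV.

    Ratios with empty denominators are reported as NaN with a warning,
    never silently as zero.
    """
    calls = np.asarray(calls)
    truths = np.asarray(truths)
    if calls.shape != truths.shape:
        raise InvalidArgumentError("calls and truths differ in length")
    pos_c = calls == positive_class
    pos_t = truths == positive_class
    tp = int((pos_c & pos_t).sum())
    fp = int((pos_c & ~pos_t).sum())
    tn = int((~pos_c & ~pos_t).sum())
    fn = int((~pos_c & pos_t).sum())

    def ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (empty denominator); reported as NaN")
            return float("nan")
        return num / den

    return MetricReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=ratio(tp + tn, tp + tn + fp + fn, "accuracy"),
        sensitivity=ratio(tp, tp + fn, "sensitivity"),
        specificity=ratio(tn, tn + fp, "specificity"),
        ppv=ratio(tp, tp + fp, "ppv"),
        level=level, fold_id=fold_id,
    )


def roc_auc(scores, truths, positive_class=True):
    """ROC curve over all distinct score thresholds and trapezoidal AUC.

    Ties in scores move the curve diagonally (simultaneous threshold
    crossing).  Returns (fpr, tpr, thresholds, auc).
    """
    scores = np.asarray(scores, dtype=np.float64)
    y = (np.asarray(truths) == positive_class).astype(int)
    if np.unique(y).size < 2:
        raise InvalidDataError("both classes must be present for a ROC curve")
    fpr, tpr, thr = _sk_roc_curve(y, scores)
    return fpr, tpr, thr, float(_sk_auc(fpr, tpr))


def cohens_kappa(ratings_a, ratings_b) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e), with the
    expected agreement from the product of the raters' marginals."""
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape or a.size == 0:
        raise InvalidArgumentError("ratings must be equal-length non-empty vectors")
    cats = np.unique(np.concatenate([a, b]))
    n = a.size
    p_o = float((a == b).mean())
    p_e = float(sum((a == c).mean() * (b == c).mean() for c in cats))
    if p_e >= 1.0:
        raise DegenerateInputError("expected agreement is 1 (both raters constant and equal)")
    return (p_o - p_e) / (1.0 - p_e)


# ---------------------------------------------------------------------------
# hypothesis tests


def unpaired_ttest(sample_a, sample_b) -> tuple[float, int, float]:
    """Pooled-variance two-sample t-test; returns (t, df, two-sided p).

    Degenerate cases: zero pooled variance with equal means gives (0, df, 1);
    zero variance with unequal means is reported as an infinite t with p=0
    and a warning.
    """
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise InvalidArgumentError("each sample needs >= 2 observations")
    df = a.size + b.size - 2
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if sp2 == 0.0:
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        warnings.warn("zero pooled variance with unequal means; p reported as 0")
        return float(np.sign(a.mean() - b.mean()) * np.inf), df, 0.0
    res = sstats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), df, float(res.pvalue)


def one_sample_ttest(sample, reference_value: float) -> tuple[float, int, float]:
    """One-sample t-test of the sample mean against a constant."""
    a = np.asarray(sample, dtype=np.float64)
    if a.size < 2:
        raise InvalidArgumentError("sample needs >= 2 observations")
    df = a.size - 1
    if a.var(ddof=1) == 0.0:
        if a.mean() == reference_value:
            return 0.0, df, 1.0
        warnings.warn("zero sample variance with mean != reference; p reported as 0")
        return float(np.sign(a.mean() - reference_value) * np.inf), df, 0.0
    res = sstats.ttest_1samp(a, reference_value)
    return float(res.statistic), df, float(res.pvalue)


def ks_compare(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test: D = sup |F_a - F_b| with the
    asymptotic p-value."""
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise InvalidArgumentError("KS test requires non-empty samples")
    res = sstats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def ks_compare_roc(scores_a, truths_a, scores_b, truths_b, n_grid: int = 1001):
    """Compare two ROC curves by a KS test on their TPR values interpolated
    onto a common FPR grid.  (A statistically unconventional but explicit
    operationalization of 'comparing ROC curves'.)"""
    fa, ta, _, _ = roc_auc(scores_a, truths_a)
    fb, tb, _, _ = roc_auc(scores_b, truths_b)
    grid = np.linspace(0.0, 1.0, n_grid)
    ta_i = np.interp(grid, fa, ta)
    tb_i = np.interp(grid, fb, tb)
    return ks_compare(ta_i, tb_i)


# ---------------------------------------------------------------------------
# patient-level splits


def _patient_labels(patient_table: pd.DataFrame, schema: str = "v1") -> tuple[np.ndarray, np.ndarray]:
    pids = patient_table["patient_id"].to_numpy()
    col = f"label_{schema}" if f"label_{schema}" in patient_table.columns else "label"
    y = np.array([1 if is_failing_label(str(v)) else 0 for v in patient_table[col]])
    return pids, y


def crossval_split(patient_table: pd.DataFrame, n_folds: int = 3, rng_seed: int = 0,
                   schema: str = "v1") -> FoldAssignment:
    """Label-stratified patient-level partition into ``n_folds`` folds.
    All of a patient's images and patches follow the patient."""
    pids, y = _patient_labels(patient_table, schema)
    if n_folds > len(pids):
        raise InvalidArgumentError("more folds than patients")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=int(rng_seed) & 0x7FFFFFFF)
    folds: dict[str, int] = {}
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(len(pids)), y)):
        for i in test_idx:
            folds[str(pids[i])] = f
    return FoldAssignment(folds)


def train_test_split_patients(patient_table: pd.DataFrame, rng_seed: int = 0,
                              schema: str = "v1") -> tuple[list[str], list[str]]:
    """Seeded, label-stratified near-equal split: floor(n/2) patients train,
    the remainder test (209 patients -> 104 train / 105 test)."""
    pids, y = _patient_labels(patient_table, schema)
    n = len(pids)
    if n < 2:
        raise InvalidArgumentError("need >= 2 patients to split")
    rng = np.random.default_rng(rng_seed)
    n_train = n // 2
    # per-class quotas: floor of the proportional share, remainders to the
    # classes with the largest fractional part
    classes, counts = np.unique(y, return_counts=True)
    exact = counts * n_train / n
    quota = np.floor(exact).astype(int)
    rem = n_train - quota.sum()
    for c in np.argsort(-(exact - quota), kind="stable")[:rem]:
        quota[c] += 1
    train_ids: list[str] = []
    for c, q in zip(classes, quota):
        members = pids[y == c]
        picked = rng.permutation(len(members))[:q]
        train_ids.extend(str(members[i]) for i in picked)
    train_set = set(train_ids)
    test_ids = [str(p) for p in pids if str(p) not in train_set]
    return sorted(train_ids), sorted(test_ids)


def summarize_folds(reports: list[MetricReport]) -> dict:
    """Mean +/- sd across fold models, Table-style."""
    out = {}
    for name in ("accuracy", "sensitivity", "specificity", "ppv", "auc"):
        vals = np.array([getattr(r, name) for r in reports], dtype=np.float64)
        out[name] = {"mean": float(np.nanmean(vals)), "sd": float(np.nanstd(vals, ddof=1)) if len(vals) > 1 else 0.0}
    return out
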