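"""Validation apparatus: annotation alignment, classification metrics,
inter-rater agreement and Bland–Altman agreement on classified minutes.

Annotations are interval tracks (start, end, label, rater) aligned to the
1-s epoch grid by majority coverage; epochs whose majority label is
"other", "invisible" or "uncertain" — or with no coverage at all — are
excluded, and an epoch excluded by either series of a comparison is
dropped from both (pairwise exclusion). Metrics are one-vs-all per class;
the overall balanced accuracy is the unweighted mean of per-class recalls
and the overall F1 is prevalence-weighted, with typical free-living
behaviour proportions as default weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .classify import BEHAVIOURS, EXCLUDED, EpochLabelSeries

__all__ = [
    "AnnotationTrack",
    "Interval",
    "ConfusionMatrix",
    "MetricsReport",
    "BlandAltmanResult",
    "annotations_to_epochs",
    "confusion",
    "pool_confusions",
    "class_metrics",
    "interrater",
    "agreement_from_confusion",
    "bland_altman",
    "f1_from_precision_recall",
    "balanced_accuracy_from",
    "overall_balanced_accuracy",
    "round_half_away",
    "CLASS_ORDER",
    "NON_BEHAVIOUR_LABELS",
    "FREE_LIVING_WEIGHTS",
]

#: fixed class order for confusion matrices and reports
CLASS_ORDER = ("sedentary", "stand", "walk", "run", "stairs", "cycle", "move")

#: annotator categories that never count as behaviours
NON_BEHAVIOUR_LABELS = frozenset({"other", "invisible", "uncertain"})

#: default prevalence weights for the overall F1: share (%) of a 24-h day
#: spent in each behaviour under free-living wear by a reference method.
FREE_LIVING_WEIGHTS = {
    "sedentary": 75.7,
    "stand": 11.2,
    "move": 4.2,
    "walk": 5.3,
    "run": 0.4,
    "stairs": 0.5,
    "cycle": 2.0,
}


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (display convention for printed tables)."""
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(float(x))).copy_abs().quantize(q, rounding=ROUND_HALF_UP)
    return float(d.copy_negate() if x < 0 else d)


@dataclass(frozen=True)
class Interval:
    start_s: float
    end_s: float
    label: str
    rater: str = "r1"

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError(f"interval start {self.start_s} must precede end {self.end_s}")


@dataclass
class AnnotationTrack:
    """Interval annotations, possibly from several raters."""

    intervals: list[Interval]

    def raters(self) -> list[str]:
        return sorted({iv.rater for iv in self.intervals})

    def for_rater(self, rater: str) -> "AnnotationTrack":
        return AnnotationTrack([iv for iv in self.intervals if iv.rater == rater])

    def validate_non_overlapping(self) -> None:
        for rater in self.raters():
            ivs = sorted(self.for_rater(rater).intervals, key=lambda iv: iv.start_s)
            for a, b in zip(ivs, ivs[1:]):
                if b.start_s < a.end_s - 1e-9:
                    raise ValueError(
                        f"overlapping intervals for rater {rater}: "
                        f"[{a.start_s}, {a.end_s}) and [{b.start_s}, {b.end_s})"
                    )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "start_s": [iv.start_s for iv in self.intervals],
                "end_s": [iv.end_s for iv in self.intervals],
                "label": [iv.label for iv in self.intervals],
                "rater": [iv.rater for iv in self.intervals],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "AnnotationTrack":
        frame = pd.read_csv(path)
        return cls(
            [
                Interval(float(r.start_s), float(r.end_s), str(r.label), str(r.rater))
                for r in frame.itertuples()
            ]
        )


def annotations_to_epochs(
    track: AnnotationTrack, t0_s: float, n_epochs: int, rater: str | None = None
) -> EpochLabelSeries:
    """Majority-coverage alignment of intervals onto the 1-s epoch grid.

    Each epoch takes the label covering most of it; transitions inherit
    the majority behaviour. Epochs whose majority label is a
    non-behaviour category, or with no coverage, become ``excluded``.
    """
    sub = track if rater is None else track.for_rater(rater)
    sub.validate_non_overlapping()
    labels = []
    for i in range(n_epochs):
        e0, e1 = t0_s + i, t0_s + i + 1
        cover: dict[str, float] = {}
        for iv in sub.intervals:
            ov = min(e1, iv.end_s) - max(e0, iv.start_s)
            if ov > 0:
                cover[iv.label] = cover.get(iv.label, 0.0) + ov
        if not cover:
            labels.append(EXCLUDED)
            continue
        best = max(cover, key=lambda k: cover[k])
        labels.append(EXCLUDED if best in NON_BEHAVIOUR_LABELS else best)
    return EpochLabelSeries(labels, t0_s)


@dataclass
class ConfusionMatrix:
    """K×K counts, rows = true behaviour, columns = predicted."""

    counts: pd.DataFrame

    @property
    def classes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts.to_numpy()) / self.total)

    def row_percent(self) -> pd.DataFrame:
        arr = self.counts.to_numpy(dtype=float)
        sums = arr.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(sums > 0, 100.0 * arr / sums, np.nan)
        return pd.DataFrame(pct, index=self.counts.index, columns=self.counts.columns)


def _ordered_classes(present: set[str]) -> list[str]:
    return [c for c in CLASS_ORDER if c in present]


def confusion(true: EpochLabelSeries, pred: EpochLabelSeries) -> ConfusionMatrix:
    """Epoch-wise confusion matrix with pairwise exclusion."""
    if len(true) != len(pred):
        raise ValueError(f"length mismatch: {len(true)} true vs {len(pred)} predicted epochs")
    pairs = [
        (t, p)
        for t, p in zip(true.labels, pred.labels)
        if t != EXCLUDED and p != EXCLUDED
    ]
    if not pairs:
        raise ValueError("no comparable epochs after exclusions")
    present = {t for t, _ in pairs} | {p for _, p in pairs}
    classes = _ordered_classes(present)
    mat = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in pairs:
        mat.loc[t, p] += 1
    return ConfusionMatrix(mat)


def pool_confusions(matrices: list[ConfusionMatrix]) -> ConfusionMatrix:
    """Pool across participants by summing counts (union of classes)."""
    if not matrices:
        raise ValueError("no confusion matrices to pool")
    present: set[str] = set()
    for m in matrices:
        present |= set(m.classes)
    classes = _ordered_classes(present)
    out = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for m in matrices:
        out.loc[m.counts.index, m.counts.columns] += m.counts
    return ConfusionMatrix(out)


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def balanced_accuracy_from(recall: float, specificity: float) -> float:
    return (recall + specificity) / 2.0


def overall_balanced_accuracy(recalls) -> float:
    """Unweighted mean of per-class recalls."""
    r = list(recalls)
    if not r:
        raise ValueError("no recalls")
    return float(np.mean(r))


@dataclass
class MetricsReport:
    """Per-class one-vs-all metrics and overall summaries."""

    per_class: pd.DataFrame  # rows = classes; precision/recall/specificity/f1/balanced_accuracy
    overall_balanced_accuracy: float
    weighted_f1: float
    weights: dict

    def to_frame(self) -> pd.DataFrame:
        return self.per_class


def class_metrics(cm: ConfusionMatrix, weights: dict | None = None) -> MetricsReport:
    """One-vs-all precision/recall/specificity/F1/balanced accuracy.

    Classes with zero true instances are omitted from the report (absent,
    not zero). ``weights`` are prevalences for the overall weighted F1,
    renormalised over the classes actually present; default:
    :data:`FREE_LIVING_WEIGHTS`.
    """
    arr = cm.counts.to_numpy(dtype=float)
    if arr.sum() == 0:
        raise ValueError("empty confusion matrix")
    total = arr.sum()
    rows = []
    for k, cls in enumerate(cm.classes):
        tp = arr[k, k]
        fn = arr[k, :].sum() - tp
        fp = arr[:, k].sum() - tp
        tn = total - tp - fn - fp
        if tp + fn == 0:
            continue  # no true instances: metric undefined, report absent
        precision = tp / (tp + fp) if tp + fp > 0 else 0.0
        recall = tp / (tp + fn)
        specificity = tn / (tn + fp) if tn + fp > 0 else 0.0
        rows.append(
            {
                "class": cls,
                "precision": precision,
                "recall": recall,
                "specificity": specificity,
                "f1": f1_from_precision_recall(precision, recall),
                "balanced_accuracy": balanced_accuracy_from(recall, specificity),
            }
        )
    per_class = pd.DataFrame(rows).set_index("class")
    oba = overall_balanced_accuracy(per_class["recall"])
    wsrc = weights or FREE_LIVING_WEIGHTS
    used = {c: wsrc.get(c, 0.0) for c in per_class.index}
    wsum = sum(used.values())
    if wsum <= 0:
        used = {c: 1.0 for c in per_class.index}
        wsum = float(len(used))
    wf1 = sum(used[c] * per_class.loc[c, "f1"] for c in per_class.index) / wsum
    return MetricsReport(per_class, float(oba), float(wf1), used)


def agreement_from_confusion(counts: np.ndarray) -> tuple[float, float]:
    """Observed agreement and Cohen's kappa from a square label-pair table."""
    arr = np.asarray(counts, dtype=float)
    n = arr.sum()
    if n == 0:
        raise ValueError("no comparable epochs")
    p_o = np.trace(arr) / n
    p_e = float((arr.sum(axis=1) / n) @ (arr.sum(axis=0) / n))
    kappa = 0.0 if np.isclose(p_e, 1.0) else (p_o - p_e) / (1.0 - p_e)
    return float(p_o), float(kappa)


def interrater(
    track_a: AnnotationTrack,
    track_b: AnnotationTrack,
    t0_s: float,
    n_epochs: int,
) -> tuple[float, float]:
    """Percent agreement and Cohen's kappa between two raters.

    Both tracks are epoch-aligned; epochs excluded by either rater are
    dropped pairwise. Chance agreement for kappa comes from the marginal
    label distributions of the compared epochs.
    """
    a = annotations_to_epochs(track_a, t0_s, n_epochs)
    b = annotations_to_epochs(track_b, t0_s, n_epochs)
    pairs = [
        (x, y)
        for x, y in zip(a.labels, b.labels)
        if x != EXCLUDED and y != EXCLUDED
    ]
    if not pairs:
        raise ValueError("no comparable epochs after exclusions")
    classes = sorted({x for x, _ in pairs} | {y for _, y in pairs})
    idx = {c: i for i, c in enumerate(classes)}
    mat = np.zeros((len(classes), len(classes)))
    for x, y in pairs:
        mat[idx[x], idx[y]] += 1
    return agreement_from_confusion(mat)


@dataclass
class BlandAltmanResult:
    """Agreement between paired per-participant measurements (minutes)."""

    mean_bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    relative_bias_pct: float | None  # None when the reference mean is 0
    n_pairs: int

    def display_relative_pct(self) -> float | None:
        if self.relative_bias_pct is None:
            return None
        return round_half_away(self.relative_bias_pct, 0)


def bland_altman(values_test, values_ref) -> BlandAltmanResult:
    """Mean bias, sample-SD limits of agreement and relative bias.

    ``diffs = test − ref``; limits of agreement are
    ``bias ± 1.96 · SD(diffs)`` (SD with n−1); relative bias is
    ``100 · bias / mean(ref)``, undefined (None) when the reference mean
    is zero.
    """
    test = np.asarray(list(values_test), dtype=float)
    ref = np.asarray(list(values_ref), dtype=float)
    if test.shape != ref.shape:
        raise ValueError("paired lists must have equal length")
    n = len(test)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    diffs = test - ref
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    ref_mean = float(ref.mean())
    rel = None if np.isclose(ref_mean, 0.0) else 100.0 * bias / ref_mean
    return BlandAltmanResult(
        mean_bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        relative_bias_pct=rel,
        n_pairs=n,
    )
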