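"""Performance metrics, the storage-day ANOVA/Tukey analysis, and the
stratified calibration/test partition.

Regression models are scored by R-squared and RMSE; classifiers by overall
accuracy, computed from the confusion matrix as trace/total x 100 (the
per-class true/false positive/negative counts are exposed through the
one-vs-rest reduction).  The storage-time effect on the destructive quality
attributes is assessed by one-way ANOVA with Tukey HSD compact-letter
grouping at alpha = 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "AnovaTable",
    "Partition",
    "regression_metrics",
    "classification_metrics",
    "one_way_anova",
    "tukey_groups",
    "split_dataset",
]


@dataclass
class ConfusionMatrix:
    """K x K count matrix; labels ordered (by storage day for this study)."""

    counts: np.ndarray
    labels: tuple

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("confusion matrix must be K x K with K labels")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @classmethod
    def from_labels(cls, observed, predicted, labels: Sequence | None = None) -> "ConfusionMatrix":
        observed = np.asarray(observed)
        predicted = np.asarray(predicted)
        if observed.shape != predicted.shape:
            raise ValueError("observed and predicted lengths differ")
        if labels is None:
            labels = np.unique(np.concatenate([observed, predicted]))
        index = {lab: i for i, lab in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=int)
        for o, p in zip(observed, predicted):
            counts[index[o], index[p]] += 1
        return cls(counts, tuple(labels))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def per_class(self) -> pd.DataFrame:
        """One-vs-rest tp/fp/fn/tn counts per class."""
        tp = np.diag(self.counts)
        fp = self.counts.sum(axis=0) - tp
        fn = self.counts.sum(axis=1) - tp
        tn = self.total - tp - fp - fn
        return pd.DataFrame(
            {"tp": tp, "fp": fp, "fn": fn, "tn": tn},
            index=pd.Index(self.labels, name="class"),
        )


@dataclass
class MetricsReport:
    """R-squared / RMSE / accuracy bundle for one evaluation stage."""

    stage: str                       # calibration | cross-validation | test
    n: int
    r2: float | None = None          # dimensionless, <= 1
    rmse: float | None = None        # response units
    accuracy: float | None = None    # percent


def regression_metrics(observed, predicted, stage: str = "test") -> MetricsReport:
    """R-squared = 1 - SS_res/SS_tot and RMSE = sqrt(mean squared error)."""
    yo = np.asarray(observed, dtype=float).ravel()
    yp = np.asarray(predicted, dtype=float).ravel()
    if yo.shape != yp.shape or yo.size < 2:
        raise ValueError("observed and predicted must share a length of at least 2")
    rmse = float(np.sqrt(np.mean((yo - yp) ** 2)))
    ss_tot = float(np.sum((yo - yo.mean()) ** 2))
    if ss_tot == 0:
        warnings.warn("constant observed values: R-squared undefined")
        r2 = float("nan")
    else:
        r2 = 1.0 - float(np.sum((yo - yp) ** 2)) / ss_tot
    return MetricsReport(stage=stage, n=yo.size, r2=r2, rmse=rmse)


def classification_metrics(confusion: ConfusionMatrix, stage: str = "test") -> MetricsReport:
    """Overall accuracy = 100 x correct/total from the confusion matrix."""
    if confusion.total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = 100.0 * float(np.trace(confusion.counts)) / confusion.total
    return MetricsReport(stage=stage, n=confusion.total, accuracy=accuracy)


@dataclass
class AnovaTable:
    """One-way decomposition: time (between-day), error (within-day), total."""

    ss_time: float
    df_time: int
    ss_error: float
    df_error: int
    f: float
    p: float

    @property
    def ms_time(self) -> float:
        return self.ss_time / self.df_time

    @property
    def ms_error(self) -> float:
        return self.ss_error / self.df_error

    @property
    def ss_total(self) -> float:
        return self.ss_time + self.ss_error

    def to_frame(self, attribute: str = "") -> pd.DataFrame:
        rows = [
            (attribute, "Time (day)", self.ss_time, self.df_time, self.ms_time, self.f, self.p),
            (attribute, "Error", self.ss_error, self.df_error, self.ms_error, np.nan, np.nan),
            (attribute, "Total", self.ss_total, self.df_time + self.df_error,
             np.nan, np.nan, np.nan),
        ]
        return pd.DataFrame(rows, columns=[
            "attribute", "source", "sum_sq", "df", "mean_sq", "F", "p"])


def one_way_anova(values, group_labels) -> AnovaTable:
    """Standard one-way ANOVA of ``values`` against categorical groups."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(group_labels)
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    if counts.min() < 2:
        raise ValueError(f"groups with fewer than two members: {uniq[counts < 2]}")
    grand = values.mean()
    ss_time = float(sum(
        n_g * (values[groups == g].mean() - grand) ** 2
        for g, n_g in zip(uniq, counts)))
    ss_error = float(sum(
        ((values[groups == g] - values[groups == g].mean()) ** 2).sum()
        for g in uniq))
    df_time = len(uniq) - 1
    df_error = values.size - len(uniq)
    ms_error = ss_error / df_error
    f = (ss_time / df_time) / ms_error if ms_error > 0 else float("inf")
    p = float(stats.f.sf(f, df_time, df_error))
    return AnovaTable(ss_time, df_time, ss_error, df_error, float(f), p)


def tukey_groups(values, group_labels, alpha: float = 0.05) -> dict:
    """Tukey HSD compact letter display.

    Groups sharing at least one letter are not significantly different at
    ``alpha`` by the studentized-range test.  Letters are assigned by the
    insert-and-absorb algorithm on groups ordered by decreasing mean.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(group_labels)
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    if counts.min() < 2:
        raise ValueError(f"groups with fewer than two members: {uniq[counts < 2]}")
    means = {g: values[groups == g].mean() for g in uniq}

    if np.ptp(values) == 0:
        return {g: "a" for g in uniq}       # no variance at all: one shared letter

    res = pairwise_tukeyhsd(values, groups, alpha=alpha)
    different = set()
    for (g1, g2), reject in zip(
            [(res.groupsunique[i], res.groupsunique[j])
             for i in range(len(res.groupsunique))
             for j in range(i + 1, len(res.groupsunique))],
            res.reject):
        if reject:
            different.add(frozenset((g1, g2)))

    ordered = sorted(uniq, key=lambda g: -means[g])
    letter_sets: list[set] = []             # each set = groups sharing one letter
    for g in ordered:
        placed = False
        for s in letter_sets:
            if all(frozenset((g, other)) not in different for other in s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    # absorb redundant letters
    letter_sets = [s for i, s in enumerate(letter_sets)
                   if not any(i != j and s <= t for j, t in enumerate(letter_sets))]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in uniq}
    for letter, s in zip(alphabet, letter_sets):
        for g in s:
            out[g] += letter
    return {g: "".join(sorted(out[g])) for g in uniq}


@dataclass(frozen=True)
class Partition:
    """Disjoint, covering calibration/test id sets, stratified by day."""

    calibration_ids: tuple
    test_ids: tuple
    seed: int | None = None

    def __post_init__(self) -> None:
        if set(self.calibration_ids) & set(self.test_ids):
            raise ValueError("calibration and test sets overlap")


def split_dataset(
    sample_ids: Sequence,
    day_labels: Sequence,
    fractions: tuple[float, float] = (0.7, 0.3),
    seed: int | None = None,
) -> Partition:
    """Stratified-by-day random split into calibration and test sets.

    The total calibration count is ``round(f_cal * N)``; per-day counts
    deviate from perfect proportionality by at most one (largest-remainder
    apportionment with seeded tie-breaking).  120 samples over 8 balanced
    days give the canonical 84/36 split.
    """
    f_cal, f_test = fractions
    if not (0 < f_cal < 1 and 0 < f_test < 1):
        raise ValueError("fractions must lie in (0, 1)")
    if abs(f_cal + f_test - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    ids = np.asarray(sample_ids)
    days = np.asarray(day_labels)
    if ids.shape != days.shape:
        raise ValueError("sample ids and day labels disagree in length")
    n = ids.size
    n_cal = int(round(f_cal * n))
    rng = np.random.default_rng(seed)

    uniq = np.unique(days)
    per_day = {d: int(np.floor(f_cal * (days == d).sum())) for d in uniq}
    shortfall = n_cal - sum(per_day.values())
    remainders = {d: f_cal * (days == d).sum() - per_day[d] for d in uniq}
    tiebreak = {d: rng.random() for d in uniq}
    for d in sorted(uniq, key=lambda d: (-remainders[d], tiebreak[d]))[:shortfall]:
        per_day[d] += 1

    cal: list = []
    test: list = []
    for d in uniq:
        members = ids[days == d]
        order = rng.permutation(members.size)
        cal.extend(members[order[: per_day[d]]])
        test.extend(members[order[per_day[d]:]])
    return Partition(tuple(cal), tuple(test), seed=seed)
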