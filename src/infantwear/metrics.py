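"""Classification metrics and wear-minute comparison tables.

Non-wear is the positive class throughout: a true positive is a non-wear
minute classified as non-wear.  Ratios with a zero denominator are reported
as missing (NaN), never as 0, and missing values are excluded from fold
averages with a logged count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NONWEAR, WEAR = "nonwear", "wear"
METRICS = ("accuracy", "sensitivity", "specificity", "ppv", "npv", "f1")


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


@dataclass(frozen=True)
class ConfusionSummary:
    """Confusion counts (non-wear positive) and derived proportions."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return _ratio(self.tp + self.tn, self.n)

    @property
    def sensitivity(self) -> float:
        return _ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return _ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return _ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float:
        return _ratio(self.tn, self.tn + self.fn)

    @property
    def f1(self) -> float:
        """Harmonic mean of sensitivity and PPV; missing when either is."""
        s, p = self.sensitivity, self.ppv
        if math.isnan(s) or math.isnan(p):
            return math.nan
        return _ratio(2 * s * p, s + p) if (s + p) > 0 else math.nan

    def metric(self, name: str) -> float:
        return getattr(self, name)


def confusion_metrics(predictions: Iterable, criterion: Iterable) -> ConfusionSummary:
    """Confusion counts from paired labels (missing pairs excluded).

    Raises if no paired, non-missing labels remain.
    """
    pred = pd.Series(list(predictions), dtype=object)
    crit = pd.Series(list(criterion), dtype=object)
    if len(pred) != len(crit):
        raise ValueError("predictions and criterion must have the same length")
    ok = pred.notna() & crit.notna()
    pred, crit = pred[ok], crit[ok]
    if not len(pred):
        raise ValueError("no paired non-missing labels")
    if not set(pred.unique()) <= {NONWEAR, WEAR} or not set(crit.unique()) <= {NONWEAR, WEAR}:
        raise ValueError(f"labels must be '{WEAR}' or '{NONWEAR}'")
    tp = int(((pred == NONWEAR) & (crit == NONWEAR)).sum())
    fp = int(((pred == NONWEAR) & (crit == WEAR)).sum())
    tn = int(((pred == WEAR) & (crit == WEAR)).sum())
    fn = int(((pred == WEAR) & (crit == NONWEAR)).sum())
    return ConfusionSummary(tp=tp, fp=fp, tn=tn, fn=fn)


def summarize_folds(folds: Sequence[ConfusionSummary]) -> pd.DataFrame:
    """Unweighted (macro) mean of each metric over folds, with the per-fold
    (min, max) range.  Folds where a metric is undefined are excluded from
    that metric's average; the exclusion count is logged and reported.
    """
    if not folds:
        raise ValueError("at least one fold is required")
    rows = []
    for m in METRICS:
        vals = np.array([f.metric(m) for f in folds], dtype=float)
        defined = vals[~np.isnan(vals)]
        n_excluded = int(np.isnan(vals).sum())
        if n_excluded:
            logger.info("metric %s undefined in %d fold(s); excluded from mean", m, n_excluded)
        rows.append(
            {
                "metric": m,
                "mean": float(defined.mean()) if len(defined) else math.nan,
                "min": float(defined.min()) if len(defined) else math.nan,
                "max": float(defined.max()) if len(defined) else math.nan,
                "n_folds": len(defined),
                "n_excluded": n_excluded,
            }
        )
    return pd.DataFrame(rows).set_index("metric")


def pooled_confusion(folds: Sequence[ConfusionSummary]) -> ConfusionSummary:
    """Sum confusion counts over folds (micro/pooled view)."""
    return ConfusionSummary(
        tp=sum(f.tp for f in folds),
        fp=sum(f.fp for f in folds),
        tn=sum(f.tn for f in folds),
        fn=sum(f.fn for f in folds),
    )


def _per_participant_minutes(labels: pd.DataFrame) -> pd.DataFrame:
    counts = (
        labels.groupby("participant_id")["label"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=[NONWEAR, WEAR], fill_value=0)
    )
    return counts


def wear_minutes_table(
    methods: Mapping[str, pd.DataFrame],
    criterion: pd.DataFrame,
) -> pd.DataFrame:
    """Wear/non-wear minute tallies per method versus the criterion.

    Every input frame needs columns ``participant_id``, ``minute_start``
    and ``label`` ('wear'/'nonwear').  Output has one row per method (the
    criterion first): totals summed over participants, per-participant
    mean (SD), and the absolute percent difference from the criterion
    total, rounded to 0.1%.

    Raises if a method is missing a participant present in the criterion.
    """
    crit_counts = _per_participant_minutes(criterion)
    crit_total = crit_counts.sum()

    def row(name: str, counts: pd.DataFrame, is_criterion: bool) -> dict:
        total = counts.sum()
        out = {
            "method": name,
            "total_nonwear": int(total[NONWEAR]),
            "total_wear": int(total[WEAR]),
            "mean_nonwear": round(float(counts[NONWEAR].mean()), 1),
            "sd_nonwear": round(float(counts[NONWEAR].std(ddof=1)), 1) if len(counts) > 1 else math.nan,
            "mean_wear": round(float(counts[WEAR].mean()), 1),
            "sd_wear": round(float(counts[WEAR].std(ddof=1)), 1) if len(counts) > 1 else math.nan,
        }
        for cls in (NONWEAR, WEAR):
            if is_criterion or crit_total[cls] == 0:
                out[f"pct_diff_{cls}"] = math.nan
            else:
                out[f"pct_diff_{cls}"] = round(
                    abs(total[cls] - crit_total[cls]) / crit_total[cls] * 100.0, 1
                )
        return out

    rows = [row("criterion", crit_counts, True)]
    crit_pids = set(crit_counts.index)
    for name, frame in methods.items():
        counts = _per_participant_minutes(frame)
        missing = crit_pids - set(counts.index)
        if missing:
            raise ValueError(f"method {name!r} is missing participant(s) {sorted(missing)}")
        counts = counts.reindex(sorted(crit_pids | set(counts.index)), fill_value=0)
        rows.append(row(name, counts, False))
    return pd.DataFrame(rows).set_index("method")


def stratified_wear_minutes(
    methods: Mapping[str, pd.DataFrame],
    criterion: pd.DataFrame,
    annotations: pd.DataFrame,
    by: str = "state",
) -> dict[str, pd.DataFrame]:
    """Wear-minute tables restricted to each value of an annotation column.

    ``annotations`` carries ``participant_id``, ``minute_start`` and the
    stratification column (e.g. 'state' with values 'sleep'/'wake'); only
    annotated minutes are counted.
    """
    key = ["participant_id", "minute_start"]
    ann = annotations.dropna(subset=[by])[key + [by]]
    out: dict[str, pd.DataFrame] = {}
    for value, sub in ann.groupby(by):
        keys = sub[key]
        crit = criterion.merge(keys, on=key, how="inner")
        meth = {name: frame.merge(keys, on=key, how="inner") for name, frame in methods.items()}
        out[str(value)] = wear_minutes_table(meth, crit)
    return out
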