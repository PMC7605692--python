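"""Consecutive-zero-counts baseline for wear/non-wear classification.

The comparison method from the infant actigraphy literature: every maximal
run of consecutive zero-count 60-s epochs at least ``min_run`` minutes long
is labeled non-wear (in the source protocols this also removes non-waking
time); everything else, including isolated zeros in shorter runs, is wear.
The combined-site rule labels an epoch wear if *either* site is wear.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

NONWEAR, WEAR = "nonwear", "wear"


def zero_run_labels(counts: Sequence[float], min_run: int = 2) -> np.ndarray:
    """Label an epoch count vector by the consecutive-zero-counts rule.

    Returns an object array of 'wear'/'nonwear', one per epoch.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1:
        raise ValueError("counts must be one-dimensional")
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    labels = np.full(c.size, WEAR, dtype=object)
    if not c.size:
        return labels
    zero = c == 0
    # maximal zero runs via boundaries of the zero mask
    edges = np.flatnonzero(np.diff(np.concatenate(([0], zero.view(np.int8), [0]))))
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start >= min_run:
            labels[start:stop] = NONWEAR
    return labels


def classify_zero_runs(series: pd.DataFrame, min_run: int = 2) -> pd.DataFrame:
    """Apply the zero-run rule to a count series frame.

    ``series`` needs ``epoch_start`` and ``vm_counts`` columns (extra
    identifier columns such as ``participant_id``/``site`` are carried
    through).  Returns the frame with a ``label`` column and
    ``provenance='zero_counts'``.
    """
    out = series.copy()
    out["label"] = zero_run_labels(out["vm_counts"].to_numpy(), min_run=min_run)
    out["provenance"] = "zero_counts"
    return out


def combine_sites(hip: pd.DataFrame, ankle: pd.DataFrame) -> pd.DataFrame:
    """Combined-site decision: wear iff at least one site is wear.

    Both frames need ``epoch_start`` and ``label`` columns with identical
    timestamps in identical order.
    """
    h = hip.reset_index(drop=True)
    a = ankle.reset_index(drop=True)
    if len(h) != len(a):
        raise ValueError(f"site series lengths differ ({len(h)} vs {len(a)})")
    ts_h = pd.to_datetime(h["epoch_start"]).to_numpy()
    ts_a = pd.to_datetime(a["epoch_start"]).to_numpy()
    mismatch = ts_h != ts_a
    if mismatch.any():
        i = int(np.flatnonzero(mismatch)[0])
        raise ValueError(
            f"timestamp mismatch at epoch {i}: hip {ts_h[i]} vs ankle {ts_a[i]}"
        )
    wear = (h["label"].to_numpy(object) == WEAR) | (a["label"].to_numpy(object) == WEAR)
    out = pd.DataFrame({"epoch_start": ts_h, "label": np.where(wear, WEAR, NONWEAR)})
    if "participant_id" in h.columns:
        out.insert(0, "participant_id", h["participant_id"].to_numpy())
    out["provenance"] = "zero_counts_combined"
    return out
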