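"""Minute-level features from raw triaxial acceleration.

Converts raw (typically 30 Hz) accelerometer samples into the per-minute
feature table used by the wear/non-wear classifiers: per-axis means, vector
magnitude (VM), per-axis inclination angles, and a sliding coefficient of
variation (CV) over 2--5 minute windows.

Conventions
-----------
* All accelerations are in milli-g; a stationary device reads VM ~= 1000 mg.
* VM and inclination angles are computed per sample and *then* averaged into
  one-minute epochs aligned to wall-clock minute boundaries; partial leading
  and trailing minutes are dropped.
* The sliding CV of an anchor minute is the minimum of scale*(sd/|mean|)
  over every window of ``w`` consecutive minutes that contains the anchor
  (``w`` placements).  Anchors for which not all placements exist (the first
  and last ``w - 1`` minutes) are missing.  ``scale`` defaults to 100, i.e.
  a true percent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

logger = logging.getLogger(__name__)

SITES = ("hip", "ankle")
AXES = ("x", "y", "z")
CV_CHANNELS = ("x", "y", "z", "vm")
DEFAULT_WINDOWS = (2, 3, 4, 5)
#: device dynamic range, milli-g (+-8 g)
DYNAMIC_RANGE_MG = 8000.0

LABEL_COLUMNS = ("wear", "state", "location")


@dataclass
class RawTriaxialSeries:
    """One participant x site recording of equally spaced triaxial samples.

    ``samples`` is an ``(n, 3)`` float array in milli-g, ordered in time and
    starting at ``start_time`` with spacing ``1 / sample_rate`` seconds.
    """

    participant_id: str
    site: str
    start_time: pd.Timestamp
    samples: np.ndarray
    sample_rate: float = 30.0

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValueError(f"site must be one of {SITES}, got {self.site!r}")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        self.start_time = pd.Timestamp(self.start_time)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must have shape (n, 3)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if np.abs(self.samples).max(initial=0.0) > DYNAMIC_RANGE_MG:
            raise ValueError(
                f"samples exceed the +-{DYNAMIC_RANGE_MG:.0f} milli-g dynamic range"
            )

    def __len__(self) -> int:
        return len(self.samples)


def compute_vm(x, y, z):
    """Euclidean norm sqrt(x^2 + y^2 + z^2) of the three axes (milli-g)."""
    x, y, z = (np.asarray(a, dtype=float) for a in (x, y, z))
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y)) and np.all(np.isfinite(z))):
        raise ValueError("compute_vm requires finite inputs")
    out = np.sqrt(x * x + y * y + z * z)
    return float(out) if out.ndim == 0 else out


def compute_inclination(x, y, z, axis: str):
    """Angle (degrees, in [0, 180]) between one device axis and the measured
    acceleration vector: acos(a_axis / VM).

    Undefined (NaN) where VM == 0.
    """
    axis = axis.lower()
    if axis not in AXES:
        raise ValueError(f"axis must be one of {AXES}, got {axis!r}")
    x, y, z = (np.asarray(a, dtype=float) for a in (x, y, z))
    vm = compute_vm(x, y, z)
    comp = {"x": x, "y": y, "z": z}[axis]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(vm > 0, comp / np.where(vm > 0, vm, 1.0), np.nan)
    ang = np.degrees(np.arccos(np.clip(ratio, -1.0, 1.0)))
    return float(ang) if np.ndim(ang) == 0 else ang


def _minute_alignment(series: RawTriaxialSeries) -> tuple[int, pd.Timestamp, int]:
    """Offset (samples) to the first wall-clock minute boundary, its
    timestamp, and samples per minute."""
    spm = int(round(series.sample_rate * 60))
    start = series.start_time
    boundary = start.ceil("min") if start != start.floor("min") else start
    offset = int(np.ceil((boundary - start).total_seconds() * series.sample_rate - 1e-9))
    return offset, boundary, spm


def aggregate_minutes(series: RawTriaxialSeries) -> pd.DataFrame:
    """Collapse a raw series into per-minute means (CV columns not filled).

    VM and per-axis inclination are computed per sample before averaging.
    Only complete clock minutes are emitted; a series shorter than one
    complete minute yields an empty frame with a warning.
    """
    offset, first_minute, spm = _minute_alignment(series)
    n_minutes = max(0, (len(series) - offset)) // spm
    if n_minutes == 0:
        warnings.warn(
            f"series {series.participant_id}/{series.site} shorter than one "
            "complete clock minute; no epochs emitted",
            stacklevel=2,
        )
        return _empty_minute_frame()

    block = series.samples[offset : offset + n_minutes * spm]
    shaped = block.reshape(n_minutes, spm, 3)
    vm = np.linalg.norm(shaped, axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(vm[..., None] > 0, shaped / np.where(vm[..., None] > 0, vm[..., None], 1.0), np.nan)
    incl = np.degrees(np.arccos(np.clip(ratio, -1.0, 1.0)))

    minutes = first_minute + pd.to_timedelta(np.arange(n_minutes), unit="min")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)  # all-NaN minutes
        incl_mean = np.nanmean(incl, axis=1)
    out = pd.DataFrame(
        {
            "participant_id": series.participant_id,
            "site": series.site,
            "minute_start": minutes,
            "mean_x": shaped[:, :, 0].mean(axis=1),
            "mean_y": shaped[:, :, 1].mean(axis=1),
            "mean_z": shaped[:, :, 2].mean(axis=1),
            "mean_vm": vm.mean(axis=1),
            "incl_x": incl_mean[:, 0],
            "incl_y": incl_mean[:, 1],
            "incl_z": incl_mean[:, 2],
        }
    )
    return out


def _empty_minute_frame() -> pd.DataFrame:
    cols = ["participant_id", "site", "minute_start", "mean_x", "mean_y",
            "mean_z", "mean_vm", "incl_x", "incl_y", "incl_z"]
    return pd.DataFrame({c: pd.Series(dtype="object" if c in ("participant_id", "site") else "float64") for c in cols}).assign(
        minute_start=pd.Series(dtype="datetime64[ns]")
    )[cols]


def placement_cvs(values: Sequence[float], w: int, scale: float = 100.0) -> np.ndarray:
    """CV of every length-``w`` placement of every anchor minute.

    Returns an ``(n, w)`` array; column ``p`` is the window starting
    ``w - 1 - p`` minutes before the anchor, so column 0 is the fully
    backward placement and column ``w - 1`` the fully forward one.
    Placements extending past either end of the series are NaN.

    A placement with sd == 0 and mean == 0 has CV 0 (an all-zero stationary
    window reads as "no variability"); sd > 0 with mean == 0 is undefined
    (NaN).  Signed channels use ``|mean|`` in the denominator so CVs are
    non-negative.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("values must be one-dimensional")
    n = v.size
    if w < 2:
        raise ValueError("window length w must be >= 2")
    if n < w:
        raise ValueError(f"series of length {n} is shorter than window w={w}")

    wins = sliding_window_view(v, w)           # (n - w + 1, w)
    means = wins.mean(axis=1)
    sds = wins.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(
            means != 0,
            scale * sds / np.abs(means),
            np.where(sds == 0, 0.0, np.nan),
        )

    out = np.full((n, w), np.nan)
    anchors = np.arange(n)
    for p in range(w):
        starts = anchors - (w - 1) + p
        ok = (starts >= 0) & (starts <= n - w)
        out[ok, p] = cv[starts[ok]]
    return out


def sliding_cv(
    values: Sequence[float],
    w: int,
    scale: float = 100.0,
    require_all_placements: bool = True,
) -> np.ndarray:
    """Per-minute sliding CV: the minimum over all ``w`` placements.

    With ``require_all_placements`` (the default) an anchor is defined only
    when every one of its ``w`` placements fits inside the series, i.e. the
    first and last ``w - 1`` minutes are missing.  The ``min-over-available``
    fallback defines any anchor with at least one placement.
    """
    pc = placement_cvs(values, w, scale)
    n = pc.shape[0]
    out = np.full(n, np.nan)
    if require_all_placements:
        valid = np.zeros(n, dtype=bool)
        if n >= 2 * w - 1:
            valid[w - 1 : n - w + 1] = True
    else:
        valid = ~np.all(np.isnan(pc), axis=1)
    if valid.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            out[valid] = np.nanmin(pc[valid], axis=1)
    return out


def add_sliding_cvs(
    minute_frame: pd.DataFrame,
    windows: Iterable[int] = DEFAULT_WINDOWS,
    scale: float = 100.0,
    require_all_placements: bool = True,
) -> pd.DataFrame:
    """Append cv{w}_{channel} columns to a single contiguous minute frame."""
    out = minute_frame.sort_values("minute_start").reset_index(drop=True)
    step = out["minute_start"].diff().dropna()
    if len(step) and not (step == pd.Timedelta(minutes=1)).all():
        raise ValueError("minute frame must be contiguous at 1-minute spacing")
    for w in windows:
        for ch in CV_CHANNELS:
            col = f"cv{w}_{ch}"
            if len(out) >= w:
                out[col] = sliding_cv(
                    out[f"mean_{ch}"].to_numpy(), w, scale, require_all_placements
                )
            else:
                out[col] = np.nan
    return out


def build_feature_table(
    series: Iterable[RawTriaxialSeries],
    labels: pd.DataFrame | None = None,
    windows: Iterable[int] = DEFAULT_WINDOWS,
    scale: float = 100.0,
    require_all_placements: bool = True,
) -> pd.DataFrame:
    """Build the minute-level feature table for a set of recordings.

    Parameters
    ----------
    series
        Raw recordings, one per participant x site.
    labels
        Optional criterion annotations with columns ``participant_id``,
        ``site``, ``minute_start``, ``wear`` ('wear'/'nonwear'), and
        optionally ``state`` ('sleep'/'wake') and ``location``.  Joined on
        participant x site x minute; unmatched label rows are reported with
        a warning, unlabeled feature minutes are retained with missing
        labels.

    Raises
    ------
    ValueError
        If the same participant x site x minute appears twice.
    """
    windows = tuple(windows)
    frames = []
    for s in series:
        mf = aggregate_minutes(s)
        if len(mf):
            frames.append(add_sliding_cvs(mf, windows, scale, require_all_placements))
    if not frames:
        table = _empty_minute_frame()
    else:
        table = pd.concat(frames, ignore_index=True)

    key = ["participant_id", "site", "minute_start"]
    dup = table.duplicated(subset=key, keep=False)
    if dup.any():
        first = table.loc[dup, key].iloc[0]
        raise ValueError(
            "duplicate minute for participant "
            f"{first['participant_id']!r} site {first['site']!r} at {first['minute_start']}"
        )

    if labels is not None:
        lab = labels.copy()
        lab["minute_start"] = pd.to_datetime(lab["minute_start"])
        keep = [c for c in LABEL_COLUMNS if c in lab.columns]
        lab = lab[key + keep]
        merged = table.merge(lab, on=key, how="left", indicator=False)
        matched = lab.merge(table[key], on=key, how="left", indicator=True)
        unmatched = matched["_merge"] == "left_only"
        if unmatched.any():
            bad = matched.loc[unmatched, key].head(3).to_dict("records")
            warnings.warn(
                f"{int(unmatched.sum())} label minute(s) did not match any "
                f"feature minute (first: {bad})",
                stacklevel=2,
            )
        table = merged
    else:
        for c in LABEL_COLUMNS:
            table[c] = pd.NA

    n_edge = int(table[[f"cv{w}_{c}" for w in windows for c in CV_CHANNELS]].isna().any(axis=1).sum())
    logger.info("feature table: %d minutes, %d with missing CVs (edges)", len(table), n_edge)
    return table


def pivot_sites(table: pd.DataFrame, sites: Sequence[str] = SITES) -> pd.DataFrame:
    """Widen a long feature table to one row per participant x minute with
    site-prefixed feature columns (``hip_incl_x``, ``ankle_cv4_z``, ...).

    Only minutes present for every requested site are kept.  Criterion
    labels must agree across sites for the same minute.
    """
    feature_cols = [
        c for c in table.columns
        if c not in ("participant_id", "site", "minute_start", *LABEL_COLUMNS)
    ]
    label_cols = [c for c in LABEL_COLUMNS if c in table.columns]
    parts = []
    for site in sites:
        sub = table[table["site"] == site]
        renamed = sub.rename(columns={c: f"{site}_{c}" for c in feature_cols})
        renamed = renamed.drop(columns=["site"])
        parts.append(renamed)
    out = parts[0]
    for nxt, site in zip(parts[1:], sites[1:]):
        out = out.merge(
            nxt,
            on=["participant_id", "minute_start"],
            how="inner",
            suffixes=("", f"__{site}"),
        )
        for c in label_cols:
            other = f"{c}__{site}"
            if other in out.columns:
                both = out[c].notna() & out[other].notna()
                if (out.loc[both, c] != out.loc[both, other]).any():
                    bad = out.loc[both].loc[out.loc[both, c] != out.loc[both, other]].iloc[0]
                    raise ValueError(
                        f"conflicting {c!r} labels across sites for participant "
                        f"{bad['participant_id']!r} at {bad['minute_start']}"
                    )
                out[c] = out[c].fillna(out[other])
                out = out.drop(columns=[other])
    return out
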