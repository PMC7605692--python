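"""Readers, writers and the end-to-end pipeline.

Canonical on-disk formats are plain CSV: ActiGraph-style RAW CSV (10-line
header, samples in g) or a headerless ``timestamp,x,y,z`` dialect in
milli-g for raw data; ActiLife-style 60-s count exports (with or without a
header block); and the package's own feature/label/count tables.  All
timestamps are serialized as ISO-8601 without timezone.  Every writer adds
a ``#`` provenance comment line (version, seed, config hash) that readers
skip.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .baseline import classify_zero_runs, combine_sites
from .features import RawTriaxialSeries, build_feature_table
from .metrics import stratified_wear_minutes, wear_minutes_table
from .tree import ModelSpec, TrainedTree, LOOCVResults, WearTreeModel

logger = logging.getLogger(__name__)

ACTIGRAPH_HEADER_LINES = 10

#: default column names accepted when ingesting an external minute-level
#: training table; override any entry via ``column_map``
FEATURE_COLUMN_CANDIDATES: dict[str, tuple[str, ...]] = {
    "participant_id": ("participant_id", "participant", "id", "subject", "subject_id"),
    "site": ("site", "placement", "location_site", "attachment_site"),
    "minute_start": ("minute_start", "timestamp", "time", "epoch", "minute"),
    "wear": ("wear", "wear_status", "criterion", "class", "label"),
}


def _provenance(seed: int | None = None, config_hash: str | None = None) -> str:
    bits = [f"# infantwear v{__version__}"]
    if seed is not None:
        bits.append(f"seed={seed}")
    if config_hash is not None:
        bits.append(f"config={config_hash}")
    return " ".join(bits)


def _write_csv(df: pd.DataFrame, path, seed: int | None = None, config_hash: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_provenance(seed, config_hash) + "\n")
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# raw acceleration


def _parse_actigraph_header(lines: list[str], path) -> tuple[pd.Timestamp, float]:
    head = "".join(lines)
    if "Serial Number" not in head:
        raise ValueError(f"{path}: ActiGraph header lacks a 'Serial Number:' line")
    rate_m = re.search(r"(\d+(?:\.\d+)?)\s*Hz", lines[0])
    rate = float(rate_m.group(1)) if rate_m else 30.0
    time_m = re.search(r"Start Time[,\s]+(\d{1,2}:\d{2}:\d{2})", head)
    date_m = re.search(r"Start Date[,\s]+(\S+)", head)
    if not (time_m and date_m):
        raise ValueError(f"{path}: ActiGraph header lacks Start Time/Start Date")
    start = pd.Timestamp(f"{pd.Timestamp(date_m.group(1)).date()} {time_m.group(1)}")
    return start, rate


def read_raw(
    path,
    dialect: str = "auto",
    participant_id: str = "",
    site: str = "hip",
    sample_rate: float | None = None,
    units: str | None = None,
) -> RawTriaxialSeries:
    """Read one raw recording.

    dialect 'actigraph': 10-line RAW CSV header then (Timestamp,)
    Accelerometer X/Y/Z columns in g.  dialect 'plain': headerless
    ``timestamp,x,y,z`` rows in milli-g.  'auto' sniffs the first line.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first:
        raise ValueError(f"{path}: empty file")
    if dialect == "auto":
        dialect = "actigraph" if first.startswith("------------ Data File Created By") else "plain"

    if dialect == "actigraph":
        with open(path) as fh:
            header = [fh.readline() for _ in range(ACTIGRAPH_HEADER_LINES)]
        start, rate = _parse_actigraph_header(header, path)
        try:
            body = pd.read_csv(path, skiprows=ACTIGRAPH_HEADER_LINES)
        except Exception as exc:  # pragma: no cover - pandas message passthrough
            raise ValueError(f"{path}: malformed data rows ({exc})") from exc
        acc_cols = [c for c in body.columns if c.strip().lower().startswith("accelerometer")]
        if len(acc_cols) != 3:
            # headerless data block: re-read without header
            body = pd.read_csv(path, skiprows=ACTIGRAPH_HEADER_LINES, header=None)
            acc_cols = list(body.columns[-3:])
        xyz = body[acc_cols].to_numpy(dtype=float)
        factor = 1000.0 if units in (None, "g") else 1.0
        if sample_rate is not None:
            rate = sample_rate
        return RawTriaxialSeries(participant_id, site, start, xyz * factor, rate)

    if dialect != "plain":
        raise ValueError(f"unknown raw dialect {dialect!r}")
    try:
        body = pd.read_csv(path, header=None, names=["timestamp", "x", "y", "z"], comment="#")
    except Exception as exc:
        raise ValueError(f"{path}: malformed data rows ({exc})") from exc
    if not len(body):
        raise ValueError(f"{path}: no data rows")
    ts = pd.to_datetime(body["timestamp"])
    if sample_rate is None:
        if len(ts) < 2:
            raise ValueError(f"{path}: cannot infer sample rate from a single row")
        dt = (ts.iloc[1:] - ts.iloc[:-1].values).dt.total_seconds().median()
        sample_rate = 1.0 / dt
    factor = 1000.0 if units == "g" else 1.0
    xyz = body[["x", "y", "z"]].to_numpy(dtype=float) * factor
    series = RawTriaxialSeries(participant_id, site, ts.iloc[0], xyz, sample_rate)
    logger.info("%s: %d samples spanning %.1f s", path, len(series), len(series) / sample_rate)
    return series


def write_raw_plain(series: RawTriaxialSeries, path) -> None:
    """Write the headerless ``timestamp,x,y,z`` dialect (milli-g)."""
    n = len(series)
    ts = series.start_time + pd.to_timedelta(np.arange(n) / series.sample_rate, unit="s")
    df = pd.DataFrame(
        {
            "timestamp": ts.strftime("%Y-%m-%dT%H:%M:%S.%f"),
            "x": series.samples[:, 0],
            "y": series.samples[:, 1],
            "z": series.samples[:, 2],
        }
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, header=False, float_format="%.3f")


def write_actigraph_raw(series: RawTriaxialSeries, path, serial: str = "MOS2X00000000") -> None:
    """Write the ActiGraph RAW CSV dialect (10-line header, samples in g)."""
    st = series.start_time
    header = [
        f"------------ Data File Created By ActiGraph wGT3X-BT ActiLife v6.13.3 "
        f"Firmware v1.9.2 date format M/d/yyyy at {series.sample_rate:.0f} Hz  Filter Normal -----------",
        f"Serial Number: {serial}",
        f"Start Time {st.strftime('%H:%M:%S')}",
        f"Start Date {st.strftime('%m/%d/%Y')}",
        "Epoch Period (hh:mm:ss) 00:00:00",
        f"Download Time {st.strftime('%H:%M:%S')}",
        f"Download Date {st.strftime('%m/%d/%Y')}",
        "Current Memory Address: 0",
        "Current Battery Voltage: 4.07     Mode = 12",
        "--------------------------------------------------",
    ]
    df = pd.DataFrame(series.samples / 1000.0, columns=["Accelerometer X", "Accelerometer Y", "Accelerometer Z"])
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, index=False, float_format="%.4f")


# ---------------------------------------------------------------------------
# tables


def write_feature_table(table: pd.DataFrame, path, seed: int | None = None) -> None:
    _write_csv(table, path, seed=seed)


def read_feature_table(path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a minute-level feature table (this package's output or an
    externally deposited training table).

    ``column_map`` maps canonical names (participant_id, site, minute_start,
    wear, ...) to the file's column names; without it, common synonyms are
    tried.  A missing label column is tolerated (labels left missing, with a
    log message); other unmappable required columns raise an error listing
    the candidates tried.
    """
    df = pd.read_csv(path, comment="#")
    rename: dict[str, str] = {}
    for canonical, candidates in FEATURE_COLUMN_CANDIDATES.items():
        if column_map and canonical in column_map:
            src = column_map[canonical]
            if src not in df.columns:
                raise ValueError(f"{path}: mapped column {src!r} for {canonical!r} not found")
            rename[src] = canonical
            continue
        hit = next((c for c in df.columns if c.lower() in candidates), None)
        if hit is not None:
            rename[hit] = canonical
        elif canonical == "wear":
            logger.info("%s: no wear label column found; labels left missing", path)
        else:
            raise ValueError(
                f"{path}: cannot resolve required column {canonical!r}; tried {candidates}"
            )
    df = df.rename(columns=rename)
    df["minute_start"] = pd.to_datetime(df["minute_start"])
    if "wear" in df.columns:
        df["wear"] = _normalize_wear(df["wear"])
    else:
        df["wear"] = pd.NA
    dup = df.duplicated(subset=["participant_id", "site", "minute_start"], keep=False)
    if dup.any():
        first = df.loc[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate minute for participant {first['participant_id']!r} "
            f"site {first['site']!r} at {first['minute_start']}"
        )
    return df


def _normalize_wear(col: pd.Series) -> pd.Series:
    def norm(v):
        if pd.isna(v):
            return pd.NA
        if isinstance(v, str):
            s = v.strip().lower()
            if s in ("wear", "1", "true"):
                return "wear"
            if s in ("nonwear", "non-wear", "non_wear", "0", "false"):
                return "nonwear"
            raise ValueError(f"unrecognized wear label {v!r}")
        return "wear" if int(v) == 1 else "nonwear"

    return col.map(norm)


def write_labels(labels: pd.DataFrame, path, seed: int | None = None) -> None:
    """Write the criterion label CSV (wear encoded 1=wear, 0=nonwear)."""
    out = labels.copy()
    out["wear"] = out["wear"].map({"wear": 1, "nonwear": 0})
    _write_csv(out, path, seed=seed)


def read_labels(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    df["minute_start"] = pd.to_datetime(df["minute_start"])
    df["wear"] = _normalize_wear(df["wear"])
    return df


def write_counts(counts: pd.DataFrame, path, seed: int | None = None) -> None:
    _write_csv(counts, path, seed=seed)


def read_counts(path, dialect: str = "auto") -> pd.DataFrame:
    """Read a 60-s epoch count CSV.

    'plain' (this package's own export): columns including epoch_start and
    vm_counts (or axis1..3 + vm).  'actilife': 10-line header block before
    the column row.  'auto' sniffs the first line.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first:
        raise ValueError(f"{path}: empty file")
    if dialect == "auto":
        dialect = "actilife" if first.startswith("------------") else "plain"
    skip = ACTIGRAPH_HEADER_LINES if dialect == "actilife" else 0
    df = pd.read_csv(path, skiprows=skip, comment="#")
    cols = {c.lower().strip(): c for c in df.columns}
    if "vm_counts" in cols:
        df = df.rename(columns={cols["vm_counts"]: "vm_counts"})
    elif "vm" in cols:
        df = df.rename(columns={cols["vm"]: "vm_counts"})
    elif all(k in cols for k in ("axis1", "axis2", "axis3")):
        ax = df[[cols["axis1"], cols["axis2"], cols["axis3"]]].to_numpy(float)
        df["vm_counts"] = np.sqrt((ax**2).sum(axis=1))
    else:
        raise ValueError(f"{path}: no vm/axis count columns found")
    ts_col = cols.get("epoch_start") or cols.get("timestamp") or cols.get("date")
    if ts_col is None:
        raise ValueError(f"{path}: no epoch_start/timestamp column found")
    df = df.rename(columns={ts_col: "epoch_start"})
    df["epoch_start"] = pd.to_datetime(df["epoch_start"])
    if (df["vm_counts"] < 0).any():
        raise ValueError(f"{path}: negative counts")
    return df


def save_model(tree: TrainedTree, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(tree.to_json())


def load_model(path) -> TrainedTree:
    return TrainedTree.from_json(Path(path).read_text())


# ---------------------------------------------------------------------------
# configuration + pipeline


@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    Either ``feature_table`` (skip raw ingestion) or ``raw_paths`` +
    ``labels`` must be given.  ``counts`` enables the zero-counts baseline
    comparison.
    """

    out_dir: str = "infantwear_out"
    feature_table: str | None = None
    raw_paths: Sequence[str] = field(default_factory=list)
    raw_dialect: str = "auto"
    labels: str | None = None
    counts: str | None = None
    site_modes: Sequence[str] = ("hip", "ankle", "combined")
    cv_windows: Sequence[int] = (2, 3, 4, 5)
    cv_scale: float = 100.0
    predictors: Sequence[str] | None = None
    cp_low: float = 1e-5
    cp_high: float = 1e-1
    cp_size: int = 50
    inner_folds: int = 10
    min_run: int = 2
    seed: int = 0

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")  # identifies the computation, not its destination
        return hashlib.sha256(json.dumps(payload, default=str, sort_keys=True).encode()).hexdigest()[:12]


def parse_config_file(path) -> dict:
    """Flat ``key = value`` config format; '#' starts a comment."""
    out: dict[str, str] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{i}: expected 'key = value'")
        k, v = (part.strip() for part in line.split("=", 1))
        out[k] = v
    return out


def _raw_identity_from_name(path: Path) -> tuple[str, str]:
    """Infer participant and site from a '<pid>_<site>.csv' filename."""
    stem = path.stem
    for site in ("hip", "ankle"):
        if stem.endswith(f"_{site}"):
            return stem[: -len(site) - 1], site
    raise ValueError(f"{path}: cannot infer participant/site from filename (expect <pid>_<site>.csv)")


def run_pipeline(config: RunConfig) -> dict:
    """Run features -> LOOCV -> baseline -> comparison tables.

    Deterministic given config + seed; every output CSV starts with a
    provenance comment.  Any stage failure raises with the stage name.
    Returns a dict of result objects and written paths.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    results: dict = {"out_dir": str(out_dir), "config_hash": chash}
    from .tree import default_cp_grid  # local import to avoid cycle at module load

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return deco

    # --- features ---------------------------------------------------------
    @stage("features")
    def features():
        if config.feature_table:
            return read_feature_table(config.feature_table)
        if not config.raw_paths or not config.labels:
            raise ValueError("need either feature_table or raw_paths + labels")
        labels = read_labels(config.labels)
        series = []
        for p in config.raw_paths:
            p = Path(p)
            pid, site = _raw_identity_from_name(p)
            series.append(read_raw(p, dialect=config.raw_dialect, participant_id=pid, site=site))
        return build_feature_table(
            series, labels=labels, windows=config.cv_windows, scale=config.cv_scale
        )

    write_feature_table(features, out_dir / "features.csv", seed=config.seed)
    results["features"] = features

    # --- models -----------------------------------------------------------
    cp_grid = default_cp_grid(config.cp_low, config.cp_high, config.cp_size)
    summaries = {}
    fold_frames = []
    method_labels: dict[str, pd.DataFrame] = {}
    for mode in config.site_modes:
        @stage(f"loocv[{mode}]")
        def cv(mode=mode):
            model = WearTreeModel(
                features,
                site_mode=mode,
                predictors=config.predictors,
                cp_grid=cp_grid,
                inner_folds=config.inner_folds,
                seed=config.seed,
            )
            return model.loocv()

        summaries[mode] = cv.summary()
        per_fold = cv.metrics_by_fold()
        per_fold.insert(0, "site_mode", mode)
        fold_frames.append(per_fold)
        preds = cv.predictions().dropna(subset=["y_pred"])
        method_labels[f"{mode}_tree"] = preds.rename(columns={"y_pred": "label"})[
            ["participant_id", "minute_start", "label"]
        ]
        results[f"loocv_{mode}"] = cv

    _write_csv(pd.concat(fold_frames, ignore_index=True), out_dir / "fold_metrics.csv", seed=config.seed, config_hash=chash)
    summary_rows = []
    for mode, s in summaries.items():
        s = s.reset_index()
        s.insert(0, "site_mode", mode)
        summary_rows.append(s)
    _write_csv(pd.concat(summary_rows, ignore_index=True), out_dir / "model_summary.csv", seed=config.seed, config_hash=chash)

    # --- baseline ---------------------------------------------------------
    criterion = (
        features.dropna(subset=["wear"])
        .groupby(["participant_id", "minute_start"], as_index=False)["wear"]
        .first()
        .rename(columns={"wear": "label"})
    )
    if config.counts:
        @stage("baseline")
        def baseline_labels():
            counts = read_counts(config.counts)
            per_site = {}
            for site, sub in counts.groupby("site"):
                frames = []
                for pid, ser in sub.groupby("participant_id"):
                    frames.append(classify_zero_runs(ser.sort_values("epoch_start"), min_run=config.min_run))
                per_site[site] = pd.concat(frames, ignore_index=True)
            out = {}
            for site, frame in per_site.items():
                out[f"{site}_zero_counts"] = frame.rename(
                    columns={"epoch_start": "minute_start"}
                )[["participant_id", "minute_start", "label"]]
            if {"hip", "ankle"} <= set(per_site):
                combined = []
                for pid in per_site["hip"]["participant_id"].unique():
                    h = per_site["hip"][per_site["hip"]["participant_id"] == pid]
                    a = per_site["ankle"][per_site["ankle"]["participant_id"] == pid]
                    combined.append(combine_sites(h, a))
                out["combined_zero_counts"] = pd.concat(combined, ignore_index=True).rename(
                    columns={"epoch_start": "minute_start"}
                )[["participant_id", "minute_start", "label"]]
            return out

        for name, frame in baseline_labels.items():
            method_labels[name] = frame

    # --- comparison -------------------------------------------------------
    @stage("report")
    def comparison():
        usable = {
            name: frame.merge(criterion[["participant_id", "minute_start"]], on=["participant_id", "minute_start"])
            for name, frame in method_labels.items()
        }
        return wear_minutes_table(usable, criterion)

    _write_csv(comparison.reset_index(), out_dir / "wear_minutes.csv", seed=config.seed, config_hash=chash)
    results["wear_minutes"] = comparison

    log = out_dir / "run_log.txt"
    log.write_text(
        _provenance(config.seed, chash)
        + "\n"
        + json.dumps(asdict(config), default=str, indent=2)
        + "\n"
    )
    results["log"] = str(log)
    return results
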