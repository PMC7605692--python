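"""Synthetic infant accelerometer recordings with criterion labels.

Generates labeled raw 30 Hz triaxial series (hip and ankle), minute-level
criterion labels, and minute-epoch pseudo-counts, so every pipeline stage is
testable without real device data.  Four behavioural states are emulated:

``nonwear_table``
    Device initialized/removed and left on a laboratory table: gravity along
    a fixed near-vertical device orientation plus sensor noise only.
``worn_sleep``
    Infant asleep: near-constant posture with sporadic caregiver-induced
    twitches on the ankle and slow orientation drift.  The hip device is
    modeled as motionless and lying roughly flat (supine infant), which
    deliberately overlaps the table condition -- the mechanism behind the
    hip model's weaker published performance.
``worn_awake``
    Waking movement: frequent damped-sinusoid bursts, ankle-dominant.
``caregiver_handling``
    Handling/carrying: bursts correlated across both sites.

Per-sample signal model: ``1000 * orientation + N(0, noise_sd)`` per axis,
plus Poisson-arriving damped-sinusoid bursts of random direction, frequency
and duration, plus a slow per-minute orientation random walk in worn states.

Pseudo-counts are a synthetic stand-in for the proprietary ActiLife
raw-to-count conversion: per minute, ``floor(12 * max(0, mean|VM - 1000| -
3 mg))``.  Noiseless stationary minutes therefore yield exactly zero counts,
and quiet sleep falls inside the dead band (mostly zero counts), as the
zero-counts comparison requires.

Everything is reproducible from a single seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .features import RawTriaxialSeries, SITES, build_feature_table

STATES = ("nonwear_table", "worn_sleep", "worn_awake", "caregiver_handling")

#: per-state signal parameters: sensor noise (milli-g), burst arrivals per
#: minute, burst amplitude (milli-g), orientation drift (degrees/minute)
STATE_DEFAULTS: dict[str, dict[str, float]] = {
    "nonwear_table": dict(noise_sd=2.0, burst_rate=0.0, burst_amplitude=0.0, drift_rate=0.0),
    "worn_sleep": dict(noise_sd=3.0, burst_rate=0.08, burst_amplitude=120.0, drift_rate=0.4),
    "worn_awake": dict(noise_sd=5.0, burst_rate=5.0, burst_amplitude=250.0, drift_rate=1.5),
    "caregiver_handling": dict(noise_sd=6.0, burst_rate=4.0, burst_amplitude=200.0, drift_rate=3.0),
}

#: site multipliers on burst_rate/drift_rate: ankle movement dominates while
#: worn; the sleeping hip is motionless
SITE_SCALES: dict[str, dict[str, float]] = {
    "nonwear_table": {"hip": 1.0, "ankle": 1.0},
    "worn_sleep": {"hip": 0.0, "ankle": 1.0},
    "worn_awake": {"hip": 0.3, "ankle": 1.0},
    "caregiver_handling": {"hip": 1.0, "ankle": 1.0},
}

LOCATIONS = {
    "nonwear_table": "laboratory table",
    "worn_sleep": "rocker",
    "worn_awake": "rocker",
    "caregiver_handling": "held by caregiver",
}

#: pseudo-count dead band (milli-g) and gain (counts per milli-g)
COUNT_DEADBAND_MG = 3.0
COUNT_GAIN = 12.0


@dataclass
class SegmentSpec:
    """One behavioural segment of a recording.

    Numeric fields left as None fall back to the state defaults above;
    ``orientation`` maps site -> unit gravity direction and is sampled per
    participant when None.
    """

    state: str
    duration: int  # whole minutes
    orientation: dict[str, np.ndarray] | None = None
    noise_sd: float | None = None
    burst_rate: float | None = None
    burst_amplitude: float | None = None
    drift_rate: float | None = None

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"state must be one of {STATES}, got {self.state!r}")
        if self.duration < 1:
            raise ValueError("segment duration must be >= 1 minute")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.burst_rate is not None and self.burst_rate < 0:
            raise ValueError("burst_rate must be >= 0")
        if self.orientation is not None:
            for site, v in self.orientation.items():
                v = np.asarray(v, dtype=float)
                if not math.isclose(float(np.linalg.norm(v)), 1.0, rel_tol=1e-6):
                    raise ValueError(f"orientation for {site!r} must have unit norm")

    def param(self, name: str) -> float:
        value = getattr(self, name)
        return STATE_DEFAULTS[self.state][name] if value is None else value

    @property
    def wear(self) -> str:
        return "nonwear" if self.state == "nonwear_table" else "wear"

    @property
    def sleep_state(self):
        if self.state == "worn_sleep":
            return "sleep"
        if self.state in ("worn_awake", "caregiver_handling"):
            return "wake"
        return pd.NA


@dataclass
class ScenarioConfig:
    """A full synthetic study: participants x sites x segment sequence."""

    participants: int
    segments: Sequence[SegmentSpec]
    sites: Sequence[str] = SITES
    sample_rate: float = 30.0
    seed: int = 0
    #: per-participant multiplicative jitter on segment durations (+-fraction)
    duration_jitter: float = 0.0
    start_time: pd.Timestamp = pd.Timestamp("2020-01-06 08:00:00")

    def __post_init__(self) -> None:
        if self.participants < 1:
            raise ValueError("participants must be >= 1")
        self.segments = list(self.segments)
        if not self.segments or sum(s.duration for s in self.segments) < 1:
            raise ValueError("config must contain at least one minute of signal")


def default_study_config(seed: int = 0) -> ScenarioConfig:
    """Study-scale default: 15 participants x 2 sites, per participant ~451
    non-wear minutes (two table blocks around the wear period) and ~321 wear
    minutes split across sleep (132), waking movement (101) and caregiver
    handling (88), with +-8% per-participant duration jitter."""
    segments = [
        SegmentSpec("nonwear_table", 226),
        SegmentSpec("worn_sleep", 66),
        SegmentSpec("worn_awake", 50),
        SegmentSpec("caregiver_handling", 44),
        SegmentSpec("worn_sleep", 66),
        SegmentSpec("worn_awake", 51),
        SegmentSpec("caregiver_handling", 44),
        SegmentSpec("nonwear_table", 225),
    ]
    return ScenarioConfig(
        participants=15, segments=segments, sites=SITES, sample_rate=30.0,
        seed=seed, duration_jitter=0.08,
    )


# ---------------------------------------------------------------------------
# orientation helpers


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _tilted(base: np.ndarray, tilt_deg: float, azimuth: float) -> np.ndarray:
    """Unit vector at ``tilt_deg`` from ``base`` in the ``azimuth`` direction."""
    base = _unit(np.asarray(base, dtype=float))
    helper = np.array([1.0, 0.0, 0.0])
    if abs(base @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = _unit(np.cross(base, helper))
    e2 = np.cross(base, e1)
    t = math.radians(tilt_deg)
    return math.cos(t) * base + math.sin(t) * (math.cos(azimuth) * e1 + math.sin(azimuth) * e2)


def _sample_orientation(rng: np.random.Generator, state: str, site: str) -> np.ndarray:
    az = rng.uniform(0, 2 * math.pi)
    if state == "nonwear_table":
        # device flat on the table, face up: small tilt from -z
        return _tilted(np.array([0.0, 0.0, -1.0]), rng.uniform(0.0, 6.0), az)
    if state == "worn_sleep":
        if site == "hip":
            # supine infant: hip device lies nearly flat, overlapping the table
            return _tilted(np.array([0.0, 0.0, -1.0]), rng.uniform(0.0, 10.0), az)
        return _tilted(np.array([0.0, -1.0, 0.0]), rng.uniform(10.0, 30.0), az)
    if site == "hip":
        # reclined in the rocker / held upright-ish
        return _tilted(np.array([0.0, 0.0, -1.0]), rng.uniform(10.0, 35.0), az)
    return _tilted(np.array([0.0, -1.0, 0.0]), rng.uniform(10.0, 40.0), az)


def _drift_walk(
    rng: np.random.Generator, start: np.ndarray, minutes: int, step_deg: float
) -> np.ndarray:
    """Per-minute orientation random walk of ``step_deg`` degrees per step."""
    out = np.empty((minutes, 3))
    v = _unit(np.asarray(start, dtype=float))
    for i in range(minutes):
        out[i] = v
        if step_deg > 0:
            w = rng.normal(size=3)
            w -= (w @ v) * v
            norm = np.linalg.norm(w)
            if norm > 0:
                a = math.radians(step_deg)
                v = _unit(math.cos(a) * v + math.sin(a) * (w / norm))
    return out


# ---------------------------------------------------------------------------
# signal generation


def _burst_events(
    rng: np.random.Generator, rate_per_min: float, minutes: int, sample_rate: float
) -> list[dict]:
    """Poisson-arriving damped-sinusoid burst parameters for one segment."""
    n_samples = int(round(minutes * 60 * sample_rate))
    n_bursts = rng.poisson(rate_per_min * minutes)
    events = []
    for _ in range(n_bursts):
        events.append(
            dict(
                start=int(rng.integers(0, max(1, n_samples))),
                duration_s=rng.uniform(0.5, 3.0),
                freq_hz=rng.uniform(2.0, 8.0),
                phase=rng.uniform(0, 2 * math.pi),
                direction=_unit(rng.normal(size=3)),
                amp_scale=rng.uniform(0.5, 1.5),
            )
        )
    return events


def _apply_bursts(
    sig: np.ndarray, events: Iterable[dict], amplitude: float, sample_rate: float
) -> None:
    n = len(sig)
    for ev in events:
        length = int(ev["duration_s"] * sample_rate)
        if length < 2:
            continue
        stop = min(n, ev["start"] + length)
        length = stop - ev["start"]
        if length < 2:
            continue
        t = np.arange(length) / sample_rate
        tau = ev["duration_s"] / 3.0
        env = amplitude * ev["amp_scale"] * np.exp(-t / tau) * np.sin(
            2 * math.pi * ev["freq_hz"] * t + ev["phase"]
        )
        sig[ev["start"] : stop] += np.outer(env, ev["direction"])


def _segment_signal(
    rng: np.random.Generator,
    seg: SegmentSpec,
    site: str,
    orientation: np.ndarray,
    sample_rate: float,
    shared_events: list[dict] | None,
) -> np.ndarray:
    spm = int(round(sample_rate * 60))
    scale = SITE_SCALES[seg.state][site]
    ori = _drift_walk(rng, orientation, seg.duration, seg.param("drift_rate") * scale)
    sig = 1000.0 * np.repeat(ori, spm, axis=0)
    noise_sd = seg.param("noise_sd")
    if noise_sd > 0:
        sig += rng.normal(0.0, noise_sd, size=sig.shape)
    if shared_events is not None:
        events = shared_events
    else:
        events = _burst_events(rng, seg.param("burst_rate") * scale, seg.duration, sample_rate)
    _apply_bursts(sig, events, seg.param("burst_amplitude"), sample_rate)
    return sig


def pseudo_counts(vm_by_minute: np.ndarray) -> np.ndarray:
    """Synthetic 60-s epoch counts from per-minute raw VM samples.

    ``vm_by_minute`` has shape (minutes, samples_per_minute).  Counts are
    ``floor(12 * max(0, mean|VM - 1000| - 3))`` -- zero for stationary
    minutes, positive once movement lifts the mean VM deviation past the
    3 mg dead band.
    """
    dev = np.abs(vm_by_minute - 1000.0).mean(axis=1)
    return np.floor(np.maximum(0.0, dev - COUNT_DEADBAND_MG) * COUNT_GAIN).astype(int)


def _jittered_segments(
    rng: np.random.Generator, config: ScenarioConfig
) -> list[SegmentSpec]:
    if config.duration_jitter <= 0:
        return list(config.segments)
    out = []
    for seg in config.segments:
        factor = rng.uniform(1 - config.duration_jitter, 1 + config.duration_jitter)
        out.append(replace(seg, duration=max(1, int(round(seg.duration * factor)))))
    return out


def generate_participant(
    pid: str, config: ScenarioConfig, seed_seq: np.random.SeedSequence
) -> tuple[dict[str, RawTriaxialSeries], pd.DataFrame, pd.DataFrame]:
    """Raw series per site, minute criterion labels, and pseudo-counts for
    one participant."""
    rng = np.random.default_rng(seed_seq)
    segments = _jittered_segments(rng, config)
    spm = int(round(config.sample_rate * 60))

    # per-segment orientations and shared (cross-site) caregiver bursts
    orientations: list[dict[str, np.ndarray]] = []
    shared: list[list[dict] | None] = []
    for seg in segments:
        if seg.orientation is not None:
            orientations.append({s: np.asarray(seg.orientation[s], float) for s in config.sites})
        else:
            orientations.append(
                {s: _sample_orientation(rng, seg.state, s) for s in config.sites}
            )
        if seg.state == "caregiver_handling":
            shared.append(
                _burst_events(rng, seg.param("burst_rate"), seg.duration, config.sample_rate)
            )
        else:
            shared.append(None)

    series: dict[str, RawTriaxialSeries] = {}
    counts_frames = []
    label_frames = []
    total_minutes = sum(s.duration for s in segments)
    minute_index = config.start_time + pd.to_timedelta(np.arange(total_minutes), unit="min")

    for site in config.sites:
        parts = [
            _segment_signal(rng, seg, site, orientations[i][site], config.sample_rate, shared[i])
            for i, seg in enumerate(segments)
        ]
        sig = np.concatenate(parts, axis=0)
        series[site] = RawTriaxialSeries(
            participant_id=pid,
            site=site,
            start_time=config.start_time,
            samples=sig,
            sample_rate=config.sample_rate,
        )
        vm = np.linalg.norm(sig.reshape(total_minutes, spm, 3), axis=2)
        counts_frames.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "site": site,
                    "epoch_start": minute_index,
                    "vm_counts": pseudo_counts(vm),
                }
            )
        )
        wear = np.concatenate([[seg.wear] * seg.duration for seg in segments])
        state = np.concatenate([[seg.sleep_state] * seg.duration for seg in segments])
        loc = np.concatenate([[LOCATIONS[seg.state]] * seg.duration for seg in segments])
        label_frames.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "site": site,
                    "minute_start": minute_index,
                    "wear": wear,
                    "state": state,
                    "location": loc,
                }
            )
        )

    return series, pd.concat(label_frames, ignore_index=True), pd.concat(counts_frames, ignore_index=True)


def participant_ids(n: int) -> list[str]:
    return [f"P{i + 1:02d}" for i in range(n)]


def generate_recording(
    config: ScenarioConfig,
) -> tuple[dict[tuple[str, str], RawTriaxialSeries], pd.DataFrame, pd.DataFrame]:
    """Generate the full scenario: raw series per participant x site,
    criterion label table, and pseudo-count table."""
    children = np.random.SeedSequence(config.seed).spawn(config.participants)
    recordings: dict[tuple[str, str], RawTriaxialSeries] = {}
    labels, counts = [], []
    for pid, child in zip(participant_ids(config.participants), children):
        series, lab, cnt = generate_participant(pid, config, child)
        for site, s in series.items():
            recordings[(pid, site)] = s
        labels.append(lab)
        counts.append(cnt)
    return recordings, pd.concat(labels, ignore_index=True), pd.concat(counts, ignore_index=True)


def generate_feature_dataset(
    config: ScenarioConfig,
    windows: Iterable[int] = (2, 3, 4, 5),
    scale: float = 100.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate the scenario and reduce straight to the minute feature table.

    Streams one participant at a time so the raw 30 Hz signal never has to
    be held in memory for the whole study.  Returns (features, labels,
    counts); the feature table already carries the criterion labels.
    """
    children = np.random.SeedSequence(config.seed).spawn(config.participants)
    feats, labels, counts = [], [], []
    for pid, child in zip(participant_ids(config.participants), children):
        series, lab, cnt = generate_participant(pid, config, child)
        feats.append(build_feature_table(series.values(), labels=lab, windows=windows, scale=scale))
        labels.append(lab)
        counts.append(cnt)
    return (
        pd.concat(feats, ignore_index=True),
        pd.concat(labels, ignore_index=True),
        pd.concat(counts, ignore_index=True),
    )
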