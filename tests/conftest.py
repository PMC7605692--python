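import numpy as np
import pandas as pd
import pytest

from infantwear import ScenarioConfig, SegmentSpec

# Per-minute VM series of the published worked example (milli-g), 10:30-10:40.
TABLE1_VM = [
    1020.73, 1021.07, 1021.28, 1021.30, 1021.48, 1021.12,
    1036.18, 1024.44, 990.04, 974.24, 969.71,
]

# Printed CV cells for anchors 10:32..10:38 (indices 2..8), scale 1e4:
# (cv2_back, cv2_fwd, cv3_back, cv3_center, cv3_fwd, min2, min3).
# The 10:32 three-minute-center cell is printed 1.1 but the identical window
# appears as 1.2 in the 10:33 three-minute-backward cell; the self-consistent
# computed value (1.248 -> 1.2) is used here.
TABLE1_CELLS = {
    2: (1.5, 0.1, 2.7, 1.2, 1.1, 0.1, 1.1),
    3: (0.1, 1.2, 1.2, 1.1, 1.8, 0.1, 1.1),
    4: (1.2, 2.5, 1.1, 1.8, 83.7, 1.2, 1.1),
    5: (2.5, 103.5, 1.8, 83.7, 77.0, 2.5, 1.8),
    6: (103.5, 80.6, 83.7, 77.0, 235.8, 80.6, 77.0),
    7: (80.6, 241.5, 77.0, 235.8, 257.6, 80.6, 77.0),
    8: (241.5, 113.8, 235.8, 257.6, 109.1, 113.8, 109.1),
}


def brute_force_sliding_cv(values, w, scale=100.0):
    """Independent enumeration oracle for the min-over-placements sliding CV."""
    n = len(values)
    out = [float("nan")] * n
    for i in range(n):
        if i < w - 1 or i > n - w:
            continue  # not all placements available
        cvs = []
        for start in range(i - w + 1, i + 1):
            win = values[start : start + w]
            mean = sum(win) / w
            sd = (sum((x - mean) ** 2 for x in win) / (w - 1)) ** 0.5
            if mean == 0:
                if sd == 0:
                    cvs.append(0.0)
                # sd > 0 with zero mean: undefined placement, dropped
            else:
                cvs.append(scale * sd / abs(mean))
        if cvs:
            out[i] = min(cvs)
    return out


def make_separable_table(
    n_participants=5, minutes_per_class=30, site="ankle", seed=0, start="2020-01-06 08:00"
):
    """Feature table with cleanly separated wear/non-wear feature regimes."""
    rng = np.random.default_rng(seed)
    rows = []
    t0 = pd.Timestamp(start)
    for p in range(n_participants):
        pid = f"S{p + 1:02d}"
        for j in range(2 * minutes_per_class):
            nonwear = j < minutes_per_class
            rows.append(
                {
                    "participant_id": pid,
                    "site": site,
                    "minute_start": t0 + pd.Timedelta(minutes=j),
                    "incl_x": rng.normal(90, 3),
                    "incl_y": rng.normal(95 if nonwear else 160, 3),
                    "incl_z": rng.normal(176, 1.2) if nonwear else rng.normal(90, 8),
                    "cv4_x": abs(rng.normal(0.01, 0.005)) if nonwear else abs(rng.normal(3, 1)),
                    "cv4_y": abs(rng.normal(0.01, 0.005)) if nonwear else abs(rng.normal(3, 1)),
                    "cv4_z": abs(rng.normal(0.01, 0.005)) if nonwear else abs(rng.normal(2, 0.7)),
                    "wear": "nonwear" if nonwear else "wear",
                }
            )
    return pd.DataFrame(rows)


def make_noise_table(n=2000, seed=0, site="ankle", n_participants=4):
    """Labels independent of features."""
    rng = np.random.default_rng(seed)
    t0 = pd.Timestamp("2020-01-06 08:00")
    df = pd.DataFrame(
        {
            "participant_id": [f"N{1 + (i % n_participants):02d}" for i in range(n)],
            "site": site,
            "minute_start": t0 + pd.to_timedelta(np.arange(n), unit="min"),
            "incl_x": rng.normal(90, 20, n),
            "incl_y": rng.normal(90, 20, n),
            "incl_z": rng.normal(90, 20, n),
            "cv4_x": np.abs(rng.normal(1, 0.5, n)),
            "cv4_y": np.abs(rng.normal(1, 0.5, n)),
            "cv4_z": np.abs(rng.normal(1, 0.5, n)),
            "wear": rng.choice(["wear", "nonwear"], n),
        }
    )
    return df


@pytest.fixture
def tiny_config():
    return ScenarioConfig(
        participants=2,
        segments=[
            SegmentSpec("nonwear_table", 12),
            SegmentSpec("worn_sleep", 8),
            SegmentSpec("worn_awake", 8),
            SegmentSpec("caregiver_handling", 6),
            SegmentSpec("nonwear_table", 10),
        ],
        seed=7,
    )
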