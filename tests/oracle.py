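"""Brute-force reference classifier used to validate the production rules.

Independent implementation: exhaustive window scans over every contiguous
interval range instead of run bookkeeping.
"""

import numpy as np


def brute_force_classify(track, u_ref, params, frame_interval_s=1.0):
    """Return (motion class, rolling velocity or None) for one track table."""
    t = track.sort_values("frame")
    if len(t) < 2:
        return "free", None
    frames = t["frame"].to_numpy()
    dx = np.diff(t["x_um"].to_numpy())
    dy = np.diff(t["y_um"].to_numpy())
    disp = np.hypot(dx, dy)
    gaps = np.diff(frames)
    speeds = disp / (gaps * frame_interval_s)
    diameter = float(t["diameter_um"].median())
    n = len(speeds)
    stationary = disp / gaps < params.epsilon_um
    slow = speeds < params.rolling_threshold_fraction * u_ref

    # adhesion: any window [i, j) of all-stationary intervals spanning at
    # least min_stationary_frames observed frames, ending at the last
    # interval (terminal policy) or anywhere (variant)
    adhesion = False
    for i in range(n):
        for j in range(i + 1, n + 1):
            if not stationary[i:j].all():
                continue
            if frames[j] - frames[i] + 1 < params.min_stationary_frames:
                continue
            if params.arrest_policy == "terminal" and j != n:
                continue
            adhesion = True
    if adhesion:
        return "adhesion", None

    # rolling: any all-slow window whose path exceeds one median diameter;
    # velocity from the maximum-path qualifying window
    best_path, best_time = -1.0, 1.0
    for i in range(n):
        for j in range(i + 1, n + 1):
            if not slow[i:j].all():
                continue
            path = float(disp[i:j].sum())
            if path > params.min_rolling_diameters * diameter and path > best_path:
                best_path = path
                best_time = float(gaps[i:j].sum()) * frame_interval_s
    if best_path > 0:
        return "rolling", best_path / best_time

    # tethering: a slow-or-arrested interval followed by a fast interval
    for i in range(n):
        if slow[i] or stationary[i]:
            if any(not slow[j] for j in range(i + 1, n)):
                return "tethering", None
            break
    return "free", None


def random_speed_track(rng, u_ref=134.0):
    """Random piecewise-regime track exercising every rule boundary."""
    import pandas as pd

    n = int(rng.integers(1, 31))
    regimes = []
    while sum(len(r) for r in regimes) < n:
        kind = rng.choice(["fast", "slow", "stop", "noise"])
        length = int(rng.integers(1, 8))
        if kind == "fast":
            v = rng.uniform(0.6, 1.3) * u_ref
        elif kind == "slow":
            v = rng.uniform(0.05, 0.45) * u_ref
        elif kind == "stop":
            v = rng.uniform(0.0, 4.0)
        else:
            v = rng.uniform(0.0, 1.2) * u_ref
        regimes.append([v] * length)
    speeds = np.concatenate(regimes)[: n - 1] if n > 1 else np.empty(0)
    xs = np.concatenate([[0.0], np.cumsum(speeds)])
    frames = np.arange(n)
    if n > 3 and rng.random() < 0.3:  # knock out a frame: gap handling
        drop = int(rng.integers(1, n - 1))
        keep = np.ones(n, bool)
        keep[drop] = False
        xs, frames = xs[keep], frames[keep]
    return pd.DataFrame(
        {
            "frame": frames,
            "track_id": 0,
            "x_um": xs,
            "y_um": rng.normal(0, 1.0, size=len(xs)),
            "diameter_um": float(rng.uniform(70, 100)),
            "condition": "X",
            "field_id": 0,
        }
    )
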