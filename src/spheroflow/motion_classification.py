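"""Motion classification of spheroid tracks and cohort percentages.

This is the core computation of the assay.  Every track is assigned exactly
one motion class, with precedence adhesion > rolling > tethering > free:

* **adhesion** — the spheroid arrests: at least ``min_stationary_frames``
  consecutive observed frames with per-frame displacement below the
  stationarity threshold ``epsilon``, with the arrest persisting to the end
  of the observation (default policy) or occurring anywhere (variant).
* **rolling** — sustained sub-hydrodynamic translation: some contiguous run
  of intervals all slower than ``c * u_ref`` whose summed path length
  exceeds one spheroid diameter.
* **tethering** — transient capture: at least one interval slower than
  ``c * u_ref`` (or an arrest) followed by a return to free-transport speed
  before the spheroid leaves the field.
* **free** — none of the above.

``u_ref`` is the reference (hydrodynamic) velocity of a non-interacting
spheroid, either computed from the flow context at the cohort's median
diameter ("analytic") or estimated as an upper percentile of all observed
interval speeds ("empirical").  The rolling threshold fraction ``c``
defaults to 0.5, the leukocyte-rolling convention; ``c = 1`` reproduces the
literal "below the hydrodynamic velocity" reading, which at 1 frame/s is
fragile against measurement noise.

Cohort percentages divide class counts by the total number of spheroids
that passed through the field during the 30 s recording; counts pool across
fields before dividing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .flow_geometry import FlowContext, ShearRamp, hydrodynamic_velocity

__all__ = [
    "CLASS_TETHERING",
    "CLASS_ROLLING",
    "CLASS_ADHESION",
    "CLASS_FREE",
    "ClassificationParams",
    "ClassifiedTrack",
    "CohortSummary",
    "frame_velocities",
    "reference_velocity",
    "classify_track",
    "classify_cohort",
    "summarize_cohort",
    "detachment_fraction",
]

CLASS_TETHERING = "tethering"
CLASS_ROLLING = "rolling"
CLASS_ADHESION = "adhesion"
CLASS_FREE = "free"


@dataclass(frozen=True)
class ClassificationParams:
    """Operational thresholds for the tether/roll/arrest rules.

    epsilon_um is the per-frame displacement below which a spheroid counts
    as stationary (um per frame); min_rolling_diameters the rolling path
    requirement in units of the track's median diameter.
    """

    reference_mode: str = "analytic"          # "analytic" | "empirical"
    rolling_threshold_fraction: float = 0.5   # c
    epsilon_um: float = 5.0
    min_rolling_diameters: float = 1.0
    min_stationary_frames: int = 2
    empirical_percentile: float = 90.0
    arrest_policy: str = "terminal"           # "terminal" | "anywhere"
    count_single_frame_tracks: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.rolling_threshold_fraction <= 1):
            raise ValueError("rolling threshold fraction must lie in (0, 1]")
        if self.epsilon_um < 0:
            raise ValueError("epsilon must be non-negative")
        if self.min_stationary_frames < 2:
            raise ValueError("an arrest needs at least 2 frames")
        if self.reference_mode not in ("analytic", "empirical"):
            raise ValueError("reference_mode must be 'analytic' or 'empirical'")
        if self.arrest_policy not in ("terminal", "anywhere"):
            raise ValueError("arrest_policy must be 'terminal' or 'anywhere'")


@dataclass(frozen=True)
class ClassifiedTrack:
    """One track's class assignment with its supporting evidence."""

    track_id: int
    motion_class: str
    rolling_velocity_um_s: float | None = None
    n_frames: int = 0
    condition: str = ""
    field_id: int = 0
    rolling_segment: tuple[int, int] | None = None  # (first frame, last frame)
    arrest_segment: tuple[int, int] | None = None
    flags: tuple[str, ...] = ()


def frame_velocities(track: pd.DataFrame, frame_interval_s: float = 1.0) -> np.ndarray:
    """Speeds (um/s) between consecutive observed frames, gap-aware.

    A missed detection (frame gap) divides the displacement by the elapsed
    time, not the nominal frame interval.  Single-detection tracks yield an
    empty array.
    """
    t = track.sort_values("frame")
    if len(t) < 2:
        return np.empty(0)
    dx = np.diff(t["x_um"].to_numpy())
    dy = np.diff(t["y_um"].to_numpy())
    dframes = np.diff(t["frame"].to_numpy())
    return np.hypot(dx, dy) / (dframes * frame_interval_s)


def reference_velocity(
    tracks: pd.DataFrame,
    flow: FlowContext | None,
    params: ClassificationParams,
    frame_interval_s: float = 1.0,
) -> tuple[float, str]:
    """Reference free-transport velocity u_ref (um/s) and the mode used.

    Analytic: hydrodynamic velocity at the cohort's median diameter.
    Empirical: the configured upper percentile of all interval speeds, a
    robust stand-in for free-transport speed that ignores a minority of
    interacting (slow) tracks.  Falls back to analytic below 5 tracks.
    """
    mode = params.reference_mode
    n_tracks = tracks["track_id"].nunique() if len(tracks) else 0
    if mode == "empirical" and n_tracks < 5:
        if flow is None:
            raise ValueError("empirical u_ref needs >= 5 tracks or a flow context")
        warnings.warn("fewer than 5 tracks; falling back to analytic u_ref")
        mode = "analytic"
    if mode == "analytic":
        if flow is None:
            raise ValueError("analytic u_ref requires a flow context")
        if len(tracks):
            med_d = float(tracks.groupby("track_id")["diameter_um"].median().median())
        else:
            med_d = 85.0
        return hydrodynamic_velocity(flow, med_d), "analytic"
    speeds = np.concatenate(
        [
            frame_velocities(g, frame_interval_s)
            for _, g in tracks.groupby("track_id")
        ]
    )
    if speeds.size == 0:
        raise ValueError("no intervals available for empirical u_ref")
    return float(np.percentile(speeds, params.empirical_percentile)), "empirical"


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) index pairs, stop exclusive."""
    runs = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


def classify_track(
    track: pd.DataFrame,
    u_ref: float,
    params: ClassificationParams = ClassificationParams(),
    frame_interval_s: float = 1.0,
) -> ClassifiedTrack:
    """Assign one motion class to a track (precedence: adhesion > rolling >
    tethering > free).  See the module docstring for the operational rules."""
    if u_ref <= 0:
        raise ValueError("u_ref must be positive")
    t = track.sort_values("frame")
    track_id = int(t["track_id"].iloc[0])
    condition = str(t["condition"].iloc[0]) if "condition" in t else ""
    field_id = int(t["field_id"].iloc[0]) if "field_id" in t else 0
    frames = t["frame"].to_numpy()
    common = dict(
        track_id=track_id, n_frames=len(t), condition=condition, field_id=field_id
    )
    if len(t) < 2:
        return ClassifiedTrack(
            motion_class=CLASS_FREE, flags=("single_frame",), **common
        )

    dx = np.diff(t["x_um"].to_numpy())
    dy = np.diff(t["y_um"].to_numpy())
    disp = np.hypot(dx, dy)
    dframes = np.diff(frames)
    speeds = disp / (dframes * frame_interval_s)
    per_frame_disp = disp / dframes
    diameter = float(t["diameter_um"].median())

    stationary = per_frame_disp < params.epsilon_um
    slow = speeds < params.rolling_threshold_fraction * u_ref

    # --- adhesion ---------------------------------------------------------
    arrest_segment = None
    for start, stop in _runs(stationary):
        n_frames_in_run = int(frames[stop] - frames[start] + 1)
        terminal = stop == len(stationary)
        qualifies = n_frames_in_run >= params.min_stationary_frames and (
            terminal if params.arrest_policy == "terminal" else True
        )
        if qualifies:
            arrest_segment = (int(frames[start]), int(frames[stop]))
            if params.arrest_policy == "terminal" or terminal:
                break
    if arrest_segment is not None:
        return ClassifiedTrack(
            motion_class=CLASS_ADHESION, arrest_segment=arrest_segment, **common
        )

    # --- rolling ----------------------------------------------------------
    best = None  # (path, start, stop)
    for start, stop in _runs(slow):
        path = float(disp[start:stop].sum())
        if path > params.min_rolling_diameters * diameter:
            if best is None or path > best[0]:
                best = (path, start, stop)
    if best is not None:
        path, start, stop = best
        elapsed = float(dframes[start:stop].sum()) * frame_interval_s
        return ClassifiedTrack(
            motion_class=CLASS_ROLLING,
            rolling_velocity_um_s=path / elapsed,
            rolling_segment=(int(frames[start]), int(frames[stop])),
            **common,
        )

    # --- tethering --------------------------------------------------------
    captured = slow | stationary
    if captured.any():
        first_capture = int(np.argmax(captured))
        returned = ~slow[first_capture + 1 :]
        if returned.any():
            return ClassifiedTrack(motion_class=CLASS_TETHERING, **common)

    return ClassifiedTrack(motion_class=CLASS_FREE, **common)


def classify_cohort(
    tracks: pd.DataFrame,
    flow: FlowContext | None,
    params: ClassificationParams = ClassificationParams(),
    frame_interval_s: float = 1.0,
) -> tuple[list[ClassifiedTrack], float]:
    """Classify every track of a trajectory table; returns (tracks, u_ref)."""
    u_ref, _ = reference_velocity(tracks, flow, params, frame_interval_s)
    out = [
        classify_track(g, u_ref, params, frame_interval_s)
        for _, g in tracks.groupby("track_id", sort=True)
    ]
    return out, u_ref


@dataclass(frozen=True)
class CohortSummary:
    """Per-condition counts, percentages and rolling-velocity distribution.

    Percentages divide class counts by the total number of spheroids that
    transited the field during the recording (pooled across fields).
    """

    condition: str
    shear_dyn_cm2: float
    n_total: int
    n_tethering: int
    n_rolling: int
    n_adhesion: int
    rolling_velocities_um_s: tuple[float, ...] = ()
    empty: bool = False

    def __post_init__(self) -> None:
        if self.n_tethering + self.n_rolling + self.n_adhesion > self.n_total:
            raise ValueError("class counts exceed the cohort total")

    def _pct(self, count: int) -> float:
        return 100.0 * count / self.n_total if self.n_total else 0.0

    @property
    def pct_tethering(self) -> float:
        return self._pct(self.n_tethering)

    @property
    def pct_rolling(self) -> float:
        return self._pct(self.n_rolling)

    @property
    def pct_adhesion(self) -> float:
        return self._pct(self.n_adhesion)

    @property
    def median_rolling_velocity_um_s(self) -> float | None:
        if not self.rolling_velocities_um_s:
            return None
        return float(np.median(self.rolling_velocities_um_s))

    def to_row(self) -> dict:
        return {
            "condition": self.condition,
            "shear_dyn_cm2": self.shear_dyn_cm2,
            "n_total": self.n_total,
            "n_tethering": self.n_tethering,
            "n_rolling": self.n_rolling,
            "n_adhesion": self.n_adhesion,
            "pct_tethering": self.pct_tethering,
            "pct_rolling": self.pct_rolling,
            "pct_adhesion": self.pct_adhesion,
            "median_rolling_velocity_um_s": self.median_rolling_velocity_um_s,
        }


def summarize_cohort(
    classified: list[ClassifiedTrack],
    condition: str,
    shear_dyn_cm2: float,
    params: ClassificationParams = ClassificationParams(),
) -> CohortSummary:
    """Pool classified tracks of one condition/shear into a CohortSummary.

    Single-frame tracks enter the denominator only when the configured
    policy counts them.  An empty input yields an explicit empty-cohort
    summary rather than a division by zero.
    """
    kept = [
        c
        for c in classified
        if params.count_single_frame_tracks or "single_frame" not in c.flags
    ]
    if not kept:
        return CohortSummary(condition, shear_dyn_cm2, 0, 0, 0, 0, (), empty=True)
    by = {cls: sum(1 for c in kept if c.motion_class == cls) for cls in
          (CLASS_TETHERING, CLASS_ROLLING, CLASS_ADHESION)}
    velocities = tuple(
        c.rolling_velocity_um_s
        for c in kept
        if c.motion_class == CLASS_ROLLING and c.rolling_velocity_um_s is not None
    )
    return CohortSummary(
        condition,
        shear_dyn_cm2,
        len(kept),
        by[CLASS_TETHERING],
        by[CLASS_ROLLING],
        by[CLASS_ADHESION],
        velocities,
    )


def detachment_fraction(
    adherent_ids: set[int] | list[int],
    step_observations: list[pd.DataFrame],
    ramp: ShearRamp,
    u_ref: float,
    params: ClassificationParams = ClassificationParams(),
    frame_interval_s: float = 1.0,
) -> pd.DataFrame:
    """Measured survival of initially adherent spheroids along a shear ramp.

    For each ramp step the fraction of the initially adherent set still
    satisfying the adhesion criterion in that step's observation block is
    reported; tracks absent from a block count as detached.  The measured
    curve is not forced monotone.
    """
    if not adherent_ids:
        raise ValueError("the pre-ramp adherent set is empty")
    if len(step_observations) != len(ramp):
        raise ValueError(
            f"{len(step_observations)} observation blocks for {len(ramp)} ramp steps"
        )
    ids = set(int(i) for i in adherent_ids)
    records = []
    for (tau, hold), obs in zip(ramp.steps, step_observations):
        still = 0
        if len(obs):
            for tid, g in obs.groupby("track_id"):
                if int(tid) in ids and (
                    classify_track(g, u_ref, params, frame_interval_s).motion_class
                    == CLASS_ADHESION
                ):
                    still += 1
        records.append((tau, hold, still, still / len(ids)))
    return pd.DataFrame(
        records,
        columns=["shear_dyn_cm2", "hold_s", "n_remaining", "fraction_remaining"],
    )
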