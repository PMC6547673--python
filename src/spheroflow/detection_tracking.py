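"""Spheroid detection and frame-to-frame track linking.

Detection is intentionally simple — the imaged objects are bright, sparse,
70–100 um fluorescent spheroids on a dark background: median background
subtraction, Otsu thresholding, connected components, an equivalent-diameter
size gate matching the cell-strainer gate used at collection, and
intensity-weighted sub-pixel centroids.  The reported diameter comes from
the component's area at half its peak intensity, which for a soft-edged
blob recovers the true diameter almost independently of the threshold.

Linking is greedy nearest-neighbour with a flow-aware asymmetric gate: a
candidate match may lie up to ``gate_factor * u_h * dt`` downstream of the
track head but only one diameter upstream or sideways, because at 1 frame/s
a free spheroid travels one to three diameters downstream per frame while
an arrested one stays put.  One missed detection is tolerated (track
memory of one frame).

Coordinates follow the shared convention: x downstream, y transverse,
origin at the field's upstream-left corner, units um, 0-based frames.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from .flow_geometry import FlowContext, hydrodynamic_velocity

__all__ = [
    "DETECTION_COLUMNS",
    "CalibrationError",
    "detect_spheroids",
    "detect_stack",
    "apply_track_gate",
    "link_tracks",
    "track_qc",
    "read_image_stack",
]

DETECTION_COLUMNS = ["frame", "x_um", "y_um", "diameter_um", "intensity", "field_id"]

_MIN_COMPONENT_PX = 9  # specks smaller than this are noise, not rejected objects


class CalibrationError(ValueError):
    """Pixel size or frame interval missing where required."""


def detect_spheroids(
    image: np.ndarray,
    pixel_size_um: float,
    size_gate_um: tuple[float, float] | None = (70.0, 100.0),
    frame: int = 0,
    field_id: int = 0,
    gate_margin_um: float = 5.0,
) -> pd.DataFrame:
    """Detect fluorescent spheroids in a single 2D frame.

    Returns a detection table (frame, x_um, y_um, diameter_um, intensity,
    field_id); ``df.attrs["n_gate_rejected"]`` counts components whose
    half-maximum equivalent diameter fell outside the gate.  The per-frame
    gate is widened by ``gate_margin_um`` so that objects at the gate
    boundary do not flicker in and out with measurement noise; the exact
    gate is re-applied per track on the median diameter (see
    :func:`apply_track_gate`).  A constant or effectively blank frame
    yields an empty table with a warning.
    """
    if pixel_size_um <= 0:
        raise CalibrationError("pixel size must be positive")
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single 2D frame")
    empty = pd.DataFrame(columns=DETECTION_COLUMNS)
    empty.attrs["n_gate_rejected"] = 0
    background = float(np.median(img))
    sub = np.clip(img - background, 0, None)
    if img.max() == img.min():
        warnings.warn("constant image; no detections")
        return empty
    thr = threshold_otsu(img) - background
    noise = 1.4826 * float(np.median(np.abs(img - background)))
    if thr < 3.0 * noise:
        warnings.warn("no foreground above noise; no detections")
        return empty

    mask = sub > thr
    coarse, _ = ndimage.label(mask)
    # watershed on the distance transform separates touching spheroids
    # (marker spacing just under half the smallest admissible diameter)
    d_lo = size_gate_um[0] if size_gate_um is not None else 40.0
    min_dist = max(3, int(0.45 * d_lo / pixel_size_um))
    distance = ndimage.distance_transform_edt(mask)
    peaks = peak_local_max(
        distance, min_distance=min_dist, labels=coarse, exclude_border=False
    )
    markers = np.zeros_like(coarse)
    for k, (py, px_) in enumerate(peaks, start=1):
        markers[py, px_] = k
    if markers.max() > 0:
        labels = watershed(-distance, markers, mask=mask)
        n = int(markers.max())
    else:
        labels, n = coarse, int(coarse.max())
    rows = []
    rejected = 0
    for idx in range(1, n + 1):
        region = labels == idx
        if int(region.sum()) < _MIN_COMPONENT_PX:
            continue
        values = sub[region]
        # plateau intensity: averaging the top of the profile suppresses the
        # positive bias a single noisy maximum would put on the half level
        vmax = float(values.max())
        peak = float(values[values >= 0.8 * vmax].mean())
        core = region & (sub >= 0.5 * peak)
        half_area = int(np.count_nonzero(core))
        diameter = 2.0 * np.sqrt(half_area / np.pi) * pixel_size_um
        if size_gate_um is not None and not (
            size_gate_um[0] - gate_margin_um
            <= diameter
            <= size_gate_um[1] + gate_margin_um
        ):
            rejected += 1
            continue
        # centre of mass over the plateau core only: the faint skirt of a
        # touching neighbour would otherwise drag the centroid by several um
        weights = np.where(core, sub, 0.0)
        cy, cx = ndimage.center_of_mass(weights)
        rows.append(
            (
                frame,
                cx * pixel_size_um,
                cy * pixel_size_um,
                diameter,
                float(weights.sum()),
                field_id,
            )
        )
    out = pd.DataFrame(rows, columns=DETECTION_COLUMNS)
    out.attrs["n_gate_rejected"] = rejected
    return out


def detect_stack(
    stack: np.ndarray,
    pixel_size_um: float,
    size_gate_um: tuple[float, float] | None = (70.0, 100.0),
    field_id: int = 0,
    gate_margin_um: float = 5.0,
) -> pd.DataFrame:
    """Run :func:`detect_spheroids` over every frame of a (T, H, W) stack."""
    parts = []
    rejected = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # blank individual frames are routine
        for t in range(stack.shape[0]):
            det = detect_spheroids(
                stack[t], pixel_size_um, size_gate_um, frame=t,
                field_id=field_id, gate_margin_um=gate_margin_um,
            )
            rejected += det.attrs["n_gate_rejected"]
            if len(det):
                parts.append(det)
    out = (
        pd.concat(parts, ignore_index=True)
        if parts
        else pd.DataFrame(columns=DETECTION_COLUMNS)
    )
    out.attrs["n_gate_rejected"] = rejected
    return out


def apply_track_gate(
    tracks: pd.DataFrame, size_gate_um: tuple[float, float] = (70.0, 100.0)
) -> pd.DataFrame:
    """Drop tracks whose median diameter lies outside the size gate.

    The per-detection gate is deliberately loose (measurement noise);
    pooling each track's diameters makes the final gating decision once per
    spheroid.
    """
    if len(tracks) == 0:
        return tracks
    med = tracks.groupby("track_id")["diameter_um"].median()
    keep = med[(med >= size_gate_um[0]) & (med <= size_gate_um[1])].index
    return tracks[tracks["track_id"].isin(keep)].reset_index(drop=True)


def link_tracks(
    detections: pd.DataFrame,
    flow: FlowContext,
    frame_interval_s: float = 1.0,
    gate_factor: float = 1.5,
    memory: int = 1,
    condition: str = "",
) -> pd.DataFrame:
    """Greedy nearest-neighbour linking of detections into tracks.

    For each frame, candidate (track, detection) pairs must satisfy the
    asymmetric gate — at most ``gate_factor * u_h(d) * dt * gap`` downstream,
    one diameter upstream, one diameter laterally — and are matched greedily
    by distance to the track's constant-velocity predicted position (an
    arrested spheroid is expected where it was, a free one a hydrodynamic
    step downstream), which disambiguates movers overtaking arrested
    spheroids.  Unmatched detections open new tracks; tracks unseen for
    more than ``memory`` frames close.  Returns a trajectory table in the
    shared schema.  Linking is invariant to row order of the input (a
    stable sort is applied first).
    """
    if frame_interval_s <= 0:
        raise CalibrationError("frame interval must be positive")
    if len(detections) == 0:
        return pd.DataFrame(
            columns=["frame", "track_id", "x_um", "y_um", "diameter_um",
                     "condition", "field_id"]
        )
    dets = detections.sort_values(
        ["frame", "x_um", "y_um"], kind="stable"
    ).reset_index(drop=True)

    next_id = 0
    active: list[dict] = []
    rows: list[tuple] = []

    for frame in sorted(dets["frame"].unique()):
        frame = int(frame)
        sub = dets[dets["frame"] == frame]
        active = [tr for tr in active if frame - tr["last_frame"] <= memory + 1]
        candidates = []
        for ti, tr in enumerate(active):
            gap = frame - tr["last_frame"]
            d = tr["diameter"]
            u_step = hydrodynamic_velocity(flow, d) * frame_interval_s
            reach = gate_factor * u_step * gap
            # candidate hypotheses for the track's next position: arrested
            # (stay), constant velocity, or free hydrodynamic transport —
            # a fresh track has no velocity estimate, so the hydrodynamic
            # hypothesis keeps a free spheroid's own downstream detection
            # cheaper than a lateral neighbour's
            preds = [
                (tr["x"], tr["y"]),
                (tr["x"] + tr["vx"] * gap, tr["y"] + tr["vy"] * gap),
                (tr["x"] + u_step * gap, tr["y"]),
            ]
            for di, det in enumerate(sub.itertuples()):
                dx = det.x_um - tr["x"]
                dy = det.y_um - tr["y"]
                if -d <= dx <= max(reach, d) and abs(dy) <= d:
                    cost = min(
                        float(np.hypot(det.x_um - px, det.y_um - py))
                        for px, py in preds
                    )
                    candidates.append((cost, ti, di))
        candidates.sort()
        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        for _, ti, di in candidates:
            if ti in used_tracks or di in used_dets:
                continue
            used_tracks.add(ti)
            used_dets.add(di)
            det = sub.iloc[di]
            tr = active[ti]
            gap = frame - tr["last_frame"]
            tr["vx"] = (det["x_um"] - tr["x"]) / gap
            tr["vy"] = (det["y_um"] - tr["y"]) / gap
            tr.update(x=det["x_um"], y=det["y_um"], last_frame=frame)
            tr["diameters"].append(det["diameter_um"])
            tr["diameter"] = float(np.median(tr["diameters"]))
            rows.append(
                (frame, tr["id"], det["x_um"], det["y_um"], det["diameter_um"],
                 condition, int(det["field_id"]))
            )
        for di, det in enumerate(sub.itertuples()):
            if di in used_dets:
                continue
            active.append(
                dict(
                    id=next_id,
                    x=det.x_um,
                    y=det.y_um,
                    vx=0.0,
                    vy=0.0,
                    diameter=det.diameter_um,
                    diameters=[det.diameter_um],
                    last_frame=frame,
                )
            )
            rows.append(
                (frame, next_id, det.x_um, det.y_um, det.diameter_um,
                 condition, int(det.field_id))
            )
            next_id += 1

    return pd.DataFrame(
        rows,
        columns=["frame", "track_id", "x_um", "y_um", "diameter_um",
                 "condition", "field_id"],
    )


def track_qc(tracks: pd.DataFrame, n_gate_rejected: int = 0) -> dict:
    """Quality-control report for a trajectory table (pure; input untouched).

    Reports per-field track counts, the track-length histogram, the
    fraction of single-frame tracks (whose denominator treatment is a
    configuration policy) and the detector's gate-rejection count.
    """
    if len(tracks) == 0:
        return {
            "n_tracks": 0,
            "per_field_tracks": {},
            "track_length_histogram": {},
            "fraction_single_frame": 0.0,
            "n_gate_rejected": n_gate_rejected,
        }
    lengths = tracks.groupby("track_id").size()
    per_field = (
        tracks.groupby("field_id")["track_id"].nunique().astype(int).to_dict()
    )
    hist = lengths.value_counts().sort_index()
    return {
        "n_tracks": int(lengths.size),
        "per_field_tracks": per_field,
        "track_length_histogram": {int(k): int(v) for k, v in hist.items()},
        "fraction_single_frame": float((lengths == 1).mean()),
        "n_gate_rejected": n_gate_rejected,
    }


def read_image_stack(path) -> tuple[np.ndarray, dict]:
    """Read a multi-page TIFF stack and its calibration metadata sidecar.

    Returns (stack, metadata); metadata holds pixel_size_um and
    frame_interval_s when the writer recorded them in the image description.
    """
    import tifffile

    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        meta: dict = {}
        desc = tif.pages[0].description
        if desc:
            try:
                meta = json.loads(desc)
            except (TypeError, json.JSONDecodeError):
                meta = {}
    if stack.ndim == 2:
        stack = stack[None]
    return stack, meta
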