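"""Synthetic perfusion cohorts with catch-slip adhesion kinetics.

The raw videos behind the assay are not public, so this module generates
trajectory tables (and optionally rendered image stacks) with the
statistical structure the analysis assumes.  Each spheroid enters the
imaged field at the upstream edge at a random frame, is carried at its
near-wall hydrodynamic velocity, and evolves by a discrete-time Markov
chain over four latent states::

    free --k_on--> tethered --k_arrest--------> adherent (absorbing)
                   tethered --k_release-------> free      ("tethering" event)
                   tethered --k_off(tau)------> rolling   (first bond breaks
                                                           under load, motion
                                                           continues on
                                                           successive bonds)
    rolling --k_arrest--> adherent
    rolling --k_off(tau)--> free

The bond off-rate follows a two-pathway catch-slip law with wall shear as
the force proxy,

    k_off(tau) = a * exp(-tau / f_c) + b * exp(tau / f_s),

which has a lifetime maximum at intermediate shear and therefore produces
the threshold-shear capture optimum characteristic of selectin-mediated
rolling.  Rates are converted to per-frame probabilities 1 - exp(-rate*dt),
matching the 1 frame/s observation process.

Firm (post-arrest) bonds are far more shear-resistant than tethers and get
their own catch-slip parameters, used by the detachment-ramp simulation.

All kinetic rate values are calibration artifacts of this package — the
assay itself reports no rates — chosen once so the simulated shear sweep
peaks at 0.05 dyn cm^-2 and the two default conditions contrast the way
the metastatic / non-metastatic cohorts do.  See docs/methods.md.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace, asdict

import numpy as np
import pandas as pd
from scipy.special import erfc

from .flow_geometry import FlowContext, ShearRamp, hydrodynamic_velocity

__all__ = [
    "STATE_FREE",
    "STATE_TETHERED",
    "STATE_ROLLING",
    "STATE_ADHERENT",
    "STATE_EXITED",
    "BondModel",
    "FirmBondModel",
    "SimulationConfig",
    "TRAJECTORY_COLUMNS",
    "metastatic_bond",
    "nonmetastatic_bond",
    "study_config",
    "expected_arrivals_per_field",
    "simulate_trajectories",
    "analytic_outcome_probabilities",
    "transition_probabilities",
    "simulate_detachment",
    "render_image_stack",
    "write_image_stack",
    "generate_two_condition_cohort",
]

STATE_FREE = "free"
STATE_TETHERED = "tethered"
STATE_ROLLING = "rolling"
STATE_ADHERENT = "adherent"
STATE_EXITED = "exited"

TRAJECTORY_COLUMNS = [
    "frame",
    "track_id",
    "x_um",
    "y_um",
    "diameter_um",
    "condition",
    "field_id",
]


@dataclass(frozen=True)
class BondModel:
    """Tether-scale adhesion kinetics (rates in s^-1, force scales in dyn cm^-2).

    ``rolling_speed_fraction`` is the rolling translation speed as a fraction
    of the free hydrodynamic velocity.
    """

    k_on: float = 0.1967
    catch_amplitude: float = 16100.0
    catch_scale: float = 0.004
    slip_amplitude: float = 0.00155
    slip_scale: float = 0.012
    arrest_rate: float = 0.08
    release_to_free_rate: float = 0.40
    rolling_speed_fraction: float = 0.15

    def __post_init__(self) -> None:
        for name in (
            "k_on",
            "catch_amplitude",
            "slip_amplitude",
            "arrest_rate",
            "release_to_free_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.catch_scale <= 0 or self.slip_scale <= 0:
            raise ValueError("force scales must be positive")
        if not (0 <= self.rolling_speed_fraction < 1):
            raise ValueError("rolling_speed_fraction must lie in [0, 1)")

    def off_rate(self, tau_dyn_cm2: float) -> float:
        """Catch-slip bond rupture rate at wall shear tau."""
        return self.catch_amplitude * math.exp(
            -tau_dyn_cm2 / self.catch_scale
        ) + self.slip_amplitude * math.exp(tau_dyn_cm2 / self.slip_scale)


@dataclass(frozen=True)
class FirmBondModel:
    """Post-arrest bond kinetics governing the detachment ramp.

    Much more shear-resistant than tethers: survival persists up to a few
    dyn cm^-2 and collapses near 4 dyn cm^-2 under the default parameters.
    """

    catch_amplitude: float = 0.05
    catch_scale: float = 0.50
    slip_amplitude: float = 0.001
    slip_scale: float = 0.60

    def off_rate(self, tau_dyn_cm2: float) -> float:
        return self.catch_amplitude * math.exp(
            -tau_dyn_cm2 / self.catch_scale
        ) + self.slip_amplitude * math.exp(tau_dyn_cm2 / self.slip_scale)


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one simulated perfusion condition.

    ``arrivals_per_field`` overrides the density-derived Poisson mean when
    set; ``arrival_mode`` "poisson" staggers entries uniformly over the
    recording, "burst" injects all spheroids at frame 0 (useful when an
    exactly known exposure time is wanted).  ``edta_mode`` emulates calcium
    chelation: no new bonds form (k_on = 0) and every off-rate is multiplied
    by ``edta_off_multiplier``.

    Diameters follow a normal distribution truncated to
    ``diameter_range_um`` — a cell-strainer gate applied to a roughly
    normal size population, so sizes right at the gate edges are rare.
    """

    flow: FlowContext = field(default_factory=lambda: FlowContext.from_shear(0.05))
    bond: BondModel = field(default_factory=BondModel)
    firm_bond: FirmBondModel = field(default_factory=FirmBondModel)
    diameter_range_um: tuple[float, float] = (70.0, 100.0)
    diameter_mean_um: float = 85.0
    diameter_sd_um: float = 7.0
    density_per_mL: float = 1500.0
    arrivals_per_field: float | None = None
    arrival_mode: str = "poisson"
    frame_interval_s: float = 1.0
    duration_s: float = 30.0
    n_fields: int = 3
    seed: int = 0
    condition: str = "condition"
    edta_mode: bool = False
    edta_off_multiplier: float = 50.0
    jitter_um: float = 1.0
    pixel_size_um: float = 4.0
    background_level: float = 100.0
    peak_intensity: float = 2000.0

    def __post_init__(self) -> None:
        if self.frame_interval_s <= 0:
            raise ValueError("frame interval must be positive")
        n = self.duration_s / self.frame_interval_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration must be an integer multiple of the frame interval")
        lo, hi = self.diameter_range_um
        if not (0 < lo <= hi < self.flow.geometry.height_um):
            raise ValueError("diameter range must lie within (0, channel height)")
        if self.n_fields < 1:
            raise ValueError("need at least one field")
        if self.arrival_mode not in ("poisson", "burst"):
            raise ValueError("arrival_mode must be 'poisson' or 'burst'")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s / self.frame_interval_s))

    def effective_bond(self) -> BondModel:
        """Bond model with the EDTA perturbation applied, if requested."""
        if not self.edta_mode:
            return self.bond
        m = self.edta_off_multiplier
        return replace(
            self.bond,
            k_on=0.0,
            catch_amplitude=self.bond.catch_amplitude * m,
            slip_amplitude=self.bond.slip_amplitude * m,
        )

    def firm_off_rate(self, tau_dyn_cm2: float) -> float:
        rate = self.firm_bond.off_rate(tau_dyn_cm2)
        return rate * self.edta_off_multiplier if self.edta_mode else rate

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d["flow"] = {
            "wall_shear_dyn_cm2": self.flow.wall_shear_dyn_cm2,
            "flow_rate_uL_min": self.flow.flow_rate_uL_min,
            "k_wall": self.flow.k_wall,
            "viscosity_cP": self.flow.fluid.viscosity_cP,
            "geometry_um": {
                "width": self.flow.geometry.width_um,
                "height": self.flow.geometry.height_um,
                "length": self.flow.geometry.length_um,
                "field_of_view": list(self.flow.geometry.field_of_view_um),
            },
        }
        return d


# ---------------------------------------------------------------------------
# Default two-condition presets
# ---------------------------------------------------------------------------

def metastatic_bond() -> BondModel:
    """High-avidity condition: frequent capture, slow rolling, strong arrest."""
    return BondModel()


def nonmetastatic_bond() -> BondModel:
    """Low-avidity condition: sparser capture and faster rolling."""
    return BondModel(k_on=0.0551, rolling_speed_fraction=0.25)


def study_config(
    condition: str = "M-CSC",
    wall_shear_dyn_cm2: float = 0.05,
    seed: int = 0,
    n_fields: int = 3,
    arrivals_per_field: float | None = 12.0,
    **overrides,
) -> SimulationConfig:
    """Preset emulating one perfusion condition of the assay.

    "M-CSC" uses the high-avidity bond model, "NM-CSC" the low-avidity one;
    any other label defaults to the high-avidity model unless a ``bond``
    override is supplied.
    """
    bond = overrides.pop(
        "bond", nonmetastatic_bond() if condition == "NM-CSC" else metastatic_bond()
    )
    return SimulationConfig(
        flow=FlowContext.from_shear(wall_shear_dyn_cm2),
        bond=bond,
        condition=condition,
        seed=seed,
        n_fields=n_fields,
        arrivals_per_field=arrivals_per_field,
        **overrides,
    )


def expected_arrivals_per_field(config: SimulationConfig) -> float:
    """Density-derived mean spheroid arrivals per field per recording.

    density (mL^-1) x Q x duration x (lateral fraction of the channel that
    the field of view covers).  With the default chamber this is well below
    one spheroid per recording; the study presets therefore override it.
    """
    if config.arrivals_per_field is not None:
        return float(config.arrivals_per_field)
    q_uL_s = config.flow.flow_rate_uL_min / 60.0
    per_uL = config.density_per_mL / 1000.0
    fov_y = config.flow.geometry.field_of_view_um[1]
    frac = min(1.0, fov_y / config.flow.geometry.width_um)
    return per_uL * q_uL_s * config.duration_s * frac


# ---------------------------------------------------------------------------
# The discrete-time chain
# ---------------------------------------------------------------------------

def transition_probabilities(
    bond: BondModel, tau_dyn_cm2: float, dt_s: float
) -> dict[str, dict[str, float]]:
    """Per-frame transition probabilities of the latent chain at shear tau.

    Competing exponential rates are discretised exactly: an event occurs
    within dt with probability 1 - exp(-R*dt) (R the total exit rate) and is
    attributed to each channel in proportion to its rate.
    """
    k_off = bond.off_rate(tau_dyn_cm2)
    table: dict[str, dict[str, float]] = {}
    for state, rates in (
        (STATE_FREE, {STATE_TETHERED: bond.k_on}),
        (
            STATE_TETHERED,
            {
                STATE_ADHERENT: bond.arrest_rate,
                STATE_FREE: bond.release_to_free_rate,
                STATE_ROLLING: k_off,
            },
        ),
        (
            STATE_ROLLING,
            {STATE_ADHERENT: bond.arrest_rate, STATE_FREE: k_off},
        ),
        (STATE_ADHERENT, {}),
    ):
        total = sum(rates.values())
        probs = {}
        if total > 0:
            p_event = 1.0 - math.exp(-total * dt_s)
            for target, rate in rates.items():
                probs[target] = p_event * rate / total
        probs[state] = probs.get(state, 0.0) + (1.0 - sum(probs.values()))
        table[state] = probs
    return table


def _sample_diameter(rng: np.random.Generator, config: SimulationConfig) -> float:
    """Draw one spheroid diameter from the truncated normal size model."""
    lo, hi = config.diameter_range_um
    if config.diameter_sd_um <= 0:
        return float(min(max(config.diameter_mean_um, lo), hi))
    for _ in range(1000):
        d = rng.normal(config.diameter_mean_um, config.diameter_sd_um)
        if lo <= d <= hi:
            return float(d)
    return float(min(max(config.diameter_mean_um, lo), hi))


def _state_speed(state: str, u_h: float, rho: float) -> float:
    if state == STATE_FREE:
        return u_h
    if state == STATE_ROLLING:
        return rho * u_h
    return 0.0


def simulate_trajectories(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one condition; returns (trajectory table, ground truth).

    The trajectory table has the shared schema (frame, track_id, x_um, y_um,
    diameter_um, condition, field_id); the ground-truth table adds the
    per-frame ``latent_state``.  Output is reproducible from ``config.seed``
    via per-field child streams.

    Spheroids are rigid bodies: entries that would interpenetrate a
    near-simultaneous arrival are resampled, and a spheroid passing over an
    arrested one cannot initiate a tether there (the parked spheroid
    occludes the substrate).
    """
    if config.flow.wall_shear_dyn_cm2 == 0:
        warnings.warn("tau = 0: no transport; spheroids will not traverse the field")
    bond = config.effective_bond()
    tau = config.flow.wall_shear_dyn_cm2
    dt = config.frame_interval_s
    n_frames = config.n_frames
    fov_x, fov_y = config.flow.geometry.field_of_view_um
    y_extent = min(fov_y, config.flow.geometry.width_um)
    trans = transition_probabilities(bond, tau, dt)
    mean_arrivals = expected_arrivals_per_field(config)

    rows: list[tuple] = []
    truth_rows: list[tuple] = []
    track_counter = 0
    field_seeds = np.random.SeedSequence(config.seed).spawn(config.n_fields)
    for field_id in range(config.n_fields):
        rng = np.random.default_rng(field_seeds[field_id])
        n_arrivals = rng.poisson(mean_arrivals)
        spheroids: list[dict] = []
        for _ in range(n_arrivals):
            d = _sample_diameter(rng, config)
            margin = min(d / 2.0, y_extent / 2.0)
            # rigid spheroids cannot interpenetrate: resample entries that
            # would overlap a near-simultaneous arrival at the inlet
            for _attempt in range(25):
                if config.arrival_mode == "burst":
                    entry = 0
                else:
                    entry = int(rng.integers(0, n_frames))
                y = rng.uniform(margin, y_extent - margin)
                if not any(
                    abs(entry - s["entry"]) <= 2 and abs(y - s["y"]) < 1.2 * max(d, s["d"])
                    for s in spheroids
                ):
                    break
            spheroids.append(
                dict(
                    id=track_counter,
                    d=d,
                    u_h=hydrodynamic_velocity(config.flow, d),
                    entry=entry,
                    # centroid starts just fully inside the upstream edge;
                    # the track ends once no longer fully in view
                    x=d / 2.0,
                    y=y,
                    x_exit=fov_x - d / 2.0,
                    state=STATE_FREE,
                    alive=True,
                )
            )
            track_counter += 1

        for frame in range(n_frames):
            stationary = [
                s for s in spheroids
                if s["alive"] and s["entry"] <= frame
                and s["state"] in (STATE_TETHERED, STATE_ADHERENT)
            ]
            for s in spheroids:
                if not s["alive"] or s["entry"] > frame:
                    continue
                jx = jy = 0.0
                if s["state"] in (STATE_TETHERED, STATE_ADHERENT) and config.jitter_um > 0:
                    jx, jy = rng.normal(0.0, config.jitter_um, size=2)
                rows.append(
                    (frame, s["id"], s["x"] + jx, s["y"] + jy, s["d"],
                     config.condition, field_id)
                )
                truth_rows.append(
                    (frame, s["id"], s["x"] + jx, s["y"] + jy, s["d"],
                     config.condition, field_id, s["state"])
                )
                if frame == n_frames - 1:
                    continue
                # advance by the state held during this interval, then draw
                # the state for the next frame
                s["x"] += _state_speed(s["state"], s["u_h"], bond.rolling_speed_fraction) * dt
                probs = trans[s["state"]]
                if s["state"] == STATE_FREE and any(
                    o is not s
                    and np.hypot(s["x"] - o["x"], s["y"] - o["y"])
                    < 0.5 * (s["d"] + o["d"])
                    for o in stationary
                ):
                    # substrate occluded by a parked spheroid: no capture
                    probs = {STATE_FREE: 1.0}
                targets = list(probs)
                s["state"] = targets[
                    rng.choice(len(targets), p=np.array([probs[t] for t in targets]))
                ]
                if s["x"] > s["x_exit"]:
                    s["alive"] = False  # exited; no further observations

    traj = pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)
    truth = pd.DataFrame(truth_rows, columns=TRAJECTORY_COLUMNS + ["latent_state"])
    order = ["track_id", "frame"]
    traj = traj.sort_values(order, kind="stable").reset_index(drop=True)
    truth = truth.sort_values(order, kind="stable").reset_index(drop=True)
    return traj, truth


def analytic_outcome_probabilities(
    config: SimulationConfig, n_diameter_points: int = 9
) -> dict[str, float]:
    """Exact latent-outcome probabilities of the generative chain.

    Dynamic program over (state, frames spent free, frames spent rolling) —
    position is a deterministic function of those counts — marginalised over
    the uniform entry frame (or frame 0 in burst mode) and a midpoint grid
    over the diameter range.  Returns the probability that a spheroid's
    latent state at its last in-field frame is each of free / tethered /
    rolling / adherent, plus ``exited`` (left the field before the end) and
    ``ever_captured`` (left the free state at least once).

    Serves as the independent oracle for the stochastic simulator and for
    calibrating the generative adhesion probabilities.

    ``operational_adhesion`` is the probability of the event the classifier's
    terminal-arrest rule targets: the spheroid is stationary (tethered or
    adherent) over the final observed interval of the recording.  It exceeds
    the latent ``adherent`` mass slightly because a transient tether that
    straddles the end of the recording is observationally indistinguishable
    from firm arrest.
    """
    bond = config.effective_bond()
    tau = config.flow.wall_shear_dyn_cm2
    dt = config.frame_interval_s
    n_frames = config.n_frames
    fov_x = config.flow.geometry.field_of_view_um[0]
    trans = transition_probabilities(bond, tau, dt)
    lo, hi = config.diameter_range_um
    centres = lo + (np.arange(n_diameter_points) + 0.5) * (hi - lo) / n_diameter_points
    if config.diameter_sd_um > 0:
        pdf = np.exp(
            -0.5 * ((centres - config.diameter_mean_um) / config.diameter_sd_um) ** 2
        )
    else:
        pdf = np.ones_like(centres)
    d_weights = pdf / pdf.sum()
    if config.arrival_mode == "burst":
        entries = [0]
    else:
        entries = list(range(n_frames))

    out = {k: 0.0 for k in
           (STATE_FREE, STATE_TETHERED, STATE_ROLLING, STATE_ADHERENT,
            STATE_EXITED, "ever_captured", "operational_adhesion")}
    for d, d_weight in zip(centres, d_weights):
        weight = d_weight / len(entries)
        u_h = hydrodynamic_velocity(config.flow, float(d))
        rho = bond.rolling_speed_fraction
        travel = fov_x - float(d)  # centroid travels from d/2 to fov_x - d/2
        for entry in entries:
            # key: (state, n_free, n_roll, captured_flag) -> probability
            dist = {(STATE_FREE, 0, 0, 0): 1.0}
            exited = 0.0
            exited_captured = 0.0
            for step in range(n_frames - 1 - entry):
                if step == n_frames - 2 - entry and step > 0:
                    out["operational_adhesion"] += weight * sum(
                        p for (s, _, _, _), p in dist.items()
                        if s in (STATE_TETHERED, STATE_ADHERENT)
                    )
                new: dict = {}
                for (state, nf, nr, cap), p in dist.items():
                    nf2, nr2 = nf + int(state == STATE_FREE), nr + int(state == STATE_ROLLING)
                    x = u_h * dt * nf2 + rho * u_h * dt * nr2
                    if x > travel:
                        exited += p
                        exited_captured += p * cap
                        continue
                    for target, q in trans[state].items():
                        if q == 0.0:
                            continue
                        cap2 = cap or int(target != STATE_FREE)
                        key = (target, nf2, nr2, cap2)
                        new[key] = new.get(key, 0.0) + p * q
                dist = new
            for (state, _nf, _nr, cap), p in dist.items():
                out[state] += weight * p
                out["ever_captured"] += weight * p * cap
            out[STATE_EXITED] += weight * exited
            out["ever_captured"] += weight * exited_captured
    return out


# ---------------------------------------------------------------------------
# Detachment ramp
# ---------------------------------------------------------------------------

def simulate_detachment(
    config: SimulationConfig, ramp: ShearRamp, n_adherent: int
) -> pd.DataFrame:
    """Stepwise detachment of firmly adherent spheroids under a shear ramp.

    Each spheroid survives a step of shear tau held for t seconds with
    probability exp(-k_off_firm(tau) * t); the survival curve is therefore
    monotone non-increasing.  Returns a frame with one row per step:
    shear_dyn_cm2, hold_s, n_remaining, fraction_remaining.
    """
    if n_adherent < 1:
        raise ValueError("need at least one adherent spheroid")
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x0DE7AC)))
    remaining = n_adherent
    records = []
    for tau, hold in ramp.steps:
        p_survive = math.exp(-config.firm_off_rate(tau) * hold)
        remaining = int(rng.binomial(remaining, p_survive))
        records.append((tau, hold, remaining, remaining / n_adherent))
    return pd.DataFrame(
        records,
        columns=["shear_dyn_cm2", "hold_s", "n_remaining", "fraction_remaining"],
    )


# ---------------------------------------------------------------------------
# Image rendering
# ---------------------------------------------------------------------------

class RenderingResolutionError(ValueError):
    """Spheroids would span fewer than 2 pixels at the chosen pixel size."""


def _draw_blob(frame: np.ndarray, cx: float, cy: float, radius_px: float,
               peak: float, edge_sigma_px: float = 1.5) -> None:
    """Compose a soft-edged disc (half-maximum at ``radius_px``) into ``frame``.

    Opaque bodies: overlapping discs take the pointwise maximum rather than
    summing, so a pair of touching spheroids stays at plateau brightness.
    """
    h, w = frame.shape
    pad = int(math.ceil(radius_px + 4 * edge_sigma_px))
    x0, x1 = max(0, int(cx) - pad), min(w, int(cx) + pad + 1)
    y0, y1 = max(0, int(cy) - pad), min(h, int(cy) + pad + 1)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    r = np.hypot(xx - cx, yy - cy)
    blob = peak * 0.5 * erfc((r - radius_px) / (math.sqrt(2) * edge_sigma_px))
    np.maximum(frame[y0:y1, x0:x1], blob, out=frame[y0:y1, x0:x1])


def render_image_stack(
    trajectories: pd.DataFrame, config: SimulationConfig, field_id: int = 0
) -> np.ndarray:
    """Render one field's trajectories as a 16-bit (T, H, W) image stack.

    Each spheroid is drawn as a soft-edged disc whose full width at half
    maximum equals its diameter; Poisson noise is applied on top of a flat
    fluorescence background.  An empty trajectory table yields pure-noise
    frames.  Reproducible from the configuration seed.
    """
    px = config.pixel_size_um
    if px <= 0:
        raise ValueError("pixel size must be positive")
    if config.diameter_range_um[0] / px < 2:
        raise RenderingResolutionError(
            f"spheroids span < 2 px at {px} um/px; decrease the pixel size"
        )
    fov_x, fov_y = config.flow.geometry.field_of_view_um
    w, h = int(round(fov_x / px)), int(round(fov_y / px))
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x1A6E, field_id)))
    sub = trajectories[trajectories["field_id"] == field_id] if len(trajectories) else trajectories
    stack = np.empty((config.n_frames, h, w), dtype=np.uint16)
    for t in range(config.n_frames):
        frame = np.full((h, w), float(config.background_level))
        if len(sub):
            for row in sub[sub["frame"] == t].itertuples():
                _draw_blob(
                    frame,
                    row.x_um / px,
                    row.y_um / px,
                    (row.diameter_um / 2.0) / px,
                    config.peak_intensity,
                )
        noisy = rng.poisson(np.clip(frame, 0, None))
        stack[t] = np.clip(noisy, 0, np.iinfo(np.uint16).max).astype(np.uint16)
    return stack


def write_image_stack(path, stack: np.ndarray, config: SimulationConfig) -> None:
    """Write a rendered stack as a multi-page TIFF with calibration metadata."""
    import tifffile

    meta = {
        "pixel_size_um": config.pixel_size_um,
        "frame_interval_s": config.frame_interval_s,
    }
    tifffile.imwrite(path, stack, description=json.dumps(meta))


# ---------------------------------------------------------------------------
# Two-condition cohorts
# ---------------------------------------------------------------------------

class EmptyCohortError(RuntimeError):
    """A condition produced no spheroids at all."""


def generate_two_condition_cohort(
    config_a: SimulationConfig, config_b: SimulationConfig
) -> pd.DataFrame:
    """Pooled labeled trajectory table for two conditions at equal shear.

    Conditions must share the imposed flow (equal wall shear, geometry and
    k_wall) — the assay compares cohorts at matched shear only.
    """
    fa, fb = config_a.flow, config_b.flow
    if (
        fa.wall_shear_dyn_cm2 != fb.wall_shear_dyn_cm2
        or fa.geometry != fb.geometry
        or fa.fluid != fb.fluid
        or fa.k_wall != fb.k_wall
    ):
        raise ValueError("conditions must share the flow context")
    if config_a.condition == config_b.condition:
        raise ValueError("conditions need distinct labels")
    parts = []
    for cfg in (config_a, config_b):
        traj, _ = simulate_trajectories(cfg)
        parts.append(traj)
    pooled = pd.concat(parts, ignore_index=True)
    # keep track ids unique across conditions
    key = pooled["condition"].astype(str) + ":" + pooled["track_id"].astype(str)
    pooled["track_id"] = pd.factorize(key)[0]
    return pooled
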