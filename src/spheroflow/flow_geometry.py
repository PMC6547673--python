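"""Parallel-plate flow-chamber hydrodynamics.

The perfusion assay drives spheroid suspensions through a rectangular
microchannel whose height is much smaller than its width, so the flow is
well approximated by plane Poiseuille flow.  The wall shear stress is then

    tau = 6 * mu * Q / (w * h**2)

with viscosity ``mu``, volumetric flow rate ``Q``, channel width ``w`` and
height ``h``.  A spheroid of diameter ``d`` translating freely near the wall
sees the linear part of the velocity profile; its transport speed is taken
as the fluid velocity at its centre height scaled by a near-wall drag
correction,

    u_h = k_wall * (tau / mu) * (d / 2).

The classical correction for a sphere translating along a plane wall in a
linear shear field gives ``k_wall ~ 0.5676``; ``k_wall = 1`` recovers the
undisturbed fluid velocity.

Units at the interface follow the assay conventions: shear stress in
dyn cm^-2, viscosity in cP, lengths in um, flow rate in uL min^-1,
velocities in um s^-1.  Conversions happen internally in CGS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ChannelGeometry",
    "FluidProperties",
    "FlowContext",
    "ShearRamp",
    "InvalidGeometryError",
    "InvalidSpheroidError",
    "DEFAULT_K_WALL",
    "wall_shear_from_flow_rate",
    "flow_rate_from_shear",
    "hydrodynamic_velocity",
    "make_shear_ramp",
]

#: Goldman–Cox–Brenner translation factor for a sphere in near-wall shear flow.
DEFAULT_K_WALL = 0.5676

_CP_TO_POISE = 1e-2          # 1 cP = 0.01 dyn s cm^-2
_UM_TO_CM = 1e-4
_UL_PER_MIN_TO_CM3_PER_S = 1e-3 / 60.0


class InvalidGeometryError(ValueError):
    """Channel dimensions are unphysical (non-positive width or height)."""


class InvalidSpheroidError(ValueError):
    """Spheroid diameter incompatible with the channel (d >= h or d <= 0)."""


@dataclass(frozen=True)
class ChannelGeometry:
    """Rectangular channel cross-section and imaged field of view, in um.

    ``width`` is the lateral (y) extent, ``height`` the plate gap (z), and
    ``field_of_view`` the (x, y) extent of the imaged region; x increases
    downstream with the origin at the field's upstream-left corner.
    """

    width_um: float = 1000.0
    height_um: float = 150.0
    length_um: float = 10_000.0
    field_of_view_um: tuple[float, float] = (3300.0, 2500.0)

    def __post_init__(self) -> None:
        if not (self.width_um > self.height_um > 0):
            raise InvalidGeometryError(
                f"need width > height > 0, got w={self.width_um}, h={self.height_um}"
            )
        if self.length_um <= 0:
            raise InvalidGeometryError("channel length must be positive")
        fx, fy = self.field_of_view_um
        if fx <= 0 or fy <= 0:
            raise InvalidGeometryError("field-of-view extents must be positive")


@dataclass(frozen=True)
class FluidProperties:
    """Perfusion-buffer properties; 0.9 cP matches ascitic-fluid viscosity."""

    viscosity_cP: float = 0.9

    def __post_init__(self) -> None:
        if self.viscosity_cP <= 0:
            raise ValueError("viscosity must be positive")

    @property
    def viscosity_poise(self) -> float:
        return self.viscosity_cP * _CP_TO_POISE


def wall_shear_from_flow_rate(
    geometry: ChannelGeometry, fluid: FluidProperties, flow_rate_uL_min: float
) -> float:
    """Wall shear stress (dyn cm^-2) for a volumetric flow rate (uL min^-1)."""
    if flow_rate_uL_min < 0:
        raise ValueError("flow rate must be non-negative")
    q = flow_rate_uL_min * _UL_PER_MIN_TO_CM3_PER_S
    w = geometry.width_um * _UM_TO_CM
    h = geometry.height_um * _UM_TO_CM
    return 6.0 * fluid.viscosity_poise * q / (w * h * h)


def flow_rate_from_shear(
    geometry: ChannelGeometry, fluid: FluidProperties, wall_shear_dyn_cm2: float
) -> float:
    """Volumetric flow rate (uL min^-1) producing a wall shear (dyn cm^-2)."""
    if wall_shear_dyn_cm2 < 0:
        raise ValueError("wall shear must be non-negative")
    w = geometry.width_um * _UM_TO_CM
    h = geometry.height_um * _UM_TO_CM
    q = wall_shear_dyn_cm2 * w * h * h / (6.0 * fluid.viscosity_poise)
    return q / _UL_PER_MIN_TO_CM3_PER_S


@dataclass(frozen=True)
class FlowContext:
    """Channel geometry, fluid and imposed flow, with consistent tau and Q.

    Construct with :meth:`from_shear` or :meth:`from_flow_rate` so that the
    two are mutually consistent under the plate formula.
    """

    geometry: ChannelGeometry = field(default_factory=ChannelGeometry)
    fluid: FluidProperties = field(default_factory=FluidProperties)
    wall_shear_dyn_cm2: float = 0.0
    flow_rate_uL_min: float = 0.0
    k_wall: float = DEFAULT_K_WALL

    def __post_init__(self) -> None:
        if self.wall_shear_dyn_cm2 < 0 or self.flow_rate_uL_min < 0:
            raise ValueError("shear and flow rate must be non-negative")
        if not (0 < self.k_wall <= 1):
            raise ValueError("k_wall must lie in (0, 1]")
        expected = wall_shear_from_flow_rate(
            self.geometry, self.fluid, self.flow_rate_uL_min
        )
        scale = max(abs(self.wall_shear_dyn_cm2), abs(expected), 1e-30)
        if abs(expected - self.wall_shear_dyn_cm2) > 1e-9 * scale:
            raise ValueError(
                "wall shear and flow rate are inconsistent under tau = 6*mu*Q/(w*h^2); "
                "use FlowContext.from_shear or .from_flow_rate"
            )

    @classmethod
    def from_shear(
        cls,
        wall_shear_dyn_cm2: float,
        geometry: ChannelGeometry | None = None,
        fluid: FluidProperties | None = None,
        k_wall: float = DEFAULT_K_WALL,
    ) -> "FlowContext":
        geometry = geometry or ChannelGeometry()
        fluid = fluid or FluidProperties()
        q = flow_rate_from_shear(geometry, fluid, wall_shear_dyn_cm2)
        return cls(geometry, fluid, wall_shear_dyn_cm2, q, k_wall)

    @classmethod
    def from_flow_rate(
        cls,
        flow_rate_uL_min: float,
        geometry: ChannelGeometry | None = None,
        fluid: FluidProperties | None = None,
        k_wall: float = DEFAULT_K_WALL,
    ) -> "FlowContext":
        geometry = geometry or ChannelGeometry()
        fluid = fluid or FluidProperties()
        tau = wall_shear_from_flow_rate(geometry, fluid, flow_rate_uL_min)
        return cls(geometry, fluid, tau, flow_rate_uL_min, k_wall)

    def with_shear(self, wall_shear_dyn_cm2: float) -> "FlowContext":
        """Same chamber and fluid at a different imposed wall shear."""
        return FlowContext.from_shear(
            wall_shear_dyn_cm2, self.geometry, self.fluid, self.k_wall
        )

    @property
    def shear_rate_per_s(self) -> float:
        """Wall shear rate gamma-dot = tau / mu, in s^-1."""
        return self.wall_shear_dyn_cm2 / self.fluid.viscosity_poise


def hydrodynamic_velocity(flow: FlowContext, spheroid_diameter_um: float) -> float:
    """Free near-wall transport speed (um s^-1) of a spheroid of diameter d.

    u_h = k_wall * (tau/mu) * (d/2): the linear-shear fluid velocity at the
    spheroid's centre height scaled by the near-wall drag correction.
    """
    d = spheroid_diameter_um
    if not (0 < d < flow.geometry.height_um):
        raise InvalidSpheroidError(
            f"spheroid diameter {d} um must lie in (0, {flow.geometry.height_um}) um"
        )
    return flow.k_wall * flow.shear_rate_per_s * (d / 2.0)


@dataclass(frozen=True)
class ShearRamp:
    """Stepwise shear schedule: ordered (tau dyn cm^-2, hold s) pairs."""

    steps: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.steps) == 0:
            raise ValueError("a shear ramp needs at least one step")
        taus = [t for t, _ in self.steps]
        holds = [h for _, h in self.steps]
        if any(t < 0 for t in taus):
            raise ValueError("shear steps must be non-negative")
        if any(np.diff(taus) < 0):
            raise ValueError("shear steps must be non-decreasing")
        if any(h <= 0 for h in holds):
            raise ValueError("hold durations must be positive")

    @property
    def shear_levels(self) -> np.ndarray:
        return np.array([t for t, _ in self.steps])

    @property
    def hold_durations(self) -> np.ndarray:
        return np.array([h for _, h in self.steps])

    def __len__(self) -> int:
        return len(self.steps)


def make_shear_ramp(
    start_dyn_cm2: float,
    max_dyn_cm2: float,
    n_steps: int,
    hold_s: float,
    spacing: str = "linear",
) -> ShearRamp:
    """Build a monotone shear ramp from start to max inclusive.

    ``spacing`` is "linear" or "geometric"; the last step always equals the
    maximum exactly. Geometric spacing requires a positive start.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if not (0 <= start_dyn_cm2 <= max_dyn_cm2):
        raise ValueError("need 0 <= start <= max")
    if n_steps == 1:
        levels = np.array([max_dyn_cm2])
    elif spacing == "linear":
        levels = np.linspace(start_dyn_cm2, max_dyn_cm2, n_steps)
    elif spacing == "geometric":
        if start_dyn_cm2 <= 0:
            raise ValueError("geometric spacing requires start > 0")
        levels = np.geomspace(start_dyn_cm2, max_dyn_cm2, n_steps)
    else:
        raise ValueError(f"unknown spacing {spacing!r}")
    levels[-1] = max_dyn_cm2
    return ShearRamp(tuple((float(t), float(hold_s)) for t in levels))
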