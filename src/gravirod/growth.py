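"""Active growth and gravi-proprioceptive curvature dynamics.

The shoot elongates uniformly at speed ``v`` within a growing zone of natural
arc length ``Lgz`` measured from the apical end, and the intrinsic curvature
of growing-zone segments evolves by the gravi-proprioceptive law::

    dkappa0/dt = beta * sigma * cos(theta) - gamma * kappa

where ``theta`` is the local tangent angle from the horizontal, ``kappa`` the
realized curvature, ``beta`` the gravitropic and ``gamma`` the proprioceptive
sensitivity, and ``sigma`` (+1/-1) selects the upward-bending sign for the
rod's pointing direction.  Outside the growing zone the target geometry is
frozen.  Each simulation step performs: grow, update intrinsic curvature,
re-equilibrate (recording the force-component displacement decomposition).

Dimensionless groups: sensitivity length ``ls = gamma/beta``, elasto-gravity
length ``Lg = (B/(rho g))^(1/3)``, growth-sensitivity ``S = Lgz/ls`` and
growth-elasto-gravity ``G = Lg/Lgz``.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from gravirod.mechanics import (
    DisplacementRecord,
    ForceSet,
    MechanicalParams,
    RodGeometry,
    RodState,
    equilibrate,
    forces,
    rod_geometry,
)

__all__ = [
    "GrowthParams",
    "DimensionlessGroups",
    "TrajectoryFrame",
    "Trajectory",
    "dimensionless_groups",
    "beta_for_sensitivity",
    "rho_for_elasto_gravity",
    "grow_step",
    "gravi_proprio_update",
    "simulate",
]


@dataclass
class GrowthParams:
    """Growth-zone and sensing parameters.

    growth_speed : v, mm/min (elongation rate of the whole growing zone)
    growth_zone_length : Lgz, mm (natural arc length, measured from the tip)
    gravitropic_sensitivity : beta, 1/(mm*min)
    proprioceptive_sensitivity : gamma, 1/min
    time_step : minutes per simulation step
    t_end : minutes (observation window; 140 as in the experiments)
    upward_sign : sigma, +1 for a rod pointing along +x, -1 for -x
    proprio_on_intrinsic : use kappa0 instead of the realized curvature in
        the proprioceptive term (flagged variant; default uses realized kappa)
    """

    growth_speed: float = 4.0 / 140.0
    growth_zone_length: float = 40.0
    gravitropic_sensitivity: float = 2.0e-3
    proprioceptive_sensitivity: float = 5.0e-2
    time_step: float = 1.0
    t_end: float = 140.0
    upward_sign: int = 1
    proprio_on_intrinsic: bool = False

    def __post_init__(self) -> None:
        if self.growth_speed < 0:
            raise ValueError("growth_speed must be >= 0")
        if self.growth_zone_length <= 0:
            raise ValueError("growth_zone_length must be > 0")
        if self.gravitropic_sensitivity < 0 or self.proprioceptive_sensitivity < 0:
            raise ValueError("sensitivities must be >= 0")
        if self.time_step <= 0:
            raise ValueError("time_step must be > 0")
        if self.upward_sign not in (+1, -1):
            raise ValueError("upward_sign must be +1 or -1")


@dataclass(frozen=True)
class DimensionlessGroups:
    """The model's characteristic lengths and dimensionless parameters."""

    sensitivity_length: float  # ls = gamma/beta, mm
    elasto_gravity_length: float  # Lg = (B/(rho g))^(1/3), mm
    growth_sensitivity: float  # S = Lgz/ls
    growth_elasto_gravity: float  # G = Lg/Lgz


def dimensionless_groups(
    gp: GrowthParams, mp: MechanicalParams
) -> DimensionlessGroups:
    """Compute ls, Lg, S and G from the dimensional parameters."""
    beta = gp.gravitropic_sensitivity
    gamma = gp.proprioceptive_sensitivity
    if beta <= 0 or gamma <= 0:
        raise ValueError("dimensionless groups need beta > 0 and gamma > 0")
    ls = gamma / beta
    lg = mp.elasto_gravity_length
    return DimensionlessGroups(
        sensitivity_length=ls,
        elasto_gravity_length=lg,
        growth_sensitivity=gp.growth_zone_length / ls,
        growth_elasto_gravity=lg / gp.growth_zone_length,
    )


def beta_for_sensitivity(s: float, gamma: float, lgz: float) -> float:
    """Gravitropic sensitivity realizing S = s at fixed gamma and Lgz."""
    if s <= 0 or gamma <= 0 or lgz <= 0:
        raise ValueError("S, gamma and Lgz must be > 0")
    return s * gamma / lgz


def rho_for_elasto_gravity(g_tilde: float, mp: MechanicalParams, lgz: float) -> float:
    """Linear mass density realizing G = g_tilde at fixed B, g and Lgz."""
    if g_tilde <= 0 or lgz <= 0:
        raise ValueError("G and Lgz must be > 0")
    lg = g_tilde * lgz
    return mp.bending_modulus / (mp.gravity * lg**3)


# ----------------------------------------------------------------------
# growth and sensing updates
# ----------------------------------------------------------------------


def _tip_distances(natural_lengths: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Natural arc distance from the apical end for (bond midpoints, vertices)."""
    a = natural_lengths
    # distance from the tip to the far (basal) end of each bond, cumulated
    rev = np.cumsum(a[::-1])[::-1]  # rev[j] = sum a_j..a_{N-2}
    mid = rev - 0.5 * a  # bond midpoint distance from tip
    vert = np.concatenate((rev, [0.0]))  # vertex j distance from tip
    return mid, vert


def grow_step(state: RodState, gp: GrowthParams) -> RodState:
    """Elongate growing-zone bonds by the relative increment (v/Lgz)*dt.

    A bond belongs to the growing zone when its natural-arc-length midpoint
    lies within ``Lgz`` of the apical end.  Intrinsic curvatures are carried
    over unchanged (turning angles follow the updated Voronoi lengths).  The
    basal bond between the two clamped vertices never elongates: its ends are
    frozen, so growing its natural length would only inject spurious
    compression into the clamp.
    """
    out = state.copy()
    mid, _ = _tip_distances(out.natural_lengths)
    grow = mid <= gp.growth_zone_length
    grow[0] = False
    factor = 1.0 + (gp.growth_speed / gp.growth_zone_length) * gp.time_step
    out.natural_lengths[grow] *= factor
    return out


def gravi_proprio_update(
    state: RodState, geom: RodGeometry, gp: GrowthParams
) -> RodState:
    """Apply the gravi-proprioceptive intrinsic-curvature update.

    Only interior vertices within the growing zone (natural arc distance from
    the apical end <= Lgz) are updated; the non-growing zone keeps its target
    geometry.  ``geom`` must describe the current (equilibrated) configuration.
    """
    out = state.copy()
    _, vert = _tip_distances(out.natural_lengths)
    in_zone = vert[1:-1] <= gp.growth_zone_length
    theta = geom.vertex_tangent_angles()[1:-1]
    kappa = (
        out.intrinsic_curvatures if gp.proprio_on_intrinsic else geom.curvatures
    )
    dk = gp.gravitropic_sensitivity * gp.upward_sign * np.cos(
        theta
    ) - gp.proprioceptive_sensitivity * kappa
    out.intrinsic_curvatures[in_zone] += gp.time_step * dk[in_zone]
    return out


# ----------------------------------------------------------------------
# trajectory
# ----------------------------------------------------------------------


@dataclass
class TrajectoryFrame:
    """One stored time point of a simulation.

    ``state``/``geometry`` describe the equilibrium at ``time``.
    ``forces_start`` holds the forces at the start of the relaxation that
    produced this equilibrium (after growth and curvature update);
    ``displacement`` the per-component displacement of that relaxation; and
    ``elongation_rate`` the per-bond relative natural-length growth rate
    (1/min) over the step.  All three are ``None`` on the initial frame.
    """

    time: float
    state: RodState
    geometry: RodGeometry
    forces_start: ForceSet | None = None
    displacement: DisplacementRecord | None = None
    elongation_rate: np.ndarray | None = None


@dataclass
class Trajectory:
    """Time-ordered equilibria with per-step decomposition records."""

    frames: list[TrajectoryFrame]
    mechanical_params: MechanicalParams | None = None
    growth_params: GrowthParams | None = None

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i) -> TrajectoryFrame:
        return self.frames[i]

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    @property
    def lengths(self) -> np.ndarray:
        """Current (equilibrium) total length at each frame."""
        return np.array([f.geometry.total_length for f in self.frames])

    def frame_at(self, t: float, atol: float = 1e-9) -> TrajectoryFrame:
        for f in self.frames:
            if abs(f.time - t) <= atol:
                return f
        raise KeyError(f"no frame at t = {t} min")

    def extension_ratio(self) -> float:
        return float(self.lengths[-1] / self.lengths[0])

    # -- serialization: directory of per-frame RodState CSVs + manifest
    def to_dir(self, path: str) -> None:
        os.makedirs(path, exist_ok=True)
        manifest = {
            "times": [f.time for f in self.frames],
            "residuals": [
                (f.displacement.residual if f.displacement is not None else None)
                for f in self.frames
            ],
            "mechanical_params": (
                vars(self.mechanical_params).copy()
                if self.mechanical_params is not None
                else None
            ),
            "growth_params": (
                vars(self.growth_params).copy()
                if self.growth_params is not None
                else None
            ),
        }
        for idx, f in enumerate(self.frames):
            f.state.to_csv(os.path.join(path, f"frame_{idx:04d}.csv"))
        with open(os.path.join(path, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)


def simulate(
    init: RodState,
    mp: MechanicalParams,
    gp: GrowthParams,
    equilibrate_init: bool = True,
) -> Trajectory:
    """Run the growth/sensing/equilibration loop from t = 0 to t_end.

    Per step: grow the growing-zone bonds, update intrinsic curvatures from
    the current equilibrium geometry, then re-equilibrate, recording the
    starting forces and the per-component displacement decomposition.

    Raises
    ------
    ConvergenceError
        From :func:`gravirod.mechanics.equilibrate`, annotated with the
        offending time step.
    """
    state = init.copy()
    state.time = 0.0
    if equilibrate_init:
        state, _ = equilibrate(state, mp)
    geom = rod_geometry(state)
    frames = [TrajectoryFrame(0.0, state, geom)]

    n_steps = int(round(gp.t_end / gp.time_step))
    for k in range(n_steps):
        t_new = (k + 1) * gp.time_step
        a_old = state.natural_lengths.copy()
        grown = grow_step(state, gp)
        updated = gravi_proprio_update(grown, geom, gp)
        elong = (updated.natural_lengths / a_old - 1.0) / gp.time_step
        f_start = forces(updated, mp)
        try:
            state, rec = equilibrate(updated, mp)
        except Exception as exc:
            raise type(exc)(f"at t = {t_new} min: {exc}") from exc
        state.time = t_new
        geom = rod_geometry(state)
        frames.append(
            TrajectoryFrame(
                t_new,
                state,
                geom,
                forces_start=f_start,
                displacement=rec,
                elongation_rate=elong,
            )
        )
    return Trajectory(frames, mechanical_params=mp, growth_params=gp)
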