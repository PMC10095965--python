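"""Force/displacement decomposition and differential-cell-growth (DCG) maps.

Per simulation step, the displacement of every vertex is already split into
stretching, bending and gravity contributions by the relaxation bookkeeping
(:class:`gravirod.mechanics.DisplacementRecord`).  This module aggregates the
records onto (time x arc-length) maps, projects each contribution onto the
local bending direction, compares force maxima between runs, and computes
flank elongation rates and DCG from the intrinsic geometry of each segment.

Flank lengths at distance R from the centerline use the offset-curve rule
``L(+/-) = a * (1 -/+ R*kappa0*sigma)``: for upward bending (``sigma*kappa0 > 0``)
the inner (concave) flank is the shorter one.  Relative elongation rates are
log-derivatives of the flank lengths between consecutive steps, and
``DCG = Edot_in - Edot_out`` (negative when the outer flank grows faster).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from gravirod.growth import Trajectory
from gravirod.mechanics import forces

__all__ = [
    "ForceMaps",
    "DCGMap",
    "decompose",
    "compare_max_forces",
    "flank_rates",
    "inner_flank_shrinkage_check",
]

_COMPONENTS = ("total", "stretch", "bend", "grav")


@dataclass
class ForceMaps:
    """Per-step, per-vertex displacement decomposition on a (t, s) grid.

    ``magnitude[c]`` and ``projection[c]`` are (n_steps, N) arrays for the
    components "total", "stretch", "bend", "grav"; projections are signed
    along the local unit normal toward the bending side.  ``arc`` holds the
    arc-length coordinate of each vertex at the start of the step and
    ``times`` the step end times.

    ``fs_max``/``fb_max`` are the maxima over free vertices and frames of the
    stretching/bending force magnitudes evaluated at the stored equilibria
    (where the components balance each other and gravity); they measure the
    internal forces sustaining the shape.  ``fs_max_start``/``fb_max_start``
    are the corresponding maxima at relaxation start, which additionally
    contain the genotype-independent elongation impulse of the growth step.
    """

    times: np.ndarray
    arc: np.ndarray
    magnitude: dict[str, np.ndarray]
    projection: dict[str, np.ndarray]
    fs_max: float
    fb_max: float
    fs_max_start: float
    fb_max_start: float


def _bending_normals(geometry) -> np.ndarray:
    """Unit normal toward the curved side at every vertex.

    The normal is the left-hand perpendicular of the local tangent multiplied
    by the sign of the local curvature (interior vertices; ends copy their
    neighbors).  Zero-curvature vertices use the sign of the nearest nonzero
    neighbor (or +1).
    """
    theta = geometry.vertex_tangent_angles()
    left = np.stack([-np.sin(theta), np.cos(theta)], axis=1)
    kap = geometry.curvatures
    sign = np.sign(kap)
    # fill zeros with nearest nonzero sign, default +1
    nz = np.nonzero(sign)[0]
    if len(nz) == 0:
        sign_full = np.ones(len(kap))
    else:
        idx = np.arange(len(kap))
        nearest = nz[np.argmin(np.abs(idx[:, None] - nz[None, :]), axis=1)]
        sign_full = sign.copy()
        sign_full[sign_full == 0] = sign[nearest[sign_full == 0]]
    s = np.concatenate(([sign_full[0]], sign_full, [sign_full[-1]]))
    return left * s[:, None]


def decompose(trajectory: Trajectory, side_sign: int = 1) -> ForceMaps:
    """Aggregate per-step displacement components onto (time, arc-length).

    ``side_sign = -1`` swaps the bending-side normal, flipping the sign of
    every projection (magnitudes unchanged).

    Raises
    ------
    ValueError
        If the trajectory carries no displacement records.
    """
    steps = [f for f in trajectory.frames[1:]]
    if not steps or any(f.displacement is None for f in steps):
        raise ValueError("trajectory has no displacement records to decompose")
    n = trajectory.frames[0].state.n_vertices
    nt = len(steps)
    times = np.array([f.time for f in steps])
    arc = np.empty((nt, n))
    mag = {c: np.empty((nt, n)) for c in _COMPONENTS}
    proj = {c: np.empty((nt, n)) for c in _COMPONENTS}
    fs_max = fb_max = fs_max_start = fb_max_start = 0.0
    mp = trajectory.mechanical_params
    for k, frame in enumerate(steps):
        prev = trajectory.frames[k]  # frame before this step
        arc[k] = prev.geometry.arc_length
        normal = side_sign * _bending_normals(prev.geometry)
        rec = frame.displacement
        comps = {
            "total": rec.total,
            "stretch": rec.stretch,
            "bend": rec.bend,
            "grav": rec.grav,
        }
        for c, d in comps.items():
            mag[c][k] = np.hypot(d[:, 0], d[:, 1])
            proj[c][k] = np.sum(d * normal, axis=1)
        f = frame.forces_start
        fs_max_start = max(
            fs_max_start,
            float(np.max(np.hypot(f.stretching[2:, 0], f.stretching[2:, 1]))),
        )
        fb_max_start = max(
            fb_max_start,
            float(np.max(np.hypot(f.bending[2:, 0], f.bending[2:, 1]))),
        )
        if mp is not None:
            fe = forces(frame.state, mp)
            fs_max = max(
                fs_max,
                float(np.max(np.hypot(fe.stretching[2:, 0], fe.stretching[2:, 1]))),
            )
            fb_max = max(
                fb_max,
                float(np.max(np.hypot(fe.bending[2:, 0], fe.bending[2:, 1]))),
            )
    if mp is None:  # no mechanical parameters stored: fall back to start forces
        fs_max, fb_max = fs_max_start, fb_max_start
    return ForceMaps(times, arc, mag, proj, fs_max, fb_max, fs_max_start, fb_max_start)


def compare_max_forces(traj_a: Trajectory, traj_b: Trajectory) -> dict:
    """Maximum stretching/bending force of two runs and their B/A ratios."""
    ma = decompose(traj_a)
    mb = decompose(traj_b)
    return {
        "fs_max_a": ma.fs_max,
        "fb_max_a": ma.fb_max,
        "fs_max_b": mb.fs_max,
        "fb_max_b": mb.fb_max,
        "fs_ratio": mb.fs_max / ma.fs_max,
        "fb_ratio": mb.fb_max / ma.fb_max,
    }


@dataclass
class DCGMap:
    """Flank elongation rates and DCG on a (step, segment) grid.

    ``edot_out``/``edot_in`` are relative elongation rates (1/min) of the
    outer/inner flanks at distance R from the centerline; ``dcg`` is
    ``edot_in - edot_out`` (or the variant normalized by the mean rate).
    ``arc`` holds natural-arc midpoints of the segments at the step start.
    """

    times: np.ndarray  # (n_steps,)
    arc: np.ndarray  # (n_steps, N-1)
    edot_out: np.ndarray
    edot_in: np.ndarray
    dcg: np.ndarray
    radius: float


def _bond_kappa0(state) -> np.ndarray:
    """Intrinsic curvature per bond: mean of adjacent interior-vertex values."""
    k0 = state.intrinsic_curvatures
    nb = state.n_vertices - 1
    out = np.empty(nb)
    out[0] = k0[0]
    out[-1] = k0[-1]
    out[1:-1] = 0.5 * (k0[:-1] + k0[1:])
    return out


def flank_rates(
    trajectory: Trajectory,
    radius: float,
    normalized: bool = False,
    upward_sign: int | None = None,
) -> DCGMap:
    """Flank relative elongation rates and DCG from intrinsic geometry.

    Flank natural lengths per segment: ``L_out = a*(1 + R*kappa0*sigma)`` and
    ``L_in = a*(1 - R*kappa0*sigma)``; rates are ``dln L/dt`` between
    consecutive stored steps.  ``sigma`` defaults to the trajectory's growth
    parameter ``upward_sign``.

    Raises
    ------
    ValueError
        If ``R*|kappa0| >= 1`` anywhere (flank geometry invalid).
    """
    if upward_sign is None:
        upward_sign = (
            trajectory.growth_params.upward_sign
            if trajectory.growth_params is not None
            else 1
        )
    frames = trajectory.frames
    if len(frames) < 2:
        raise ValueError("need at least two frames")
    dt = np.diff(trajectory.times)
    n_steps = len(frames) - 1
    nb = frames[0].state.n_vertices - 1
    arc = np.empty((n_steps, nb))
    ln_out = []
    ln_in = []
    for f in frames:
        a = f.state.natural_lengths
        k0 = _bond_kappa0(f.state) * upward_sign
        if np.any(radius * np.abs(k0) >= 1.0):
            raise ValueError(
                "R*|kappa0| >= 1: flank offset exceeds the bending radius"
            )
        ln_out.append(np.log(a * (1.0 + radius * k0)))
        ln_in.append(np.log(a * (1.0 - radius * k0)))
    ln_out = np.array(ln_out)
    ln_in = np.array(ln_in)
    for k in range(n_steps):
        a = frames[k].state.natural_lengths
        arc[k] = np.concatenate(([0.0], np.cumsum(a)))[:-1] + 0.5 * a
    edot_out = np.diff(ln_out, axis=0) / dt[:, None]
    edot_in = np.diff(ln_in, axis=0) / dt[:, None]
    dcg = edot_in - edot_out
    if normalized:
        mean = 0.5 * (edot_in + edot_out)
        with np.errstate(divide="ignore", invalid="ignore"):
            dcg = np.where(mean != 0, dcg / np.abs(mean), 0.0)
    return DCGMap(
        times=trajectory.times[1:],
        arc=arc,
        edot_out=edot_out,
        edot_in=edot_in,
        dcg=dcg,
        radius=radius,
    )


@dataclass
class ShrinkageReport:
    """Cells where the inner flank shrinks while the outer one grows."""

    flagged: np.ndarray  # boolean (n_steps, N-1)
    times: np.ndarray
    arc: np.ndarray

    @property
    def n_flagged(self) -> int:
        return int(self.flagged.sum())

    @property
    def any_flagged(self) -> bool:
        return bool(self.flagged.any())


def inner_flank_shrinkage_check(
    trajectory: Trajectory, radius: float, upward_sign: int | None = None
) -> ShrinkageReport:
    """Flag (t, s) cells with Edot_in < 0 while Edot_out > 0."""
    m = flank_rates(trajectory, radius, upward_sign=upward_sign)
    flagged = (m.edot_in < 0) & (m.edot_out > 0)
    return ShrinkageReport(flagged=flagged, times=m.times, arc=m.arc)
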