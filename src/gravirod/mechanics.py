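"""Discrete elastic rod: geometry, energies, forces and quasi-static equilibration.

The shoot centerline is a chain of vertices ``x_0 .. x_{N-1}`` connected by
extensible bonds with natural lengths ``a_i`` and, at interior vertices,
angular springs penalising the deviation of the turning angle from the
intrinsic one ``phi0_i = kappa0_i * abar_i``.  The basal end is clamped by
freezing ``x_0`` and ``x_1`` (position plus tangent); the apical end is free
of force and moment conditions.

Potentials::

    U_s = (ks/2) * sum_i (l_i - a_i)^2
    U_b = sum_i (kb_i/2) * (phi_i - phi0_i)^2,   kb_i = B / abar_i
    U_g = g * sum_i m_i * y_i,                   m_i = rho * abar_i

with half-segment masses at the two end vertices.  Forces are the exact
analytic negative gradients of these potentials with respect to vertex
positions, so the per-component displacement bookkeeping done during
relaxation is exactly additive.

Equilibration is overdamped relaxation along the total force; the default
FIRE scheme accelerates convergence in the stiff (practically inextensible)
regime while preserving the decomposition contract exactly (see
:func:`equilibrate`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DegenerateGeometryError",
    "ConvergenceError",
    "MechanicalParams",
    "RodState",
    "RodGeometry",
    "ForceSet",
    "DisplacementRecord",
    "rod_geometry",
    "energies",
    "forces",
    "equilibrate",
    "moment_balance_residuals",
    "straight_rod",
]


class DegenerateGeometryError(ValueError):
    """Raised when consecutive vertices coincide (undefined tangent)."""


class ConvergenceError(RuntimeError):
    """Raised when relaxation fails to reach the force tolerance."""

    def __init__(self, msg: str, residual: float | None = None):
        super().__init__(msg)
        self.residual = residual


# ----------------------------------------------------------------------
# parameter / state containers
# ----------------------------------------------------------------------


@dataclass
class MechanicalParams:
    """Elasticity, weight and relaxation parameters.

    Internal units are mm and min with the force unit fixed by the stretch
    stiffness; only the product ``rho * g`` (weight per unit length) enters
    the statics, through the elasto-gravity length ``Lg = (B/(rho g))^(1/3)``.
    ``youngs_modulus`` (MPa) and ``radius`` (mm) are bookkeeping fields used
    to convert internal force units into newtons for reporting.
    """

    stretch_stiffness: float = 4.0e5  # ks, force/mm
    bending_modulus: float = 6.4e4  # B, force*mm^2 (continuum E*pi*R^4/4)
    youngs_modulus: float = 10.0  # MPa
    radius: float = 0.75  # mm
    linear_density: float = 1.0  # rho, mass/mm
    gravity: float = 1.0  # g, oriented along -y
    mobility: float = 1.0  # mu, mm/(force*pseudo-time)
    relax_step: float | None = None  # dtau; None -> stability-bound default
    force_tol: float = 1e-3  # eps_F
    max_relax_iters: int = 500_000

    def __post_init__(self) -> None:
        for name in (
            "stretch_stiffness",
            "bending_modulus",
            "linear_density",
            "gravity",
            "mobility",
            "force_tol",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.relax_step is not None and self.relax_step <= 0:
            raise ValueError("relax_step must be > 0")
        if self.max_relax_iters < 1:
            raise ValueError("max_relax_iters must be >= 1")

    @property
    def weight_per_length(self) -> float:
        """rho*g, the only combination through which gravity acts."""
        return self.linear_density * self.gravity

    @property
    def elasto_gravity_length(self) -> float:
        """Lg = (B/(rho g))^(1/3) in mm."""
        return float((self.bending_modulus / self.weight_per_length) ** (1.0 / 3.0))

    def force_unit_newtons(self) -> float:
        """Newtons per internal force unit, via E (MPa) and R (mm).

        The physical bending modulus is ``E*pi*R^4/4`` in N*mm^2; the ratio
        to the internal ``bending_modulus`` converts force units.
        """
        b_phys = self.youngs_modulus * np.pi * self.radius**4 / 4.0  # N*mm^2
        return float(b_phys / self.bending_modulus)


@dataclass
class RodState:
    """Configuration of the discrete rod.

    positions : (N, 2) vertex coordinates in mm
    natural_lengths : (N-1,) stress-free bond lengths in mm
    intrinsic_curvatures : (N-2,) target curvature kappa0 at interior
        vertices, 1/mm (index j maps to vertex j+1)
    base_angle : clamp tangent angle (rad, vs +x); x_0 and x_1 are frozen
    time : simulation time in minutes
    """

    positions: np.ndarray
    natural_lengths: np.ndarray
    intrinsic_curvatures: np.ndarray
    base_angle: float = 0.0
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.natural_lengths = np.asarray(self.natural_lengths, dtype=float)
        self.intrinsic_curvatures = np.asarray(self.intrinsic_curvatures, dtype=float)
        n = self.positions.shape[0]
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must have shape (N, 2)")
        if n < 3:
            raise ValueError("need at least 3 vertices")
        if self.natural_lengths.shape != (n - 1,):
            raise ValueError("natural_lengths must have shape (N-1,)")
        if self.intrinsic_curvatures.shape != (n - 2,):
            raise ValueError("intrinsic_curvatures must have shape (N-2,)")
        if np.any(self.natural_lengths <= 0):
            raise ValueError("natural lengths must be > 0")

    @property
    def n_vertices(self) -> int:
        return self.positions.shape[0]

    @property
    def voronoi_natural_lengths(self) -> np.ndarray:
        """abar_i = (a_{i-1} + a_i)/2 at interior vertices, shape (N-2,)."""
        a = self.natural_lengths
        return 0.5 * (a[:-1] + a[1:])

    @property
    def total_natural_length(self) -> float:
        return float(self.natural_lengths.sum())

    def vertex_masses(self, rho: float) -> np.ndarray:
        """Lumped masses m_i = rho*abar_i with half segments at the ends."""
        a = self.natural_lengths
        m = np.empty(self.n_vertices)
        m[0] = 0.5 * a[0]
        m[-1] = 0.5 * a[-1]
        m[1:-1] = 0.5 * (a[:-1] + a[1:])
        return rho * m

    def copy(self) -> "RodState":
        return RodState(
            self.positions.copy(),
            self.natural_lengths.copy(),
            self.intrinsic_curvatures.copy(),
            self.base_angle,
            self.time,
        )

    # -- CSV serialization (index, x_mm, y_mm, natural_length_mm,
    #    intrinsic_curvature_per_mm); bond i on row i, curvature of interior
    #    vertex i on row i; unused cells empty.
    def to_csv(self, path_or_buf) -> None:
        n = self.n_vertices
        lines = ["index,x_mm,y_mm,natural_length_mm,intrinsic_curvature_per_mm"]
        for i in range(n):
            a = f"{self.natural_lengths[i]:.12g}" if i < n - 1 else ""
            k = f"{self.intrinsic_curvatures[i - 1]:.12g}" if 1 <= i <= n - 2 else ""
            lines.append(
                f"{i},{self.positions[i, 0]:.12g},{self.positions[i, 1]:.12g},{a},{k}"
            )
        text = "\n".join(lines) + "\n"
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(text)

    @classmethod
    def from_csv(cls, path_or_buf, base_angle: float | None = None,
                 time: float = 0.0) -> "RodState":
        if hasattr(path_or_buf, "read"):
            text = path_or_buf.read()
        else:
            with open(path_or_buf) as fh:
                text = fh.read()
        lines = [ln for ln in text.strip().splitlines() if ln.strip()]
        header = lines[0].strip().split(",")
        expected = ["index", "x_mm", "y_mm", "natural_length_mm",
                    "intrinsic_curvature_per_mm"]
        if header != expected:
            raise ValueError(f"bad RodState CSV header {header!r}; expected {expected}")
        rows = [ln.split(",") for ln in lines[1:]]
        xy = np.array([[float(r[1]), float(r[2])] for r in rows])
        a = np.array([float(r[3]) for r in rows[:-1]])
        k0 = np.array([float(r[4]) for r in rows[1:-1]])
        if base_angle is None:
            d = xy[1] - xy[0]
            base_angle = float(np.arctan2(d[1], d[0]))
        return cls(xy, a, k0, base_angle=base_angle, time=time)


@dataclass
class RodGeometry:
    """Derived geometric quantities of a rod configuration.

    Curvature at interior vertices is the turning angle per Voronoi natural
    length, ``kappa_i = phi_i / abar_i``; ``arc_length`` is the cumulative
    current length with s = 0 at the base.
    """

    bond_lengths: np.ndarray  # (N-1,)
    bond_angles: np.ndarray  # (N-1,) tangent angle vs +x, rad
    turning_angles: np.ndarray  # (N-2,)
    voronoi_lengths: np.ndarray  # (N-2,) from natural lengths
    curvatures: np.ndarray  # (N-2,) 1/mm
    arc_length: np.ndarray  # (N,) mm, s_0 = 0

    @property
    def total_length(self) -> float:
        return float(self.arc_length[-1])

    def vertex_tangent_angles(self) -> np.ndarray:
        """Per-vertex tangent angle: average of adjacent bond angles
        (end vertices take the single adjacent bond)."""
        th = self.bond_angles
        out = np.empty(len(th) + 1)
        out[0] = th[0]
        out[-1] = th[-1]
        # circular mean of the two adjacent bond directions
        out[1:-1] = th[:-1] + 0.5 * _wrap_angle(th[1:] - th[:-1])
        return out


@dataclass
class ForceSet:
    """Per-vertex force components and internal moments.

    Each component is the exact negative gradient of its potential.
    ``moments`` holds M_i = kb_i*(phi_i - phi0_i) at interior vertices.
    """

    stretching: np.ndarray  # (N, 2)
    bending: np.ndarray  # (N, 2)
    gravity: np.ndarray  # (N, 2)
    moments: np.ndarray  # (N-2,)

    @property
    def total(self) -> np.ndarray:
        return self.stretching + self.bending + self.gravity


@dataclass
class DisplacementRecord:
    """Per-vertex displacement of one equilibration, split by force component.

    ``total = stretch + bend + grav`` exactly (same scalar step multiplies
    each component at every relaxation iteration); clamped vertices are
    all-zero.
    """

    stretch: np.ndarray  # (N, 2)
    bend: np.ndarray  # (N, 2)
    grav: np.ndarray  # (N, 2)
    n_iters: int = 0
    residual: float = 0.0

    @property
    def total(self) -> np.ndarray:
        return self.stretch + self.bend + self.grav

    @classmethod
    def zeros(cls, n: int) -> "DisplacementRecord":
        z = np.zeros((n, 2))
        return cls(z.copy(), z.copy(), z.copy())


# ----------------------------------------------------------------------
# geometry
# ----------------------------------------------------------------------


def _wrap_angle(phi: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    return np.arctan2(np.sin(phi), np.cos(phi))


def rod_geometry(state: RodState) -> RodGeometry:
    """Compute bond lengths/angles, turning angles, curvatures and arc length.

    Raises
    ------
    DegenerateGeometryError
        If two consecutive vertices coincide.
    """
    x = state.positions
    e = np.diff(x, axis=0)
    ell = np.hypot(e[:, 0], e[:, 1])
    if np.any(ell < 1e-12):
        raise DegenerateGeometryError("coincident consecutive vertices")
    theta = np.arctan2(e[:, 1], e[:, 0])
    phi = _wrap_angle(np.diff(theta))
    abar = state.voronoi_natural_lengths
    kappa = phi / abar
    s = np.concatenate(([0.0], np.cumsum(ell)))
    return RodGeometry(ell, theta, phi, abar, kappa, s)


# ----------------------------------------------------------------------
# energies and forces
# ----------------------------------------------------------------------


def energies(state: RodState, params: MechanicalParams) -> tuple[float, float, float]:
    """Return (U_stretch, U_bend, U_gravity)."""
    geom = rod_geometry(state)
    ks = params.stretch_stiffness
    u_s = 0.5 * ks * np.sum((geom.bond_lengths - state.natural_lengths) ** 2)
    abar = geom.voronoi_lengths
    kb = params.bending_modulus / abar
    phi0 = state.intrinsic_curvatures * abar
    u_b = 0.5 * np.sum(kb * (geom.turning_angles - phi0) ** 2)
    m = state.vertex_masses(params.linear_density)
    u_g = params.gravity * np.sum(m * state.positions[:, 1])
    return float(u_s), float(u_b), float(u_g)


def _force_arrays(
    x: np.ndarray,
    a: np.ndarray,
    kappa0: np.ndarray,
    ks: float,
    bending_modulus: float,
    weights: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Core kernel: (F_stretch, F_bend, F_gravity, moments) for positions x.

    ``weights`` is the per-vertex m_i*g (precomputed; depends only on the
    natural lengths).  Raises DegenerateGeometryError on coincident vertices.
    """
    e = np.diff(x, axis=0)
    ell = np.hypot(e[:, 0], e[:, 1])
    if np.any(ell < 1e-12):
        raise DegenerateGeometryError("coincident consecutive vertices")
    n = x.shape[0]

    # stretching: F_j += ks*(l_j - a_j)*t_j ; F_{j+1} -= same
    t = e / ell[:, None]
    fs = ks * (ell - a)
    f_stretch = np.zeros((n, 2))
    f_stretch[:-1] += fs[:, None] * t
    f_stretch[1:] -= fs[:, None] * t

    # bending: gradient of the turning angles
    theta = np.arctan2(e[:, 1], e[:, 0])
    phi = _wrap_angle(np.diff(theta))
    abar = 0.5 * (a[:-1] + a[1:])
    kb = bending_modulus / abar
    moments = kb * (phi - kappa0 * abar)
    # perp(e)/l^2 is the gradient of the bond angle wrt the bond head
    perp = np.empty_like(e)
    perp[:, 0] = -e[:, 1]
    perp[:, 1] = e[:, 0]
    p = perp / (ell**2)[:, None]
    # dphi_j/dx_{j+1} = p_j ; dphi_j/dx_j = -(p_j + p_{j-1}) ;
    # dphi_j/dx_{j-1} = p_{j-1} ; force is -M_j * dphi_j/dx
    m2 = moments[:, None]
    f_bend = np.zeros((n, 2))
    f_bend[2:] += -m2 * p[1:]
    f_bend[1:-1] += m2 * (p[1:] + p[:-1])
    f_bend[:-2] += -m2 * p[:-1]

    f_grav = np.zeros((n, 2))
    f_grav[:, 1] = -weights
    return f_stretch, f_bend, f_grav, moments


def forces(state: RodState, params: MechanicalParams) -> ForceSet:
    """Analytic per-vertex forces (negative potential gradients) and moments.

    Clamped vertices report their forces but are never moved by
    :func:`equilibrate`.
    """
    weights = state.vertex_masses(params.linear_density) * params.gravity
    fs, fb, fg, m = _force_arrays(
        state.positions,
        state.natural_lengths,
        state.intrinsic_curvatures,
        params.stretch_stiffness,
        params.bending_modulus,
        weights,
    )
    return ForceSet(fs, fb, fg, m)


def moment_balance_residuals(state: RodState, params: MechanicalParams) -> np.ndarray:
    """Discrete moment-balance check at equilibrium.

    For each interior vertex i the internal moment ``M_i = kb_i*(phi_i-phi0_i)``
    must cancel the torque of the external (gravity) loads on the distal part
    of the rod about vertex i (a sagging rod has negative phi and a positive
    distal-weight torque).  Returns ``M_i + sum_{j>i} w_j*(x_j-x_i)`` with
    ``w_j = m_j*g``; the residuals vanish at equilibrium and are small near
    the free end by construction (little distal weight).
    """
    geom = rod_geometry(state)
    phi0 = state.intrinsic_curvatures * geom.voronoi_lengths
    kb = params.bending_modulus / geom.voronoi_lengths
    moments = kb * (geom.turning_angles - phi0)
    w = state.vertex_masses(params.linear_density) * params.gravity
    x = state.positions
    res = np.empty_like(moments)
    for i in range(1, state.n_vertices - 1):
        lever = x[i + 1 :, 0] - x[i, 0]
        res[i - 1] = moments[i - 1] + np.sum(w[i + 1 :] * lever)
    return res


# ----------------------------------------------------------------------
# equilibration
# ----------------------------------------------------------------------


def _stiffness_scale(state: RodState, params: MechanicalParams) -> float:
    """Estimate of the largest Hessian eigenvalue (stretch + bend)."""
    abar = state.voronoi_natural_lengths
    kb = params.bending_modulus / abar
    k_stretch = 4.0 * params.stretch_stiffness
    k_bend = 16.0 * float(np.max(kb)) / float(np.min(state.natural_lengths)) ** 2
    return k_stretch + k_bend


def equilibrate(
    state: RodState, params: MechanicalParams, method: str = "fire"
) -> tuple[RodState, DisplacementRecord]:
    """Relax the free vertices (i >= 2) to mechanical equilibrium.

    Overdamped relaxation along the total force until
    ``max_i |F^s_i + F^b_i + F^g_i| < force_tol``.  Two schemes:

    ``"gd"``
        The literal fixed-step descent ``x += mu*(F_s+F_b+F_g)*dtau`` with
        ``dtau = relax_step`` (default: a stability-bound step).
    ``"fire"`` (default)
        Inertial FIRE relaxation.  Its velocity is a scalar-weighted sum of
        past total forces, and the identical scalars are applied to
        per-component velocities, so the accumulation contract
        ``dx^c = sum_k (scalar_k * F^c_k)`` and the exact additivity
        ``dx_total = dx^s + dx^b + dx^g`` are preserved.

    Returns the equilibrated state and the :class:`DisplacementRecord`.

    Raises
    ------
    ConvergenceError
        If the tolerance is not met within ``max_relax_iters``.
    DegenerateGeometryError
        If relaxation collapses consecutive vertices irrecoverably.
    """
    from gravirod import _kernels

    n = state.n_vertices
    x = state.positions.copy()
    a = np.ascontiguousarray(state.natural_lengths)
    k0 = np.ascontiguousarray(state.intrinsic_curvatures)
    weights = state.vertex_masses(params.linear_density) * params.gravity
    acc_s = np.zeros((n, 2))
    acc_b = np.zeros((n, 2))
    acc_g = np.zeros((n, 2))

    if method == "fire":
        k_est = _stiffness_scale(state, params)
        dt_max = 1.0 / np.sqrt(params.mobility * k_est)
        status, it, res = _kernels.relax_fire(
            x,
            a,
            k0,
            params.stretch_stiffness,
            params.bending_modulus,
            weights,
            params.mobility,
            params.force_tol,
            dt_max,
            params.max_relax_iters,
            acc_s,
            acc_b,
            acc_g,
        )
    elif method == "gd":
        dtau = params.relax_step
        if dtau is None:
            dtau = 0.5 / (params.mobility * _stiffness_scale(state, params))
        status, it, res = _kernels.relax_gd(
            x,
            a,
            k0,
            params.stretch_stiffness,
            params.bending_modulus,
            weights,
            params.mobility,
            dtau,
            params.force_tol,
            params.max_relax_iters,
            acc_s,
            acc_b,
            acc_g,
        )
    else:
        raise ValueError(f"unknown relaxation method {method!r}")

    if status == 2:
        raise DegenerateGeometryError("relaxation produced coincident vertices")
    if status == 1:
        raise ConvergenceError(
            f"no equilibrium after {it} iterations "
            f"(residual {res:.3e}, tol {params.force_tol:.3e})",
            residual=float(res),
        )
    out = RodState(x, a.copy(), k0.copy(), state.base_angle, state.time)
    rec = DisplacementRecord(acc_s, acc_b, acc_g, n_iters=int(it), residual=float(res))
    return out, rec


# ----------------------------------------------------------------------
# constructors
# ----------------------------------------------------------------------


def straight_rod(
    length: float,
    n_vertices: int,
    base_angle: float = 0.0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> RodState:
    """Straight rod of given natural length at the clamp angle, at rest."""
    if n_vertices < 3:
        raise ValueError("need at least 3 vertices")
    a = np.full(n_vertices - 1, length / (n_vertices - 1))
    s = np.concatenate(([0.0], np.cumsum(a)))
    d = np.array([np.cos(base_angle), np.sin(base_angle)])
    x = np.asarray(origin, dtype=float)[None, :] + s[:, None] * d[None, :]
    k0 = np.zeros(n_vertices - 2)
    return RodState(x, a, k0, base_angle=base_angle)
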