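"""Rod mechanics: geometry, energies, analytic forces, equilibration."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gravirod import (
    ConvergenceError,
    DegenerateGeometryError,
    MechanicalParams,
    RodState,
    energies,
    equilibrate,
    forces,
    moment_balance_residuals,
    rod_geometry,
    straight_rod,
)


def _random_state(rng, n=9, jitter=0.3):
    st_ = straight_rod(float(n - 1), n)
    st_.positions = st_.positions + rng.normal(0, jitter, st_.positions.shape)
    st_.positions[0] = [0.0, 0.0]
    st_.positions[1] = [1.0, 0.0]
    st_.intrinsic_curvatures = rng.normal(0, 0.1, n - 2)
    return st_


# ----------------------------------------------------------------- geometry


class TestGeometry:
    def test_straight_rod_zero_curvature(self):
        state = straight_rod(2.0, 3)
        geom = rod_geometry(state)
        assert geom.turning_angles[0] == pytest.approx(0.0)
        assert geom.curvatures[0] == pytest.approx(0.0)

    def test_right_angle(self):
        state = RodState(
            positions=[[0, 0], [1, 0], [1, 1]],
            natural_lengths=[1.0, 1.0],
            intrinsic_curvatures=[0.0],
        )
        geom = rod_geometry(state)
        assert geom.turning_angles[0] == pytest.approx(np.pi / 2)
        assert geom.curvatures[0] == pytest.approx(np.pi / 2)

    def test_circle_curvature(self):
        # 41 vertices equally spaced on a circle of radius 10 mm
        r = 10.0
        ang = np.linspace(0, 2 * np.pi * 40 / 41, 41)
        xy = np.stack([r * np.cos(ang), r * np.sin(ang)], axis=1)
        chord = 2 * r * np.sin((ang[1] - ang[0]) / 2)
        state = RodState(xy, np.full(40, chord), np.zeros(39))
        geom = rod_geometry(state)
        assert np.all(np.abs(geom.curvatures - 0.100) < 1e-3)

    def test_arc_length_starts_at_base(self):
        state = straight_rod(10.0, 6)
        geom = rod_geometry(state)
        assert geom.arc_length[0] == 0.0
        assert geom.total_length == pytest.approx(10.0)

    def test_coincident_vertices_rejected(self):
        state = straight_rod(2.0, 3)
        state.positions[1] = state.positions[0]
        with pytest.raises(DegenerateGeometryError):
            rod_geometry(state)

    def test_voronoi_lengths(self):
        state = straight_rod(3.0, 4)
        state.natural_lengths = np.array([1.0, 2.0, 0.5])
        geom = rod_geometry(state)
        np.testing.assert_allclose(geom.voronoi_lengths, [1.5, 1.25])


# ----------------------------------------------------------------- energies


class TestEnergies:
    def test_rest_configuration_zero(self):
        state = straight_rod(5.0, 6)
        p = MechanicalParams(gravity=1e-12)
        u_s, u_b, u_g = energies(state, p)
        assert u_s == pytest.approx(0.0, abs=1e-12)
        assert u_b == pytest.approx(0.0, abs=1e-12)

    def test_single_bond_stretch(self):
        state = straight_rod(2.0, 3)
        delta = 0.1
        state.positions[2, 0] += delta
        p = MechanicalParams(stretch_stiffness=100.0)
        u_s, _, _ = energies(state, p)
        assert u_s == pytest.approx(0.5 * 100.0 * delta**2)

    def test_rigid_translation_only_changes_gravity(self, rng):
        state = _random_state(rng)
        p = MechanicalParams()
        u0 = energies(state, p)
        dy = 0.37
        state.positions[:, 1] += dy
        u1 = energies(state, p)
        total_mass = state.vertex_masses(p.linear_density).sum()
        assert u1[0] == pytest.approx(u0[0], rel=1e-9)
        assert u1[1] == pytest.approx(u0[1], rel=1e-9, abs=1e-12)
        assert u1[2] - u0[2] == pytest.approx(p.gravity * dy * total_mass, rel=1e-9)

    def test_mass_lumping_half_segments(self):
        state = straight_rod(4.0, 5)
        m = state.vertex_masses(2.0)
        np.testing.assert_allclose(m, [1.0, 2.0, 2.0, 2.0, 1.0])
        assert m.sum() == pytest.approx(2.0 * 4.0)


# ------------------------------------------------------------------- forces


def _numeric_gradients(state, params, h=1e-6):
    """Central finite differences of each potential wrt vertex positions."""
    n = state.n_vertices
    num = {k: np.zeros((n, 2)) for k in range(3)}
    for i in range(n):
        for d in range(2):
            state.positions[i, d] += h
            up = energies(state, params)
            state.positions[i, d] -= 2 * h
            dn = energies(state, params)
            state.positions[i, d] += h
            for k in range(3):
                num[k][i, d] = -(up[k] - dn[k]) / (2 * h)
    return num[0], num[1], num[2]


class TestForces:
    def test_rest_configuration_zero_force(self):
        state = straight_rod(5.0, 6)
        p = MechanicalParams(gravity=1e-12)
        f = forces(state, p)
        assert np.max(np.abs(f.stretching)) < 1e-9
        assert np.max(np.abs(f.bending)) < 1e-9

    def test_gravity_on_interior_vertex(self):
        state = straight_rod(4.0, 5)
        p = MechanicalParams(linear_density=2.0, gravity=3.0)
        f = forces(state, p)
        m = state.vertex_masses(2.0)
        np.testing.assert_allclose(f.gravity[:, 1], -3.0 * m)
        np.testing.assert_allclose(f.gravity[:, 0], 0.0)
        assert f.gravity[:, 1].sum() == pytest.approx(-3.0 * m.sum())

    @pytest.mark.parametrize("seed", range(5))
    def test_gradient_oracle(self, seed):
        rng = np.random.default_rng(seed)
        state = _random_state(rng)
        p = MechanicalParams(
            stretch_stiffness=100.0,
            bending_modulus=50.0,
            linear_density=2.0,
        )
        f = forces(state, p)
        num_s, num_b, num_g = _numeric_gradients(state, p)
        for analytic, numeric in (
            (f.stretching, num_s),
            (f.bending, num_b),
            (f.gravity, num_g),
        ):
            scale = max(np.max(np.abs(analytic)), 1e-9)
            assert np.max(np.abs(analytic - numeric)) / scale < 1e-6

    def test_moments_definition(self, rng):
        state = _random_state(rng)
        p = MechanicalParams(bending_modulus=50.0)
        f = forces(state, p)
        geom = rod_geometry(state)
        kb = p.bending_modulus / geom.voronoi_lengths
        phi0 = state.intrinsic_curvatures * geom.voronoi_lengths
        np.testing.assert_allclose(f.moments, kb * (geom.turning_angles - phi0))


# -------------------------------------------------------------- equilibrate


class TestEquilibrate:
    def test_straight_recovery_without_gravity(self, rng):
        p = MechanicalParams(
            stretch_stiffness=200.0,
            bending_modulus=20.0,
            linear_density=1.0,
            gravity=1e-9,
            force_tol=1e-9,
        )
        state = _random_state(rng, n=7, jitter=0.2)
        state.intrinsic_curvatures[:] = 0.0
        eq, _ = equilibrate(state, p)
        # unique minimum: straight line along the clamp tangent
        geom = rod_geometry(eq)
        assert np.max(np.abs(geom.turning_angles)) < 1e-5
        assert np.max(np.abs(geom.bond_lengths - eq.natural_lengths)) < 1e-6

    def test_cantilever_small_deflection(self):
        # heavy clamped rod, sag < 5% of L: Euler-Bernoulli w(L) = rho g L^4/(8B)
        length, n = 40.0, 161
        b = 6.4e5
        rhog = 0.2
        p = MechanicalParams(
            stretch_stiffness=4e5 * 4,
            bending_modulus=b,
            linear_density=rhog,
            gravity=1.0,
            force_tol=1e-6,
            max_relax_iters=1_000_000,
        )
        eq, _ = equilibrate(straight_rod(length, n), p)
        sag = -eq.positions[-1, 1]
        predicted = rhog * length**4 / (8 * b)
        assert predicted / length < 0.05
        assert sag == pytest.approx(predicted, rel=0.02)

    def test_clamp_fixed_and_residual_bound(self, wt_traj, default_mp):
        frame = wt_traj.frames[-1]
        f = forces(frame.state, default_mp)
        resid = np.hypot(f.total[2:, 0], f.total[2:, 1])
        assert np.max(resid) < default_mp.force_tol
        np.testing.assert_allclose(frame.state.positions[0], [0.0, 0.0])
        np.testing.assert_allclose(frame.state.positions[1], [1.0, 0.0])

    def test_displacement_additivity(self, soft_mp, rng):
        state = _random_state(rng, n=11)
        eq, rec = equilibrate(state, soft_mp)
        total_move = eq.positions - state.positions
        length = rod_geometry(eq).total_length
        assert np.max(np.abs(rec.total - total_move)) < 1e-8 * length
        np.testing.assert_allclose(rec.total, rec.stretch + rec.bend + rec.grav)
        assert np.all(rec.stretch[:2] == 0)

    def test_inextensibility_regime(self, wt_traj):
        for frame in wt_traj.frames[:: len(wt_traj.frames) // 7]:
            geom = frame.geometry
            strain = np.abs(geom.bond_lengths / frame.state.natural_lengths - 1)
            assert np.max(strain) < 1e-3

    def test_zero_gravity_prescribed_curvature_shape(self):
        # kappa0 prescribed, g ~ 0: equilibrium equals theta'(s) = kappa0(s)
        n = 41
        state = straight_rod(40.0, n)
        kappa0 = 0.03 * np.sin(np.linspace(0, np.pi, n - 2))
        state.intrinsic_curvatures = kappa0
        p = MechanicalParams(gravity=1e-10, force_tol=1e-8)
        eq, _ = equilibrate(state, p)
        # integrate the target shape directly
        a = state.natural_lengths
        abar = state.voronoi_natural_lengths
        theta = np.concatenate(([0.0], np.cumsum(kappa0 * abar)))
        xy = np.zeros((n, 2))
        xy[1:] = np.cumsum(
            np.stack([a * np.cos(theta), a * np.sin(theta)], axis=1), axis=0
        )
        err = np.max(np.hypot(*(eq.positions - xy).T)) / 40.0
        assert err < 1e-3

    def test_moment_balance_at_equilibrium(self):
        length, n = 40.0, 81
        b = 6.4e5
        p = MechanicalParams(
            stretch_stiffness=1.6e6,
            bending_modulus=b,
            linear_density=0.2,
            gravity=1.0,
            force_tol=1e-7,
            max_relax_iters=1_000_000,
        )
        eq, _ = equilibrate(straight_rod(length, n), p)
        res = moment_balance_residuals(eq, p)
        scale = 0.2 * length**2 / 2  # basal gravity moment
        # interior residuals vanish; the apical-most one is exactly free
        assert np.max(np.abs(res)) / scale < 1e-3
        assert abs(res[-1]) / scale < 1e-3

    def test_nonconvergence_raises(self):
        p = MechanicalParams(max_relax_iters=5, force_tol=1e-12)
        state = straight_rod(40.0, 21)
        with pytest.raises(ConvergenceError) as exc_info:
            equilibrate(state, p)
        assert exc_info.value.residual is not None

    def test_gd_matches_fire_on_soft_problem(self):
        p = MechanicalParams(
            stretch_stiffness=200.0,
            bending_modulus=20.0,
            linear_density=0.05,
            gravity=1.0,
            force_tol=1e-5,
            max_relax_iters=2_000_000,
        )
        state = straight_rod(10.0, 9)
        eq_fire, rec_fire = equilibrate(state, p, method="fire")
        eq_gd, rec_gd = equilibrate(state, p, method="gd")
        assert np.max(np.abs(eq_fire.positions - eq_gd.positions)) < 1e-3
        # both schemes honor the additivity contract
        for rec, eq in ((rec_fire, eq_fire), (rec_gd, eq_gd)):
            np.testing.assert_allclose(
                rec.total, eq.positions - state.positions, atol=1e-10
            )


# -------------------------------------------------------- params validation


class TestParams:
    @pytest.mark.parametrize(
        "field",
        [
            "stretch_stiffness",
            "bending_modulus",
            "linear_density",
            "gravity",
            "mobility",
            "force_tol",
        ],
    )
    def test_positive_parameters_enforced(self, field):
        with pytest.raises(ValueError):
            MechanicalParams(**{field: -1.0})

    def test_state_validation(self):
        with pytest.raises(ValueError):
            RodState(np.zeros((2, 2)), np.ones(1), np.zeros(0))
        with pytest.raises(ValueError):
            RodState(np.zeros((4, 2)), -np.ones(3), np.zeros(2))

    def test_elasto_gravity_length(self):
        p = MechanicalParams(bending_modulus=8000.0, linear_density=1.0, gravity=1.0)
        assert p.elasto_gravity_length == pytest.approx(20.0)


# ------------------------------------------------------------ serialization


class TestSerialization:
    def test_csv_round_trip(self, rng):
        state = _random_state(rng)
        buf = io.StringIO()
        state.to_csv(buf)
        buf.seek(0)
        back = RodState.from_csv(buf)
        np.testing.assert_allclose(back.positions, state.positions)
        np.testing.assert_allclose(back.natural_lengths, state.natural_lengths)
        np.testing.assert_allclose(
            back.intrinsic_curvatures, state.intrinsic_curvatures
        )

    def test_csv_header_checked(self):
        buf = io.StringIO("a,b,c\n1,2,3\n")
        with pytest.raises(ValueError, match="header"):
            RodState.from_csv(buf)


# --------------------------------------------------------------- properties


@settings(max_examples=25, deadline=None)
@given(
    seed=st.integers(0, 10_000),
    ks=st.floats(10.0, 1e4),
    bmod=st.floats(1.0, 1e3),
)
def test_gradient_consistency_property(seed, ks, bmod):
    """Analytic forces match finite-difference gradients on random states."""
    rng = np.random.default_rng(seed)
    state = _random_state(rng, n=7)
    p = MechanicalParams(
        stretch_stiffness=ks, bending_modulus=bmod, linear_density=1.5
    )
    f = forces(state, p)
    num_s, num_b, num_g = _numeric_gradients(state, p)
    for analytic, numeric in (
        (f.stretching, num_s),
        (f.bending, num_b),
        (f.gravity, num_g),
    ):
        scale = max(np.max(np.abs(analytic)), 1e-6)
        assert np.max(np.abs(analytic - numeric)) / scale < 1e-5
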