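"""Ground-truth-known synthetic centerline cohorts.

Emulates the study design: individuals start near-horizontal at ~40 mm,
bend upward over 140 min, and are digitized as ~20 points per frame with
isotropic Gaussian positional noise.  Two cohorts (default 16 wild-type-like
and 15 mutant-like individuals) differ only in gravitropic sensitivity.
All randomness flows from a single seed through spawned generators, so a
fixed seed reproduces the cohorts exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from gravirod.centerline import CenterlineSample, CenterlineSeries, make_interp_spline
from gravirod.growth import GrowthParams, Trajectory, dimensionless_groups, simulate
from gravirod.mechanics import MechanicalParams, RodState, equilibrate, straight_rod

__all__ = [
    "CohortSpec",
    "make_initial_rod",
    "sample_frames",
    "sample_series",
    "simulate_individual",
    "make_cohorts",
]


@dataclass
class CohortSpec:
    """Distributional description of one synthetic cohort.

    Lengths in mm, times in min, angles in rad.  Standard deviations of 0
    make the corresponding parameter deterministic.  ``frame_times`` of None
    means one frame per minute over [0, t_end].
    """

    n_individuals: int = 16
    genotype: str = "wt"
    length_mean: float = 40.0
    length_sd: float = 2.0
    base_angle_mean: float = 0.0
    base_angle_sd: float = 0.05
    beta_mean: float = 2.0e-3
    beta_sd: float = 2.0e-4
    gamma_mean: float = 5.0e-2
    gamma_sd: float = 5.0e-3
    growth_speed_mean: float = 4.0 / 140.0
    growth_speed_sd: float = 3.0e-3
    rho_mean: float = 1.0
    rho_sd: float = 0.0
    n_points: int = 20
    noise_sigma: float = 0.1
    frame_times: list[float] | None = None
    t_end: float = 140.0
    n_vertices: int = 41

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    def resolved_frame_times(self) -> np.ndarray:
        if self.frame_times is not None:
            return np.asarray(self.frame_times, dtype=float)
        return np.arange(0.0, self.t_end + 1e-9, 1.0)


def _truncated_normal(rng, mean, sd, lo=None, hi=None):
    """Draw one normal variate, redrawing outside [lo, hi] (keeps tails sane)."""
    if sd == 0:
        return float(mean)
    for _ in range(100):
        x = float(rng.normal(mean, sd))
        if (lo is None or x >= lo) and (hi is None or x <= hi):
            return x
    return float(np.clip(x, lo, hi))


def make_initial_rod(
    length: float,
    base_angle: float,
    mp: MechanicalParams,
    n_vertices: int = 41,
) -> RodState:
    """Straight clamped rod of the given length, pre-equilibrated under gravity."""
    state = straight_rod(length, n_vertices, base_angle)
    eq, _ = equilibrate(state, mp)
    return eq


def sample_frames(
    traj: Trajectory,
    frame_times,
    n_points: int,
    noise_sigma: float,
    rng: np.random.Generator | None,
    individual_id: str,
    genotype: str,
) -> CenterlineSeries:
    """Sample centerline points from stored trajectory frames.

    Points are placed at uniform arc-length spacing along an interpolating
    cubic spline through the frame's vertex positions (base and tip always
    included) and perturbed with isotropic Gaussian noise of ``noise_sigma``.

    Raises
    ------
    KeyError
        If a requested frame time is not stored in the trajectory.
    """
    if noise_sigma > 0 and rng is None:
        raise ValueError("rng required when noise_sigma > 0")
    samples = []
    for t in np.asarray(frame_times, dtype=float):
        frame = traj.frame_at(t)
        x = frame.state.positions
        s_vertices = frame.geometry.arc_length
        sx = make_interp_spline(s_vertices, x[:, 0], k=3)
        sy = make_interp_spline(s_vertices, x[:, 1], k=3)
        s_pts = np.linspace(0.0, s_vertices[-1], n_points)
        pts = np.stack([sx(s_pts), sy(s_pts)], axis=1)
        if noise_sigma > 0:
            pts = pts + rng.normal(0.0, noise_sigma, pts.shape)
        samples.append(CenterlineSample(time=float(t), points=pts))
    return CenterlineSeries(individual_id, genotype, samples)


# alias used at call sites that sample every stored frame
def sample_series(
    traj: Trajectory,
    spec: CohortSpec,
    rng: np.random.Generator | None,
    individual_id: str = "ind",
) -> CenterlineSeries:
    """Sample a full series according to a cohort spec's sampling settings."""
    return sample_frames(
        traj,
        spec.resolved_frame_times(),
        spec.n_points,
        spec.noise_sigma,
        rng,
        individual_id,
        spec.genotype,
    )


def simulate_individual(
    spec: CohortSpec,
    mp_template: MechanicalParams,
    rng: np.random.Generator,
    individual_id: str,
) -> tuple[CenterlineSeries, dict, Trajectory]:
    """Draw one individual's parameters, simulate and sample it.

    Returns the sampled series, a ground-truth parameter record and the
    underlying trajectory.
    """
    length = _truncated_normal(rng, spec.length_mean, spec.length_sd, lo=10.0)
    angle = _truncated_normal(
        rng, spec.base_angle_mean, spec.base_angle_sd, lo=-1.0, hi=1.0
    )
    beta = _truncated_normal(rng, spec.beta_mean, spec.beta_sd, lo=0.0)
    gamma = _truncated_normal(rng, spec.gamma_mean, spec.gamma_sd, lo=1e-6)
    v = _truncated_normal(rng, spec.growth_speed_mean, spec.growth_speed_sd, lo=0.0)
    rho = _truncated_normal(rng, spec.rho_mean, spec.rho_sd, lo=1e-6)
    mp = replace(mp_template, linear_density=rho)
    gp = GrowthParams(
        growth_speed=v,
        growth_zone_length=length,
        gravitropic_sensitivity=beta,
        proprioceptive_sensitivity=gamma,
        t_end=spec.t_end,
    )
    init = make_initial_rod(length, angle, mp, n_vertices=spec.n_vertices)
    traj = simulate(init, mp, gp, equilibrate_init=False)
    series = sample_series(traj, spec, rng, individual_id=individual_id)
    groups = dimensionless_groups(gp, mp) if beta > 0 and gamma > 0 else None
    truth = {
        "individual_id": individual_id,
        "genotype": spec.genotype,
        "beta": beta,
        "gamma": gamma,
        "v": v,
        "L0": length,
        "base_angle": angle,
        "rho": rho,
        "S": groups.growth_sensitivity if groups else np.nan,
        "G": groups.growth_elasto_gravity if groups else np.nan,
    }
    return series, truth, traj


def make_cohorts(
    wt_spec: CohortSpec,
    mut_spec: CohortSpec,
    mp_template: MechanicalParams | None = None,
    seed: int = 0,
    keep_trajectories: bool = False,
) -> tuple[list[CenterlineSeries], pd.DataFrame, list[Trajectory] | None]:
    """Simulate and sample both cohorts.

    Returns (series list, ground-truth table, trajectories or None).  The
    ground-truth table records per-individual parameters and the seed, for
    parameter-recovery experiments.
    """
    if mp_template is None:
        mp_template = MechanicalParams()
    root = np.random.default_rng(seed)
    series_list: list[CenterlineSeries] = []
    truths: list[dict] = []
    trajs: list[Trajectory] = []
    for spec in (wt_spec, mut_spec):
        for i in range(spec.n_individuals):
            rng = np.random.default_rng(root.integers(0, 2**63 - 1))
            ind_id = f"{spec.genotype}_{i:02d}"
            series, truth, traj = simulate_individual(spec, mp_template, rng, ind_id)
            truth["seed"] = seed
            series_list.append(series)
            truths.append(truth)
            if keep_trajectories:
                trajs.append(traj)
    table = pd.DataFrame(truths)
    return series_list, table, (trajs if keep_trajectories else None)
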