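"""Underdamped Langevin dynamics with well-tempered metadynamics on a 1D CV.

A single particle moves on the 2D Wolfe–Quapp surface in the NVT ensemble.
Integration uses the BAOAB splitting of the Langevin equation, which has the
best configurational accuracy of the standard splittings at finite timestep;
in the zero-friction, zero-temperature limit it reduces to velocity Verlet.

Metadynamics bias is deposited along a one-dimensional collective variable
(CV): the projection of (x, y) onto a unit vector, by default the interwell
axis ("good" CV), optionally rotated by an angle theta to emulate suboptimal
CVs.  Hills are Gaussian, tempered by the well-tempered rule
h = h0 * exp(-V(s)/((gamma-1) k_B T)), and accumulated on a uniform grid
with nearest-node lookup, mirroring how PLUMED evaluates a gridded bias.

Unit conventions: energies in k_B T, distances in nm, times in fs at the
interface (reported first-passage times in ns); the integrator works
internally in ps so that amu·nm²/ps² = kJ/mol holds without conversion
factors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .errors import InvalidSequenceError
from .potential import START, Position2D, good_cv_direction, wq_gradient

__all__ = [
    "SimulationConfig",
    "MetaDConfig",
    "HillList",
    "BiasTrajectory",
    "cv_project",
    "bias_value",
    "deposit_hill",
    "langevin_step",
    "run_fpt_trajectory",
    "sample_unbiased_fpts",
    "deposition_rate_to_period",
]

#: Boltzmann constant, kJ mol^-1 K^-1.
KB_KJ_MOL_K = 0.00831446261815324

# Gaussians are truncated beyond this many widths from their center when
# accumulated on the grid (exp(-18) ~ 1.5e-8, below single-hill resolution).
_HILL_CUTOFF_SIGMAS = 6.0


@dataclass(frozen=True)
class SimulationConfig:
    """Physical and bookkeeping parameters of one Langevin run.

    Defaults are the reference conditions for the Wolfe–Quapp system:
    a 40 a.u. particle at 300 K, 1 fs timestep, 0.01 fs^-1 friction,
    started at the global minimum, stopped on the committor-style target
    x < -1.4 nm ∧ y > 1.0 nm around the second minimum.
    """

    mass: float = 40.0  # a.u. (amu)
    temperature: float = 300.0  # K
    timestep: float = 1.0  # fs
    friction: float = 0.01  # fs^-1
    start: Position2D = START
    target_x_max: float = -1.4  # nm
    target_y_min: float = 1.0  # nm
    stop_check_stride: int = 1  # steps
    max_steps: int = 10**9
    seed: int | None = None
    potential_scale: float = 1.0  # multiplies the whole surface

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.friction < 0:
            raise ValueError("friction must be nonnegative")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.max_steps <= 0:
            raise ValueError("max_steps must be positive")
        if self.stop_check_stride < 1:
            raise ValueError("stop_check_stride must be >= 1")

    @property
    def kT_kJ_mol(self) -> float:
        return KB_KJ_MOL_K * self.temperature

    def in_target(self, p: Position2D) -> bool:
        return p[0] < self.target_x_max and p[1] > self.target_y_min


@dataclass(frozen=True)
class MetaDConfig:
    """Well-tempered metadynamics parameters.

    Defaults follow the reference setup: hills of height 0.5 k_B T, bias
    factor 5, width 0.1 nm, on a grid with 0.01 nm spacing, deposited every
    10^5 steps (a 10 ns^-1 deposition rate at a 1 fs timestep), biasing the
    good CV (theta = 0).
    """

    hill_height_h0: float = 0.5  # k_B T
    bias_factor_gamma: float = 5.0
    hill_width_sigma: float = 0.1  # nm
    grid_spacing: float = 0.01  # nm
    deposition_period: int = 100_000  # steps
    cv_angle_theta: float = 0.0  # degrees, rotation away from the good CV
    grid_min: float = -4.0  # nm
    grid_max: float = 4.0  # nm
    good_cv: tuple[float, float] | None = None  # default: interwell axis

    def __post_init__(self) -> None:
        if self.hill_height_h0 <= 0:
            raise ValueError("hill_height_h0 must be positive")
        if self.bias_factor_gamma <= 1:
            raise ValueError("bias_factor_gamma must exceed 1")
        if self.hill_width_sigma <= 0 or self.grid_spacing <= 0:
            raise ValueError("sigma and grid_spacing must be positive")
        if self.deposition_period < 1:
            raise ValueError("deposition_period must be >= 1")
        if self.grid_max <= self.grid_min:
            raise ValueError("grid_max must exceed grid_min")

    def cv_unit_vector(self) -> np.ndarray:
        """Lab-frame unit vector of the biased CV (good CV rotated by theta)."""
        good = np.asarray(
            self.good_cv if self.good_cv is not None else good_cv_direction(),
            dtype=float,
        )
        good = good / np.linalg.norm(good)
        th = math.radians(self.cv_angle_theta)
        rot = np.array(
            [[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]]
        )
        return rot @ good

    @property
    def n_grid(self) -> int:
        return int(round((self.grid_max - self.grid_min) / self.grid_spacing)) + 1


def deposition_rate_to_period(rate_per_ns: float, timestep_fs: float) -> int:
    """Convert a deposition rate (ns^-1) to a whole number of steps.

    Raises ValueError when the rate does not correspond to an integer
    number of timesteps.
    """
    period = 1e6 / (rate_per_ns * timestep_fs)
    rounded = round(period)
    if rounded < 1 or abs(period - rounded) > 1e-6:
        raise ValueError(
            f"deposition rate {rate_per_ns} ns^-1 is not a whole number of "
            f"{timestep_fs} fs steps"
        )
    return int(rounded)


# ---------------------------------------------------------------------------
# CV projection and hill bookkeeping
# ---------------------------------------------------------------------------


def cv_project(
    p: Position2D, theta: float = 0.0, good_cv_dir: np.ndarray | None = None
) -> float:
    """Project a position onto the good-CV direction rotated by ``theta`` degrees.

    ``theta = 0`` is the good CV itself; larger angles mix in the orthogonal
    direction and degrade the CV's ability to separate the metastable states.
    """
    e = np.asarray(good_cv_dir if good_cv_dir is not None else good_cv_direction())
    th = math.radians(theta)
    ex = math.cos(th) * e[0] - math.sin(th) * e[1]
    ey = math.sin(th) * e[0] + math.cos(th) * e[1]
    return float(p[0] * ex + p[1] * ey)


@dataclass
class HillList:
    """Record of deposited Gaussian hills with shared width.

    Heights are post-tempering (the values actually added to the bias), so
    the bias at CV value s is simply the sum of the stored Gaussians.
    Evaluation snaps s to the nearest grid node, matching the gridded bias
    used during integration.
    """

    width: float  # nm
    bias_factor: float
    grid_min: float = -4.0
    grid_max: float = 4.0
    grid_spacing: float = 0.01
    centers: np.ndarray = field(default_factory=lambda: np.empty(0))
    heights: np.ndarray = field(default_factory=lambda: np.empty(0))  # k_B T
    deposit_times: np.ndarray = field(default_factory=lambda: np.empty(0))  # fs

    @classmethod
    def from_metad(cls, cfg: MetaDConfig) -> "HillList":
        return cls(
            width=cfg.hill_width_sigma,
            bias_factor=cfg.bias_factor_gamma,
            grid_min=cfg.grid_min,
            grid_max=cfg.grid_max,
            grid_spacing=cfg.grid_spacing,
        )

    def __len__(self) -> int:
        return len(self.centers)

    def _snap(self, s: float) -> float:
        """Nearest grid node, clamped to the grid edges."""
        i = round((s - self.grid_min) / self.grid_spacing)
        i = min(max(i, 0), int(round((self.grid_max - self.grid_min) / self.grid_spacing)))
        return self.grid_min + i * self.grid_spacing


def bias_value(hills: HillList, s: float) -> float:
    """Total bias energy (k_B T) at CV value ``s``, from the gridded hills.

    Returns 0 for an empty hill list.  ``s`` outside the grid uses the
    boundary node.
    """
    if len(hills) == 0:
        return 0.0
    node = hills._snap(s)
    d = node - hills.centers
    return float(np.sum(hills.heights * np.exp(-(d * d) / (2.0 * hills.width**2))))


def deposit_hill(hills: HillList, s: float, t: float, cfg: MetaDConfig) -> HillList:
    """Append a well-tempered hill at CV value ``s`` deposited at time ``t`` fs.

    The new height is h0 * exp(-V(s)/(gamma - 1)) with V the bias (k_B T)
    before this deposition, so heights at a revisited center are
    non-increasing and the accumulated bias grows ever more slowly
    (logarithmically in the number of hills) instead of piling up linearly.
    """
    if len(hills) and t <= hills.deposit_times[-1]:
        raise InvalidSequenceError(
            f"deposit time {t} fs not after previous {hills.deposit_times[-1]} fs"
        )
    v_before = bias_value(hills, s)
    h = cfg.hill_height_h0 * math.exp(-v_before / (cfg.bias_factor_gamma - 1.0))
    return HillList(
        width=hills.width,
        bias_factor=hills.bias_factor,
        grid_min=hills.grid_min,
        grid_max=hills.grid_max,
        grid_spacing=hills.grid_spacing,
        centers=np.append(hills.centers, s),
        heights=np.append(hills.heights, h),
        deposit_times=np.append(hills.deposit_times, t),
    )


# ---------------------------------------------------------------------------
# Trajectory containers
# ---------------------------------------------------------------------------


@dataclass
class BiasTrajectory:
    """Per-step bias record of one first-passage trajectory.

    ``bias_series[i]`` is the instantaneous bias energy (k_B T) at the
    walker's CV position after step i+1 — exactly the series entering the
    acceleration-factor rescaling.  For unbiased runs the series is all
    zeros.  ``fpt_physical`` is in ns; ``reached`` is False for censored
    trajectories that hit ``max_steps`` first.
    """

    timestep: float  # fs
    bias_series: np.ndarray  # k_B T, one entry per step
    fpt_physical: float  # ns
    reached: bool
    cv_series: np.ndarray | None = None  # nm, optional (for COLVAR output)
    hills: HillList | None = None

    def __post_init__(self) -> None:
        self.bias_series = np.asarray(self.bias_series, dtype=float)
        if self.bias_series.size and self.bias_series.min() < 0:
            raise ValueError("bias_series must be nonnegative")
        if self.reached and self.bias_series.size:
            implied = self.bias_series.size * self.timestep * 1e-6
            if not math.isclose(implied, self.fpt_physical, rel_tol=1e-9, abs_tol=1e-12):
                raise ValueError(
                    "bias_series length x timestep inconsistent with fpt_physical"
                )

    @property
    def n_steps(self) -> int:
        return int(self.bias_series.size)


# ---------------------------------------------------------------------------
# Integration kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _baoab_step(x, y, vx, vy, fx, fy, dt, c1, c2, inv_m, scale, kT, rng):
    """One BAOAB step; forces in kJ/mol/nm, velocities nm/ps, dt ps.

    Returns the updated state and the force at the new position (conservative
    part only; the caller adds bias forces when metadynamics is active).
    """
    half = 0.5 * dt
    vx += half * fx * inv_m
    vy += half * fy * inv_m
    x += half * vx
    y += half * vy
    vx = c1 * vx + c2 * rng.standard_normal()
    vy = c1 * vy + c2 * rng.standard_normal()
    x += half * vx
    y += half * vy
    gx, gy = wq_gradient(x, y, scale)
    fx = -kT * gx
    fy = -kT * gy
    vx += half * fx * inv_m
    vy += half * fy * inv_m
    return x, y, vx, vy, fx, fy


@njit(cache=True)
def _run_fpt_kernel(
    x0,
    y0,
    dt_ps,
    gamma_ps,
    mass,
    kT,
    scale,
    ex,
    ey,
    use_metad,
    h0,
    bias_factor,
    sigma,
    grid_min,
    spacing,
    n_grid,
    period,
    x_max,
    y_min,
    stride,
    max_steps,
    record,
    rng,
):
    """Integrate one first-passage trajectory.

    Returns (reached, n_steps, bias_series, cv_series, hill_centers,
    hill_heights, hill_steps, n_hills).  Series arrays are sized n_steps when
    ``record`` is set, otherwise empty.
    """
    c1 = math.exp(-gamma_ps * dt_ps)
    c2 = math.sqrt(kT / mass * (1.0 - c1 * c1))
    inv_m = 1.0 / mass
    half = 0.5 * dt_ps
    sig_v = math.sqrt(kT / mass)

    x = x0
    y = y0
    # Maxwell–Boltzmann initial velocities.
    vx = sig_v * rng.standard_normal()
    vy = sig_v * rng.standard_normal()
    gx, gy = wq_gradient(x, y, scale)
    fx = -kT * gx  # total force (conservative + bias), kJ/mol/nm
    fy = -kT * gy

    grid = np.zeros(n_grid)
    dgrid = np.zeros(n_grid)
    max_hills = max_steps // period + 1 if use_metad else 1
    hill_c = np.empty(max_hills)
    hill_h = np.empty(max_hills)
    hill_step = np.empty(max_hills, dtype=np.int64)
    n_hills = 0
    win = int(_HILL_CUTOFF_SIGMAS * sigma / spacing) + 1
    inv2s2 = 1.0 / (2.0 * sigma * sigma)

    cap = 1 << 14 if record else 0
    bias_series = np.empty(cap)
    cv_series = np.empty(cap)

    reached = False
    step = 0
    while step < max_steps:
        # BAOAB with the total force; hills deposited at a step boundary act
        # from the following step onward (PLUMED stride semantics).
        vx += half * fx * inv_m
        vy += half * fy * inv_m
        x += half * vx
        y += half * vy
        vx = c1 * vx + c2 * rng.standard_normal()
        vy = c1 * vy + c2 * rng.standard_normal()
        x += half * vx
        y += half * vy
        gx, gy = wq_gradient(x, y, scale)
        fx = -kT * gx
        fy = -kT * gy
        b = 0.0
        if use_metad:
            s = ex * x + ey * y
            node = int(round((s - grid_min) / spacing))
            if node < 0:
                node = 0
            elif node >= n_grid:
                node = n_grid - 1
            fx += -kT * dgrid[node] * ex
            fy += -kT * dgrid[node] * ey
        vx += half * fx * inv_m
        vy += half * fy * inv_m
        step += 1

        if use_metad:
            if step % period == 0:
                h = h0 * math.exp(-grid[node] / (bias_factor - 1.0))
                lo = node - win
                if lo < 0:
                    lo = 0
                hi = node + win + 1
                if hi > n_grid:
                    hi = n_grid
                for i in range(lo, hi):
                    g = grid_min + i * spacing
                    d = g - s
                    e = h * math.exp(-d * d * inv2s2)
                    grid[i] += e
                    dgrid[i] += -d / (sigma * sigma) * e
                hill_c[n_hills] = s
                hill_h[n_hills] = h
                hill_step[n_hills] = step
                n_hills += 1
                # Refresh the stored force so the next first half-kick sees
                # the just-deposited hill.
                fx = -kT * (gx + dgrid[node] * ex)
                fy = -kT * (gy + dgrid[node] * ey)
            b = grid[node]

        if record:
            if step > cap:
                new_cap = cap * 2
                nb = np.empty(new_cap)
                nc = np.empty(new_cap)
                nb[:cap] = bias_series
                nc[:cap] = cv_series
                bias_series = nb
                cv_series = nc
                cap = new_cap
            bias_series[step - 1] = b
            cv_series[step - 1] = ex * x + ey * y

        if step % stride == 0 and x < x_max and y > y_min:
            reached = True
            break

    return (
        reached,
        step,
        bias_series[:step] if record else bias_series[:0],
        cv_series[:step] if record else cv_series[:0],
        hill_c[:n_hills],
        hill_h[:n_hills],
        hill_step[:n_hills],
        n_hills,
    )


@njit(cache=True)
def _run_many_unbiased(
    n_traj, x0, y0, dt_ps, gamma_ps, mass, kT, scale, x_max, y_min, stride, max_steps, rng
):
    """First-passage times (ps) of n_traj unbiased trajectories."""
    fpts = np.empty(n_traj)
    reached = np.empty(n_traj, dtype=np.bool_)
    c1 = math.exp(-gamma_ps * dt_ps)
    c2 = math.sqrt(kT / mass * (1.0 - c1 * c1))
    inv_m = 1.0 / mass
    sig_v = math.sqrt(kT / mass)
    for k in range(n_traj):
        x = x0
        y = y0
        vx = sig_v * rng.standard_normal()
        vy = sig_v * rng.standard_normal()
        gx, gy = wq_gradient(x, y, scale)
        fx = -kT * gx
        fy = -kT * gy
        step = 0
        hit = False
        while step < max_steps:
            x, y, vx, vy, fx, fy = _baoab_step(
                x, y, vx, vy, fx, fy, dt_ps, c1, c2, inv_m, scale, kT, rng
            )
            step += 1
            if step % stride == 0 and x < x_max and y > y_min:
                hit = True
                break
        fpts[k] = step * dt_ps
        reached[k] = hit
    return fpts, reached


# ---------------------------------------------------------------------------
# Python-level API
# ---------------------------------------------------------------------------


def langevin_step(
    position: np.ndarray,
    velocity: np.ndarray,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    force: np.ndarray | None = None,
    force_fn=None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Advance one BAOAB timestep; returns (position, velocity, new force).

    ``force`` is the total force (kJ/mol/nm) at the current position and
    ``force_fn(position) -> force`` evaluates the force field (defaults to
    the scaled Wolfe–Quapp conservative force); passing the returned force
    back in avoids recomputation when stepping in a loop.  Velocities are
    in nm/ps.  With friction = 0 the noise vanishes (c2 = 0) and the scheme
    reduces to velocity Verlet.
    """
    kT = cfg.kT_kJ_mol
    dt_ps = cfg.timestep * 1e-3
    gamma_ps = cfg.friction * 1e3
    c1 = math.exp(-gamma_ps * dt_ps)
    c2 = math.sqrt(kT / cfg.mass * (1.0 - c1 * c1))
    half = 0.5 * dt_ps
    if force_fn is None:

        def force_fn(p):
            gx, gy = wq_gradient(p[0], p[1], cfg.potential_scale)
            return np.array([-kT * gx, -kT * gy])

    p = np.asarray(position, dtype=float).copy()
    v = np.asarray(velocity, dtype=float).copy()
    f = np.asarray(force_fn(p) if force is None else force, dtype=float)
    v += half * f / cfg.mass
    p += half * v
    v = c1 * v + c2 * rng.standard_normal(v.shape)
    p += half * v
    f = np.asarray(force_fn(p), dtype=float)
    v += half * f / cfg.mass
    return p, v, f


def run_fpt_trajectory(
    sim: SimulationConfig,
    metad: MetaDConfig | None = None,
    rng: np.random.Generator | int | None = None,
    record_bias: bool = True,
) -> BiasTrajectory:
    """Run one trajectory until the target region is reached (or censored).

    The target predicate x < target_x_max ∧ y > target_y_min is checked
    every ``stop_check_stride`` steps.  With metadynamics active, the
    instantaneous bias at the walker's CV is recorded every step (after any
    hill deposited at that step), which is the series needed for
    first-passage-time rescaling.  Hitting ``max_steps`` returns a censored
    trajectory (``reached=False``) rather than raising.

    Identical (config, seed) pairs give bit-identical trajectories.
    """
    if rng is None:
        rng = np.random.default_rng(sim.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))

    if sim.in_target(sim.start):
        return BiasTrajectory(
            timestep=sim.timestep,
            bias_series=np.empty(0),
            fpt_physical=0.0,
            reached=True,
        )

    use_metad = metad is not None
    if use_metad:
        e = metad.cv_unit_vector()
        n_hill_cap = sim.max_steps // metad.deposition_period + 1
        if n_hill_cap > 50_000_000:
            raise ValueError(
                "max_steps / deposition_period implies an unreasonable hill count"
            )
    else:
        metad = MetaDConfig()  # placeholder values; kernel ignores them
        e = np.array([1.0, 0.0])

    (reached, n_steps, bias_series, cv_series, hc, hh, hstep, n_hills) = _run_fpt_kernel(
        float(sim.start[0]),
        float(sim.start[1]),
        sim.timestep * 1e-3,
        sim.friction * 1e3,
        sim.mass,
        sim.kT_kJ_mol,
        sim.potential_scale,
        float(e[0]),
        float(e[1]),
        use_metad,
        metad.hill_height_h0,
        metad.bias_factor_gamma,
        metad.hill_width_sigma,
        metad.grid_min,
        metad.grid_spacing,
        metad.n_grid,
        metad.deposition_period,
        sim.target_x_max,
        sim.target_y_min,
        sim.stop_check_stride,
        sim.max_steps,
        record_bias,
        rng,
    )

    hills = None
    if use_metad:
        hills = HillList(
            width=metad.hill_width_sigma,
            bias_factor=metad.bias_factor_gamma,
            grid_min=metad.grid_min,
            grid_max=metad.grid_max,
            grid_spacing=metad.grid_spacing,
            centers=np.asarray(hc),
            heights=np.asarray(hh),
            deposit_times=np.asarray(hstep, dtype=float) * sim.timestep,
        )
    if not record_bias:
        bias_series = np.zeros(0)
        cv_series = None
    elif not use_metad:
        bias_series = np.zeros(n_steps)

    return BiasTrajectory(
        timestep=sim.timestep,
        bias_series=bias_series,
        fpt_physical=n_steps * sim.timestep * 1e-6,
        reached=bool(reached),
        cv_series=cv_series if record_bias else None,
        hills=hills,
    )


def sample_unbiased_fpts(
    sim: SimulationConfig,
    n_traj: int,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """First-passage times (ns) of ``n_traj`` unbiased trajectories.

    A batched fast path for brute-force reference runs (no bias recording).
    Returns (fpts_ns, reached); censored entries report the time simulated.
    """
    if rng is None:
        rng = np.random.default_rng(sim.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    fpts_ps, reached = _run_many_unbiased(
        n_traj,
        float(sim.start[0]),
        float(sim.start[1]),
        sim.timestep * 1e-3,
        sim.friction * 1e3,
        sim.mass,
        sim.kT_kJ_mol,
        sim.potential_scale,
        sim.target_x_max,
        sim.target_y_min,
        sim.stop_check_stride,
        sim.max_steps,
        rng,
    )
    return fpts_ps * 1e-3, reached


def scaled_config(sim: SimulationConfig, scale: float) -> SimulationConfig:
    """A copy of ``sim`` with the potential multiplied by ``scale``."""
    return replace(sim, potential_scale=scale)
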