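"""Experiment drivers: tracking regimes, velocity scans, intrinsic speed,
anticipatory time, phase maps and the confluence point.

Every protocol starts from a *warm* network: the fields are relaxed
under a static stimulus until stationary, so that measured displacements
reflect the steady tracking behaviour rather than start-up transients.
Sweeps are integrated as batches (one array row per parameter cell or
stimulus velocity), which keeps even the phase-map scans desk-scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import (
    Kernel,
    ModelParams,
    RingGrid,
    RAD_PER_MS_TO_DEG_PER_S,
    gaussian_input,
)
from .simulate import (
    TrackingResult,
    center_of_mass,
    run_free,
    run_tracking,
    settle,
    steady_anticipatory_time,
    steady_value,
    unwrap_series,
)

logger = logging.getLogger("cannstpp")

#: bump speeds at or below this (rad/ms) count as static (~0.57 deg/s)
STATIC_SPEED_THRESHOLD = 1e-5

#: |tau_ant| below this (ms) counts as perfect (zero-lag) tracking
PERFECT_TRACKING_TOL_MS = 0.5


def static_threshold_deg_per_s() -> float:
    """The static-speed threshold expressed in deg/s."""
    return STATIC_SPEED_THRESHOLD * RAD_PER_MS_TO_DEG_PER_S


@dataclass(frozen=True)
class SweepSpec:
    """Parameter grids for the sweep protocols.

    Defaults are the full study grids: ``alpha``/``beta`` from 0 to 0.2
    in steps of 0.004, stimulus velocities from 0 to 0.008 rad/ms in
    steps of 0.0002, stimulus magnitude 3.0.
    """

    alpha_values: Sequence[float] = field(
        default_factory=lambda: tuple(np.round(np.arange(0.0, 0.2001, 0.004), 6))
    )
    beta_values: Sequence[float] = field(
        default_factory=lambda: tuple(np.round(np.arange(0.0, 0.2001, 0.004), 6))
    )
    v_ext_values: Sequence[float] = field(
        default_factory=lambda: tuple(np.round(np.arange(0.0, 0.008001, 0.0002), 7))
    )
    A_values: Sequence[float] = field(default_factory=lambda: (3.0,))
    tau_2_values: Sequence[float] = field(default_factory=lambda: (500.0,))

    def __post_init__(self) -> None:
        for name in ("alpha_values", "beta_values", "v_ext_values",
                     "A_values", "tau_2_values"):
            vals = tuple(float(v) for v in getattr(self, name))
            if len(vals) == 0:
                raise ValueError(f"{name} must be non-empty")
            if any(b < a for a, b in zip(vals, vals[1:])):
                raise ValueError(f"{name} must be sorted ascending")
            object.__setattr__(self, name, vals)

    @classmethod
    def coarse(cls) -> "SweepSpec":
        """Desk-scale sub-grids: 6x6 in (alpha, beta), velocity step
        0.0005 rad/ms."""
        return cls(
            alpha_values=tuple(np.round(np.linspace(0.0, 0.2, 6), 6)),
            beta_values=tuple(np.round(np.linspace(0.0, 0.2, 6), 6)),
            v_ext_values=tuple(np.round(np.arange(0.0, 0.008001, 0.0005), 7)),
        )

    def to_dict(self) -> dict:
        return {
            "alpha_values": list(self.alpha_values),
            "beta_values": list(self.beta_values),
            "v_ext_values": list(self.v_ext_values),
            "A_values": list(self.A_values),
            "tau_2_values": list(self.tau_2_values),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SweepSpec":
        known = {"alpha_values", "beta_values", "v_ext_values", "A_values",
                 "tau_2_values"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown key(s) in sweep section: {sorted(unknown)}")
        return cls(**d)


@dataclass
class VelocityScan:
    """Steady displacement versus stimulus velocity for one regime."""

    v_ext: np.ndarray  # rad/ms
    s: np.ndarray  # steady displacement, rad (NaN where never steady)
    steady: np.ndarray  # bool per velocity
    tau_ant: np.ndarray  # ms (NaN at v=0 or unsteady)
    A: float
    alpha: float
    beta: float

    def anticipation_interval(self):
        """Velocity interval where the bump leads the stimulus.

        Sign changes of the steady displacement are located by linear
        interpolation between scan points.  Returns ``(v_lo, v_hi)`` in
        rad/ms, or ``None`` when no velocity is anticipatory.  An upper
        endpoint equal to the last scanned velocity means the interval
        is open at the top of the scan range.
        """
        mask = self.steady & (self.v_ext > 0)
        v = self.v_ext[mask]
        s = self.s[mask]
        pos = np.nonzero(s > 0)[0]
        if pos.size == 0:
            return None
        first, last = int(pos[0]), int(pos[-1])
        if first == 0:
            v_lo = 0.0  # leads from the slowest scanned velocity onwards
        else:
            v_lo = _zero_crossing(v[first - 1], s[first - 1], v[first], s[first])
        if last == len(s) - 1:
            v_hi = float(v[-1])  # open at the top of the scan range
        else:
            v_hi = _zero_crossing(v[last], s[last], v[last + 1], s[last + 1])
        return v_lo, v_hi

    def anticipation_interval_deg_per_s(self):
        iv = self.anticipation_interval()
        if iv is None:
            return None
        return tuple(v * RAD_PER_MS_TO_DEG_PER_S for v in iv)

    def max_anticipatory_time(self) -> float:
        """Maximum of tau_ant over the scanned velocities (T_ant), ms.

        Negative when every velocity is delayed; NaN when no velocity
        reached steady tracking.
        """
        valid = self.steady & (self.v_ext > 0)
        if not np.any(valid):
            return float("nan")
        return float(np.max(self.tau_ant[valid]))


@dataclass
class PhaseMapResult:
    """(alpha, beta) maps of intrinsic speed and maximal anticipatory time."""

    alpha_values: np.ndarray
    beta_values: np.ndarray
    v_int: np.ndarray  # (n_alpha, n_beta), rad/ms; NaN = failed cell
    T_ant: np.ndarray  # (n_alpha, n_beta), ms; NaN = failed cell
    v_int_steady: np.ndarray  # bool, speed measurement converged
    collapsed: np.ndarray  # bool, bump vanished during the free run

    @property
    def static_mask(self) -> np.ndarray:
        return self.v_int <= STATIC_SPEED_THRESHOLD

    def anticipation_outside_moving(self) -> np.ndarray:
        """Cells with T_ant > 0 but no intrinsic motion, excluding cells
        with a moving 4-neighbour (one-grid-cell boundary tolerance)."""
        bad = (self.T_ant > 0) & self.static_mask
        moving = ~self.static_mask
        near_moving = np.zeros_like(moving)
        near_moving |= np.roll(moving, 1, axis=0)
        near_moving |= np.roll(moving, -1, axis=0)
        near_moving |= np.roll(moving, 1, axis=1)
        near_moving |= np.roll(moving, -1, axis=1)
        return bad & ~near_moving


def _zero_crossing(v0, s0, v1, s1) -> float:
    return float(v0 + (v1 - v0) * (0.0 - s0) / (s1 - s0))


def _grid_kernel(params: ModelParams, grid: Optional[RingGrid],
                 kernel: Optional[Kernel]):
    if grid is None:
        grid = RingGrid()
    if kernel is None:
        kernel = Kernel(grid, params.a)
    return grid, kernel


def warm_start(
    params: ModelParams,
    A: float,
    z0: float = 0.0,
    grid: Optional[RingGrid] = None,
    kernel: Optional[Kernel] = None,
    dt: float = 0.1,
    tol: float = 1e-7,
    t_cap: float = 12000.0,
    alpha=None,
    beta=None,
):
    """Relax the network under a static stimulus of magnitude ``A`` at
    ``z0`` until stationary; returns ``(u, S, Q)``.

    ``alpha``/``beta`` may be (B, 1) arrays to warm a sweep batch in one
    go (the fields then have shape (B, n_points))."""
    grid, kernel = _grid_kernel(params, grid, kernel)
    I_ext = gaussian_input(grid, A, z0, params.a)
    u0 = 2.0 * I_ext
    if alpha is not None:
        batch = np.broadcast_shapes(np.shape(alpha), np.shape(beta))[:-1]
        u0 = np.broadcast_to(u0, batch + u0.shape).copy()
    S0 = np.zeros_like(u0)
    Q0 = np.zeros_like(u0)
    u, S, Q, residual, elapsed = settle(
        u0, S0, Q0, params, grid, kernel, I_ext, dt=dt, tol=tol, t_cap=t_cap,
        alpha=alpha, beta=beta,
    )
    if residual > tol:
        logger.warning(
            "warm start did not reach tol %.1e within %.0f ms (residual %.2e)",
            tol, t_cap, residual,
        )
    return u, S, Q


def _moving_input(grid: RingGrid, A, v_ext, a: float, z0_init=0.0):
    """Input-field callback for a stimulus moving at constant velocity.

    ``v_ext`` (and ``A``) may be (B, 1) arrays for batched scans."""

    def fn(t):
        return gaussian_input(grid, A, z0_init + v_ext * t, a)

    return fn


def run_moving_tracking(
    params: ModelParams,
    A: float,
    v_ext: float,
    grid: Optional[RingGrid] = None,
    kernel: Optional[Kernel] = None,
    dt: float = 0.1,
    t_max: float = 6000.0,
    sample_every: int = 10,
    warm: Optional[tuple] = None,
    window: float = 500.0,
    tol: float = 1e-4,
) -> TrackingResult:
    """Track a stimulus moving at constant ``v_ext`` from a warm start.

    The returned result carries the steady anticipatory time (NaN if the
    run never became steady within ``t_max``)."""
    grid, kernel = _grid_kernel(params, grid, kernel)
    if warm is None:
        warm = warm_start(params, A, 0.0, grid, kernel, dt=dt)
    u, S, Q = (f.copy() for f in warm)
    fn = _moving_input(grid, A, v_ext, params.a)
    times, zw, _ = run_tracking(u, S, Q, params, grid, kernel, fn,
                                dt=dt, t_max=t_max, sample_every=sample_every)
    z = unwrap_series(zw, anchor=np.asarray(0.0))
    z0 = v_ext * times
    result = TrackingResult(times=times, z=z, z0=z0, s=z - z0, v_ext=v_ext)
    if v_ext != 0.0:
        steady_anticipatory_time(result, v_ext, window=window, tol=tol)
    else:
        s_steady, steady = steady_value(times, result.s, window, tol)
        result.steady = bool(steady)
    return result


def classify_regime(tau_ant: float, tol_ms: float = PERFECT_TRACKING_TOL_MS) -> str:
    """Classify steady tracking by the sign of the anticipatory time."""
    if not np.isfinite(tau_ant):
        return "not steady"
    if abs(tau_ant) <= tol_ms:
        return "perfect"
    return "anticipatory" if tau_ant > 0 else "delayed"


def run_abrupt_tracking(
    params: ModelParams,
    A: float,
    z0_from: float = 0.0,
    z0_to: float = 1.0,
    grid: Optional[RingGrid] = None,
    kernel: Optional[Kernel] = None,
    dt: float = 0.1,
    t_max: float = 1500.0,
    sample_every: int = 10,
    warm: Optional[tuple] = None,
) -> TrackingResult:
    """Stimulus jump ``z0_from -> z0_to`` at t = 0 after a warm start.

    With plasticity enabled the bump centre overshoots the destination
    before settling; without it the approach is monotonic."""
    grid, kernel = _grid_kernel(params, grid, kernel)
    if warm is None:
        warm = warm_start(params, A, z0_from, grid, kernel, dt=dt)
    u, S, Q = (f.copy() for f in warm)
    I_ext = gaussian_input(grid, A, z0_to, params.a)
    times, zw, _ = run_tracking(u, S, Q, params, grid, kernel, lambda t: I_ext,
                                dt=dt, t_max=t_max, sample_every=sample_every)
    z = unwrap_series(zw, anchor=np.asarray(float(z0_from)))
    z0 = np.full_like(times, float(z0_to))
    return TrackingResult(times=times, z=z, z0=z0, s=z - z0, v_ext=0.0)


def scan_displacement_vs_velocity(
    params: ModelParams,
    A: float,
    v_list: Sequence[float],
    grid: Optional[RingGrid] = None,
    kernel: Optional[Kernel] = None,
    dt: float = 0.1,
    t_max: float = 6000.0,
    sample_every: int = 10,
    window: float = 500.0,
    tol: float = 1e-4,
    warm: Optional[tuple] = None,
    alpha=None,
    beta=None,
) -> VelocityScan:
    """Steady displacement for each stimulus velocity, in one batched run.

    ``alpha``/``beta`` may be (B, 1) arrays aligned with ``v_list`` to
    scan heterogeneous regimes; normally they are left at the values in
    ``params`` and the batch axis enumerates velocities."""
    grid, kernel = _grid_kernel(params, grid, kernel)
    v = np.asarray(list(v_list), dtype=float)
    if warm is None:
        warm = warm_start(params, A, 0.0, grid, kernel, dt=dt,
                          alpha=alpha, beta=beta)
    u, S, Q = (np.array(f, dtype=float) for f in warm)
    if u.ndim == 1:
        u = np.broadcast_to(u, (v.size,) + u.shape).copy()
        S = np.broadcast_to(S, u.shape).copy()
        Q = np.broadcast_to(Q, u.shape).copy()
    v_col = v[:, None]
    fn = _moving_input(grid, A, v_col, params.a)
    times, zw, _ = run_tracking(u, S, Q, params, grid, kernel, fn, dt=dt,
                                t_max=t_max, sample_every=sample_every,
                                alpha=alpha, beta=beta)
    z = unwrap_series(zw, anchor=np.zeros(v.size))
    s_series = z - v_col * times
    s_steady, steady = steady_value(times, s_series, window, tol)
    s_out = np.where(steady, s_steady, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        tau = np.where(steady & (v > 0), s_steady / v, np.nan)
    return VelocityScan(
        v_ext=v, s=s_out, steady=steady, tau_ant=tau, A=float(A),
        alpha=float(params.alpha) if alpha is None else float("nan"),
        beta=float(params.beta) if beta is None else float("nan"),
    )


def find_zero_lag_velocity(
    params: ModelParams,
    A: float,
    bracket=(0.003, 0.006),
    which: str = "upper",
    tol: float = 1e-5,
    grid: Optional[RingGrid] = None,
    kernel: Optional[Kernel] = None,
    dt: float = 0.1,
    t_max: float = 6000.0,
) -> float:
    """Bisection for the velocity of perfect (zero-lag) tracking.

    ``which='upper'`` targets the anticipation-to-delay crossing (the
    canonical zero-lag case, above the small-velocity delay zone);
    ``which='lower'`` targets the delay-to-anticipation crossing below
    it.  Raises ``ValueError`` when the steady displacement does not
    change sign over the bracket."""
    if which not in ("upper", "lower"):
        raise ValueError(f"which must be 'upper' or 'lower', got {which!r}")
    grid, kernel = _grid_kernel(params, grid, kernel)
    warm = warm_start(params, A, 0.0, grid, kernel, dt=dt)

    def steady_s(v: float) -> float:
        res = run_moving_tracking(params, A, v, grid, kernel, dt=dt,
                                  t_max=t_max, warm=warm)
        if not res.steady:
            raise RuntimeError(f"tracking at v_ext = {v} never became steady")
        return res.tau_ant * v  # steady displacement

    lo, hi = float(bracket[0]), float(bracket[1])
    s_lo, s_hi = steady_s(lo), steady_s(hi)
    want_lo = 1.0 if which == "upper" else -1.0  # sign of s at the low end
    if not (np.sign(s_lo) == want_lo and np.sign(s_hi) == -want_lo):
        raise ValueError(
            f"steady displacement does not bracket a {which} crossing: "
            f"s({lo}) = {s_lo:.3e}, s({hi}) = {s_hi:.3e}"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if np.sign(steady_s(mid)) == want_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass
class IntrinsicSpeedResult:
    v_int: float  # rad/ms; NaN when collapsed
    steady: bool
    collapsed: bool

    @property
    def static(self) -> bool:
        return (not self.collapsed) and self.v_int <= STATIC_SPEED_THRESHOLD


def _fit_slope(times: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Least-squares slope of z against times, batched over rows."""
    t = times - times.mean()
    return (z - z.mean(axis=-1, keepdims=True)) @ t / (t @ t)


def _intrinsic_speed_batch(
    params: ModelParams,
    grid: RingGrid,
    kernel: Kernel,
    alpha=None,
    beta=None,
    warm: Optional[tuple] = None,
    warm_A: float = 3.0,
    dt: float = 0.1,
    shift_modulations: bool = False,
    fit_window: float = 1000.0,
    slope_tol: float = 1e-6,
    t_release_cap: float = 10000.0,
):
    """Shift-and-release measurement of the intrinsic bump speed.

    Returns ``(v_int, steady, collapsed)`` arrays over the batch."""
    if warm is None:
        warm = warm_start(params, warm_A, 0.0, grid, kernel, dt=dt,
                          alpha=alpha, beta=beta)
    u, S, Q = (np.array(f, dtype=float) for f in warm)
    # manual intervention: one 2*pi/200 step of u towards positive x per tau_s
    shift_nodes = max(1, int(round(grid.n_points / 200)))
    _, _, (u, S, Q) = run_free(
        u, S, Q, params, grid, kernel, dt=dt, t_max=100.0 * params.tau_s,
        sample_every=int(round(params.tau_s / dt)),
        shift_period=params.tau_s, shift_nodes=shift_nodes,
        shift_modulations=shift_modulations, alpha=alpha, beta=beta,
    )
    batch = np.shape(u)[:-1]
    collapsed = np.zeros(batch, dtype=bool)
    steady = np.zeros(batch, dtype=bool)
    slope_prev = np.full(batch, np.nan)
    slope = np.full(batch, np.nan)
    z_last = center_of_mass(u, grid)
    elapsed = 0.0
    while elapsed < t_release_cap:
        times, zw, (u, S, Q) = run_free(
            u, S, Q, params, grid, kernel, dt=dt, t_max=fit_window,
            sample_every=10, alpha=alpha, beta=beta,
        )
        elapsed += fit_window
        collapsed |= np.max(u, axis=-1) < 1e-3
        z = unwrap_series(zw, anchor=z_last)
        z_last = zw[..., -1]
        slope_prev, slope = slope, _fit_slope(times, z)
        if elapsed >= 2 * fit_window:
            steady = np.abs(slope - slope_prev) < slope_tol
            if np.all(steady | collapsed):
                break
    v_int = np.where(collapsed, np.nan, slope)
    return v_int, steady & ~collapsed, collapsed


def measure_intrinsic_speed(
    params: ModelParams,
    grid: Optional[RingGrid] = None,
    kernel: Optional[Kernel] = None,
    dt: float = 0.1,
    warm_A: float = 3.0,
    shift_modulations: bool = False,
) -> IntrinsicSpeedResult:
    """Intrinsic (self-sustained) bump speed of one regime.

    Protocol: settle under a static stimulus, remove it, nudge ``u`` one
    2*pi/200 step towards positive x every ``tau_s`` for 100 ``tau_s``,
    then release and fit the steady drift of the bump centre.  Speeds at
    or below 1e-5 rad/ms count as static."""
    grid, kernel = _grid_kernel(params, grid, kernel)
    v, steady, collapsed = _intrinsic_speed_batch(
        params, grid, kernel, dt=dt, warm_A=warm_A,
        shift_modulations=shift_modulations,
    )
    return IntrinsicSpeedResult(float(v), bool(steady), bool(collapsed))


def measure_max_anticipatory_time(
    params: ModelParams,
    A: float,
    v_list: Sequence[float],
    **scan_kwargs,
) -> float:
    """Maximal anticipatory time T_ant = max over velocities of the
    steady ``s / v_ext`` (ms); negative when every velocity is delayed."""
    scan = scan_displacement_vs_velocity(params, A, v_list, **scan_kwargs)
    return scan.max_anticipatory_time()


def map_phase_diagram(
    sweep: SweepSpec,
    A: float = 3.0,
    params: Optional[ModelParams] = None,
    grid: Optional[RingGrid] = None,
    dt: float = 0.1,
    tau_2: Optional[float] = None,
    cell_chunk: int = 64,
    include_v_int: bool = True,
) -> PhaseMapResult:
    """Intrinsic-speed and maximal-anticipatory-time maps over the
    (alpha, beta) grid of ``sweep``.

    Each cell is warmed once under the static stimulus; the warm state
    then seeds both the shift-and-release speed measurement and the
    velocity scan for T_ant.  Cells are processed in batches of
    ``cell_chunk``; failures (collapse, unsteadiness) mark their cell
    NaN instead of aborting the map."""
    if params is None:
        params = ModelParams()
    if tau_2 is not None:
        params = params.replace(tau_2=tau_2)
    grid, kernel = _grid_kernel(params, grid, None)
    alphas = np.asarray(sweep.alpha_values)
    betas = np.asarray(sweep.beta_values)
    v_list = np.asarray([v for v in sweep.v_ext_values if v > 0])
    na, nb = alphas.size, betas.size
    AA, BB = np.meshgrid(alphas, betas, indexing="ij")
    cells_a = AA.ravel()
    cells_b = BB.ravel()
    n_cells = cells_a.size

    v_int = np.full(n_cells, np.nan)
    T_ant = np.full(n_cells, np.nan)
    steady_flags = np.zeros(n_cells, dtype=bool)
    collapse_flags = np.zeros(n_cells, dtype=bool)

    for start in range(0, n_cells, cell_chunk):
        sl = slice(start, min(start + cell_chunk, n_cells))
        a_col = cells_a[sl][:, None]
        b_col = cells_b[sl][:, None]
        nc = a_col.shape[0]
        try:
            warm = warm_start(params, A, 0.0, grid, kernel, dt=dt,
                              alpha=a_col, beta=b_col)
        except FloatingPointError as err:
            logger.warning("phase-map chunk %s failed to warm: %s", sl, err)
            continue
        if include_v_int:
            vi, sflag, cflag = _intrinsic_speed_batch(
                params, grid, kernel, alpha=a_col, beta=b_col, warm=warm, dt=dt)
            v_int[sl] = vi
            steady_flags[sl] = sflag
            collapse_flags[sl] = cflag
        # T_ant: every (cell, velocity) pair in one batch
        nv = v_list.size
        a_rep = np.repeat(a_col, nv, axis=0)
        b_rep = np.repeat(b_col, nv, axis=0)
        v_rep = np.tile(v_list, nc)[:, None]
        u = np.repeat(warm[0], nv, axis=0)
        S = np.repeat(warm[1], nv, axis=0)
        Q = np.repeat(warm[2], nv, axis=0)
        fn = _moving_input(grid, A, v_rep, params.a)
        try:
            times, zw, _ = run_tracking(u, S, Q, params, grid, kernel, fn,
                                        dt=dt, t_max=6000.0, sample_every=10,
                                        alpha=a_rep, beta=b_rep)
        except FloatingPointError as err:
            logger.warning("phase-map chunk %s tracking failed: %s", sl, err)
            continue
        z = unwrap_series(zw, anchor=np.zeros(nc * nv))
        s_series = z - v_rep * times
        s_steady, steady = steady_value(times, s_series)
        with np.errstate(invalid="ignore"):
            tau = np.where(steady, s_steady / v_rep[:, 0], np.nan)
        tau = tau.reshape(nc, nv)
        any_steady = np.any(np.isfinite(tau), axis=1)
        tau_max = np.max(np.where(np.isfinite(tau), tau, -np.inf), axis=1)
        T_ant[sl] = np.where(any_steady, tau_max, np.nan)

    return PhaseMapResult(
        alpha_values=alphas,
        beta_values=betas,
        v_int=v_int.reshape(na, nb),
        T_ant=T_ant.reshape(na, nb),
        v_int_steady=steady_flags.reshape(na, nb),
        collapsed=collapse_flags.reshape(na, nb),
    )


def find_confluence_point(
    params: ModelParams,
    A_list: Sequence[float],
    v_list: Sequence[float],
    spread_tol: float = 2e-3,
    **scan_kwargs,
):
    """Velocity at which the displacement curves for different stimulus
    magnitudes intersect (and the common displacement there).

    Below the confluence velocity a weaker stimulus yields the greater
    anticipation; above it the ordering reverses.  The point is located
    as the descending zero crossing of the weakest-minus-strongest
    displacement difference (the velocity where the steady displacement
    becomes independent of the stimulus strength); it coincides with the
    intrinsic speed of the regime.  Requires at least two distinct
    magnitudes."""
    A_vals = [float(A) for A in A_list]
    if len(set(A_vals)) < 2:
        raise ValueError("need at least two distinct stimulus magnitudes")
    scans = [scan_displacement_vs_velocity(params, A, v_list, **scan_kwargs)
             for A in A_vals]
    v = scans[0].v_ext
    mask = (v > 0)
    for sc in scans:
        mask &= sc.steady
    if not np.any(mask):
        raise RuntimeError("no velocity reached steady tracking for all magnitudes")
    vv = v[mask]
    s_grid = np.stack([sc.s[mask] for sc in scans])  # (nA, nv)
    d = s_grid[int(np.argmin(A_vals))] - s_grid[int(np.argmax(A_vals))]
    descending = np.nonzero((d[:-1] > 0) & (d[1:] <= 0))[0]
    if descending.size == 0:
        raise RuntimeError(
            "displacement curves do not cross: the weak-stimulus "
            "anticipation advantage never reverses over the scanned range"
        )
    j = int(descending[-1])
    v_conf = _zero_crossing(vv[j], d[j], vv[j + 1], d[j + 1])
    # total spread across all magnitudes, interpolated at the crossing
    spread_at = np.array([np.interp(v_conf, vv, s_row) for s_row in s_grid])
    spread = float(spread_at.max() - spread_at.min())
    if spread > spread_tol:
        raise RuntimeError(
            f"displacement curves do not meet: spread {spread:.3e} rad at "
            f"v = {v_conf:.5g} exceeds {spread_tol}"
        )
    s_conf = float(np.interp(v_conf, vv, s_grid.mean(axis=0)))
    return v_conf, s_conf
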