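"""Time integration and tracking observables.

Two layers live here.  :func:`integrate` is the reference fixed-step
integrator operating on a single :class:`~cannstpp.model.NetworkState`
and recording full field snapshots.  The ``run_*`` engines below advance
whole *batches* of networks at once (fields shaped ``(B, n_points)``,
with per-row ``alpha``/``beta``/``v_ext``), recording only the bump
centre; the sweep protocols are built on them.  Both layers share the
same right-hand side (:func:`cannstpp.model.field_derivatives`), so they
agree exactly step for step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .model import (
    Kernel,
    ModelParams,
    NetworkState,
    RingGrid,
    StimulusSpec,
    external_input,
    field_derivatives,
    gaussian_input,
    periodic_distance,
    wrap_angle,
)

__all__ = [
    "IntegratorConfig",
    "Trajectory",
    "TrackingResult",
    "integrate",
    "center_of_mass",
    "displacement_series",
    "steady_anticipatory_time",
    "shift_state",
    "unwrap_series",
    "settle",
    "run_tracking",
    "run_free",
    "steady_value",
]


@dataclass(frozen=True)
class IntegratorConfig:
    """Fixed-step integration settings.

    ``dt`` in ms; ``method`` is ``euler`` (default) or ``rk4``;
    ``record_every`` is a sampling stride in steps; an optional
    ``convergence_tol`` stops the run early once
    ``max |du/dt| * tau_s`` falls below it (stationarity).
    """

    dt: float = 0.1
    method: str = "euler"
    t_max: float = 1000.0
    record_every: int = 10
    convergence_tol: Optional[float] = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.method not in ("euler", "rk4"):
            raise ValueError(f"method must be 'euler' or 'rk4', got {self.method!r}")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")


@dataclass
class Trajectory:
    """Sampled states of one integration run."""

    times: np.ndarray
    u: np.ndarray  # (n_samples, n_points)
    S: np.ndarray
    Q: np.ndarray
    grid: RingGrid

    def __len__(self) -> int:
        return len(self.times)

    def state_at(self, i: int) -> NetworkState:
        return NetworkState(self.u[i], self.S[i], self.Q[i], float(self.times[i]))

    @property
    def final_state(self) -> NetworkState:
        return self.state_at(len(self) - 1)


@dataclass
class TrackingResult:
    """Bump-centre trajectory against a stimulus trajectory.

    ``z`` and ``z0`` are unwrapped (cumulative) angles; ``s = z - z0``
    is the displacement, positive in the direction of stimulus motion
    meaning anticipation.  ``tau_ant`` (ms) is defined only once the
    motion is steady.
    """

    times: np.ndarray
    z: np.ndarray
    z0: np.ndarray
    s: np.ndarray
    v_ext: float = 0.0
    tau_ant: Optional[float] = None
    steady: bool = False
    v_measured: Optional[float] = None

    def summary(self) -> dict:
        return {
            "v_ext_rad_per_ms": self.v_ext,
            "tau_ant_ms": None if self.tau_ant is None else float(self.tau_ant),
            "steady": bool(self.steady),
            "v_measured_rad_per_ms": (
                None if self.v_measured is None else float(self.v_measured)
            ),
            "s_final_rad": float(self.s[-1]),
        }


def integrate(
    state: NetworkState,
    params: ModelParams,
    stim: StimulusSpec,
    grid: RingGrid,
    config: IntegratorConfig,
    kernel: Optional[Kernel] = None,
) -> Trajectory:
    """Advance one network with a fixed-step scheme, recording snapshots.

    Deterministic; includes the initial and final states in the output.
    Raises ``FloatingPointError`` (with the failure time) if any field
    becomes non-finite.
    """
    if config.dt > params.tau_s / 10.0 + 1e-12:
        raise ValueError(
            f"dt = {config.dt} exceeds the stability guard tau_s/10 = "
            f"{params.tau_s / 10.0}"
        )
    if kernel is None:
        kernel = Kernel(grid, params.a)
    dt = config.dt
    n_steps = int(round(config.t_max / dt))
    u, S, Q = state.u.copy(), state.S.copy(), state.Q.copy()
    t0 = state.t

    times = [t0]
    us, Ss, Qs = [u.copy()], [S.copy()], [Q.copy()]

    def rhs(u, S, Q, t):
        I_ext = external_input(grid, stim, t, params.a)
        return field_derivatives(u, S, Q, I_ext, params, grid, kernel)

    for step in range(1, n_steps + 1):
        t = t0 + (step - 1) * dt
        if config.method == "euler":
            du, dS, dQ = rhs(u, S, Q, t)
            u = u + dt * du
            S = S + dt * dS
            Q = Q + dt * dQ
        else:  # rk4
            k1 = rhs(u, S, Q, t)
            k2 = rhs(u + 0.5 * dt * k1[0], S + 0.5 * dt * k1[1], Q + 0.5 * dt * k1[2], t + 0.5 * dt)
            k3 = rhs(u + 0.5 * dt * k2[0], S + 0.5 * dt * k2[1], Q + 0.5 * dt * k2[2], t + 0.5 * dt)
            k4 = rhs(u + dt * k3[0], S + dt * k3[1], Q + dt * k3[2], t + dt)
            u = u + dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
            S = S + dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
            Q = Q + dt / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])

        if step % config.record_every == 0 or step == n_steps:
            if not np.all(np.isfinite(u)):
                raise FloatingPointError(
                    f"integration failed: non-finite u at t = {t0 + step * dt} ms"
                )
            times.append(t0 + step * dt)
            us.append(u.copy())
            Ss.append(S.copy())
            Qs.append(Q.copy())
            if config.convergence_tol is not None:
                du, _, _ = rhs(u, S, Q, t0 + step * dt)
                if np.max(np.abs(du)) * params.tau_s < config.convergence_tol:
                    break

    return Trajectory(np.asarray(times), np.asarray(us), np.asarray(Ss), np.asarray(Qs), grid)


def center_of_mass(u: np.ndarray, grid: RingGrid):
    """Bump centre: the periodic centre of mass of ``u`` anchored at its
    peak node, wrapped into (-pi, pi].  Broadcasts over leading axes.

    Raises ``ValueError`` if any row of ``u`` is nowhere positive.
    """
    u = np.asarray(u, dtype=float)
    if np.any(np.all(u <= 0.0, axis=-1)):
        raise ValueError("undefined bump centre: u is nowhere positive")
    n = grid.n_points
    i_max = np.argmax(u, axis=-1)
    # node offsets from the peak, computed in index arithmetic so the
    # +-pi boundary wraps identically for every rotation of the field
    offs = np.mod(np.arange(n) - np.asarray(i_max)[..., None], n)
    offs = np.where(offs > n // 2, offs - n, offs)
    d = offs * grid.dx
    z = grid.x[i_max] + np.sum(d * u, axis=-1) / np.sum(u, axis=-1)
    return wrap_angle(z)


def shift_state(
    state: NetworkState, nodes: int, include_modulations: bool = False
) -> NetworkState:
    """Circularly rotate ``u`` by a whole number of grid nodes (positive
    = towards positive x).  ``S`` and ``Q`` are rotated too only when
    ``include_modulations`` is set; the intrinsic-speed protocol shifts
    ``u`` alone."""
    nodes = int(nodes)
    new = state.copy()
    new.u = np.roll(new.u, nodes, axis=-1)
    if include_modulations:
        new.S = np.roll(new.S, nodes, axis=-1)
        new.Q = np.roll(new.Q, nodes, axis=-1)
    return new


def unwrap_series(z: np.ndarray, anchor: Optional[np.ndarray] = None) -> np.ndarray:
    """Unwrap a sampled angle series by minimal-angle increments.

    ``anchor``, if given, fixes the starting value: the first sample is
    placed on the branch of ``z[..., 0]`` nearest to it.  Per-sample
    motion must stay below pi/2 for the reconstruction to be faithful.
    """
    z = np.asarray(z, dtype=float)
    dz = periodic_distance(z[..., 1:], z[..., :-1])
    if anchor is None:
        start = z[..., :1]
    else:
        anchor = np.asarray(anchor, dtype=float)
        start = anchor[..., None] + periodic_distance(z[..., :1], anchor[..., None])
    return np.concatenate([start, start + np.cumsum(dz, axis=-1)], axis=-1)


def displacement_series(
    traj: Trajectory, stim: StimulusSpec
) -> TrackingResult:
    """Displacement ``s(t) = z(t) - z0(t)`` from a recorded trajectory.

    Both the bump centre and the stimulus centre are unwrapped before
    subtraction, so a stimulus crossing the +-pi boundary produces a
    continuous ``s``.
    """
    if len(traj) < 2:
        raise ValueError("need at least two samples to build a displacement series")
    z_wrapped = center_of_mass(traj.u, traj.grid)
    z0 = np.asarray([stim.position(t) for t in traj.times])
    z = unwrap_series(z_wrapped, anchor=np.asarray(z0[0]))
    return TrackingResult(
        times=np.asarray(traj.times),
        z=z,
        z0=z0,
        s=z - z0,
        v_ext=stim.v_ext if stim.mode == "moving" else 0.0,
    )


def steady_value(
    times: np.ndarray,
    s: np.ndarray,
    window: float = 500.0,
    tol: float = 1e-4,
):
    """Steadiness detection on displacement series (batched).

    A series is steady when ``|s(t) - s(t - window)| < tol`` throughout
    the final window.  Returns ``(s_steady, steady_mask)`` where
    ``s_steady`` is the mean of the final window.
    """
    times = np.asarray(times, dtype=float)
    s = np.asarray(s, dtype=float)
    sample_dt = times[1] - times[0]
    w = int(round(window / sample_dt))
    if w < 1 or s.shape[-1] < 2 * w + 1:
        raise ValueError("series too short for the steadiness window")
    drift = np.abs(s[..., -w:] - s[..., -2 * w : -w])
    steady = np.max(drift, axis=-1) < tol
    s_steady = np.mean(s[..., -w:], axis=-1)
    return s_steady, steady


def steady_anticipatory_time(
    result: TrackingResult,
    v_ext: Optional[float] = None,
    window: float = 500.0,
    tol: float = 1e-4,
) -> float:
    """Anticipatory time ``tau_ant = s / v_ext`` at steady tracking.

    Fills in ``tau_ant``, ``steady`` and ``v_measured`` on the result
    and returns ``tau_ant`` (NaN when the run never became steady).
    Positive values mean the bump leads the stimulus.
    """
    if v_ext is None:
        v_ext = result.v_ext
    if v_ext == 0.0:
        raise ValueError("tau_ant is undefined for a static stimulus (v_ext = 0)")
    s_steady, steady = steady_value(result.times, result.s, window, tol)
    sample_dt = result.times[1] - result.times[0]
    w = int(round(window / sample_dt))
    slope = np.polyfit(result.times[-w:], result.z[-w:], 1)[0]
    result.v_measured = float(slope)
    result.steady = bool(steady)
    result.tau_ant = float(s_steady / v_ext) if steady else float("nan")
    return result.tau_ant


# ---------------------------------------------------------------------------
# batched engines


def _advance(
    u,
    S,
    Q,
    params: ModelParams,
    grid: RingGrid,
    kernel: Kernel,
    dt: float,
    n_steps: int,
    t0: float = 0.0,
    input_fn: Optional[Callable[[float], np.ndarray]] = None,
    alpha=None,
    beta=None,
):
    """Euler-advance batched fields in place-ish; returns final fields."""
    for step in range(n_steps):
        t = t0 + step * dt
        I_ext = None if input_fn is None else input_fn(t)
        du, dS, dQ = field_derivatives(u, S, Q, I_ext, params, grid, kernel, alpha, beta)
        u = u + dt * du
        S = S + dt * dS
        Q = Q + dt * dQ
    return u, S, Q


def settle(
    u,
    S,
    Q,
    params: ModelParams,
    grid: RingGrid,
    kernel: Kernel,
    I_ext: Optional[np.ndarray],
    dt: float = 0.1,
    tol: float = 1e-7,
    t_cap: float = 12000.0,
    check_every: float = 100.0,
    alpha=None,
    beta=None,
):
    """Relax batched networks under a fixed input until stationarity.

    The residual is ``max(|du|*tau_s, |dS|*tau_1, |dQ|*tau_2)`` over all
    rows and nodes, i.e. each field's distance from its own equilibrium.
    Returns ``(u, S, Q, residual, elapsed_ms)``.
    """
    steps_per_check = max(1, int(round(check_every / dt)))
    elapsed = 0.0
    residual = np.inf
    fn = None if I_ext is None else (lambda t: I_ext)
    while elapsed < t_cap:
        u, S, Q = _advance(u, S, Q, params, grid, kernel, dt, steps_per_check,
                           input_fn=fn, alpha=alpha, beta=beta)
        elapsed += steps_per_check * dt
        du, dS, dQ = field_derivatives(u, S, Q, I_ext, params, grid, kernel, alpha, beta)
        residual = max(
            np.max(np.abs(du)) * params.tau_s,
            np.max(np.abs(dS)) * params.tau_1,
            np.max(np.abs(dQ)) * params.tau_2,
        )
        if not np.isfinite(residual):
            raise FloatingPointError(
                f"settling failed: non-finite fields after {elapsed} ms"
            )
        if residual < tol:
            break
    return u, S, Q, float(residual), elapsed


def run_tracking(
    u,
    S,
    Q,
    params: ModelParams,
    grid: RingGrid,
    kernel: Kernel,
    input_fn: Callable[[float], np.ndarray],
    dt: float = 0.1,
    t_max: float = 6000.0,
    sample_every: int = 10,
    alpha=None,
    beta=None,
):
    """Advance batched networks under a time-varying input, recording the
    bump centre.

    Returns ``(times, z_wrapped, (u, S, Q))`` where ``z_wrapped`` has
    shape ``(..., n_samples)``; sampling includes t=0 and the final step.
    """
    n_steps = int(round(t_max / dt))
    if n_steps % sample_every != 0:
        raise ValueError("t_max/dt must be a multiple of sample_every")
    n_samples = n_steps // sample_every + 1
    z = np.empty(np.shape(u)[:-1] + (n_samples,))
    z[..., 0] = center_of_mass(u, grid)
    for i in range(1, n_samples):
        t0 = (i - 1) * sample_every * dt
        u, S, Q = _advance(u, S, Q, params, grid, kernel, dt, sample_every,
                           t0=t0, input_fn=input_fn, alpha=alpha, beta=beta)
        zc = center_of_mass(u, grid)
        if not np.all(np.isfinite(zc)):
            raise FloatingPointError(
                f"tracking failed: non-finite centre at t = {i * sample_every * dt} ms"
            )
        z[..., i] = zc
    times = np.arange(n_samples) * sample_every * dt
    return times, z, (u, S, Q)


def run_free(
    u,
    S,
    Q,
    params: ModelParams,
    grid: RingGrid,
    kernel: Kernel,
    dt: float = 0.1,
    t_max: float = 1000.0,
    sample_every: int = 10,
    shift_period: Optional[float] = None,
    shift_nodes: int = 1,
    shift_modulations: bool = False,
    alpha=None,
    beta=None,
):
    """Input-free evolution, optionally with periodic manual shifts of
    ``u`` (the intrinsic-speed intervention).

    When ``shift_period`` is set, ``u`` is rolled by ``shift_nodes``
    grid nodes every ``shift_period`` ms (and ``S``/``Q`` too if
    ``shift_modulations``).  Returns ``(times, z_wrapped, (u, S, Q))``.
    """
    n_steps = int(round(t_max / dt))
    if n_steps % sample_every != 0:
        raise ValueError("t_max/dt must be a multiple of sample_every")
    if shift_period is not None:
        steps_per_shift = int(round(shift_period / dt))
        if steps_per_shift % sample_every != 0:
            raise ValueError("shift_period must be a multiple of the sampling stride")
    n_samples = n_steps // sample_every + 1
    z = np.empty(np.shape(u)[:-1] + (n_samples,))
    z[..., 0] = center_of_mass(u, grid)
    for i in range(1, n_samples):
        u, S, Q = _advance(u, S, Q, params, grid, kernel, dt, sample_every,
                           alpha=alpha, beta=beta)
        if shift_period is not None and (i * sample_every) % steps_per_shift == 0:
            u = np.roll(u, shift_nodes, axis=-1)
            if shift_modulations:
                S = np.roll(S, shift_nodes, axis=-1)
                Q = np.roll(Q, shift_nodes, axis=-1)
        z[..., i] = center_of_mass(u, grid)
    times = np.arange(n_samples) * sample_every * dt
    return times, z, (u, S, Q)
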