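"""Translational stability of stationary bump states.

A stationary bump of the input-free network can lose stability against
*positional* perturbations: a displaced state

``u = u0 + u1 du0/dx``, ``S = S0 + S1 (x - z) S0``, ``Q = Q0 + Q1 (x - z) Q0``

evolves, to linear order, as ``d/dt (u1, S1, Q1) = M (u1, S1, Q1)`` for a
3x3 matrix ``M`` whose leading eigenvalue real part (written
``lambda_max`` here) classifies the regime: positive means the bump
slides off spontaneously (the *moving* phase underlying intrinsic
motion), non-positive means it stays put (*static* phase).

``M`` is built by numerical linearisation: each displacement mode is
applied as a small perturbation, the exact right-hand side is
differenced centrally, and the response is projected back onto the mode
shapes with dx-weighted inner products.  Two couplings are structural
zeros (the ``u`` equation never reads ``Q``, the ``Q`` equation never
reads ``S``); they are asserted to vanish numerically and then zeroed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import CollapseError, Kernel, ModelParams, RingGrid, field_derivatives
from .protocols import SweepSpec
from .simulate import center_of_mass
from .model import periodic_distance

logger = logging.getLogger("cannstpp")

#: lambda_max above this counts as the moving phase (numerical tolerance
#: around the neutral translation mode of the continuous attractor)
MOVING_PHASE_TOL = 1e-7

#: numerically obtained structural-zero entries must not exceed this
STRUCTURAL_ZERO_TOL = 1e-8


@dataclass
class StationaryState:
    """Input-free fixed point of the field dynamics (bump centred at 0)."""

    u0: np.ndarray
    S0: np.ndarray
    Q0: np.ndarray
    z: float
    residual: float


@dataclass
class StabilityResult:
    """Displacement-mode matrix and its spectrum for one regime."""

    M: np.ndarray  # 3x3, mode order (u, S, Q)
    eigenvalues: np.ndarray  # three complex values
    lambda_max: float  # largest real part
    phase: str  # 'static' or 'moving'
    fd_error: float  # Richardson estimate of the finite-difference error


@dataclass
class StabilityMap:
    alpha_values: np.ndarray
    beta_values: np.ndarray
    lambda_max: np.ndarray  # (n_alpha, n_beta); NaN = failed cell
    phase: np.ndarray  # bool, True = moving
    failures: list = field(default_factory=list)


def _symmetrize(f: np.ndarray, grid: RingGrid) -> np.ndarray:
    return 0.5 * (f + grid.mirror(f))


def _solve_stationary_batch(
    params: ModelParams,
    grid: RingGrid,
    kernel: Kernel,
    alpha=None,
    beta=None,
    batch_shape=(),
    dt: float = 0.5,
    residual_tol: float = 1e-10,
    t_cap: float = 60000.0,
    check_every: float = 500.0,
    symmetrize_every: int = 5,
    init_amplitude: float = 10.0,
):
    """Relax to the symmetric input-free fixed point, batched.

    Symmetrising the fields about x = 0 every few steps projects out the
    (possibly unstable) translation mode, so the iteration converges to
    the static solution even in the moving phase.  Returns
    ``(u, S, Q, residual, collapsed)``.
    """
    x = grid.x
    u = init_amplitude * np.exp(-(x**2) / (4.0 * params.a**2))
    u = np.broadcast_to(u, batch_shape + u.shape).copy()
    S = np.zeros_like(u)
    Q = np.zeros_like(u)
    steps_per_check = int(round(check_every / dt))
    elapsed = 0.0
    residual = np.full(batch_shape, np.inf)
    collapsed = np.zeros(batch_shape, dtype=bool)
    while elapsed < t_cap:
        for step in range(steps_per_check):
            du, dS, dQ = field_derivatives(u, S, Q, None, params, grid, kernel,
                                           alpha, beta)
            u = u + dt * du
            S = S + dt * dS
            Q = Q + dt * dQ
            if step % symmetrize_every == 0:
                u = _symmetrize(u, grid)
                S = _symmetrize(S, grid)
                Q = _symmetrize(Q, grid)
        elapsed += steps_per_check * dt
        du, dS, dQ = field_derivatives(u, S, Q, None, params, grid, kernel,
                                       alpha, beta)
        residual = np.max(
            np.stack([np.abs(du), np.abs(dS), np.abs(dQ)]), axis=(0, -1)
        )
        collapsed = np.max(u, axis=-1) < 1e-3
        if np.all((residual < residual_tol) | collapsed):
            break
    return u, S, Q, residual, collapsed


def solve_stationary_state(
    params: ModelParams,
    grid: Optional[RingGrid] = None,
    kernel: Optional[Kernel] = None,
    dt: float = 0.5,
    residual_tol: float = 1e-10,
    t_cap: float = 60000.0,
) -> StationaryState:
    """Input-free stationary bump of the network.

    Raises :class:`~cannstpp.model.CollapseError` when no bump solution
    exists (the state decays to zero), and ``RuntimeError`` when the
    relaxation fails to reach ``residual_tol`` (max |d(field)/dt|).
    """
    if grid is None:
        grid = RingGrid()
    if kernel is None:
        kernel = Kernel(grid, params.a)
    u, S, Q, residual, collapsed = _solve_stationary_batch(
        params, grid, kernel, dt=dt, residual_tol=residual_tol, t_cap=t_cap,
    )
    if bool(collapsed):
        raise CollapseError(
            "no stationary bump: the activity collapsed to the zero state"
        )
    if float(residual) > residual_tol:
        raise RuntimeError(
            f"stationary solve did not converge: residual {float(residual):.2e} "
            f"> {residual_tol:.0e} after {t_cap} ms"
        )
    z = float(center_of_mass(u, grid))
    return StationaryState(u0=u, S0=S, Q0=Q, z=z, residual=float(residual))


def _spectral_ddx(f: np.ndarray, grid: RingGrid) -> np.ndarray:
    n = grid.n_points
    k_ang = 2.0 * math.pi * np.fft.rfftfreq(n, d=grid.dx)
    return np.fft.irfft(np.fft.rfft(f, axis=-1) * (1j * k_ang), n=n, axis=-1)


def _mode_matrix_at_eps(
    st: StationaryState,
    params: ModelParams,
    grid: RingGrid,
    kernel: Kernel,
    modes,
    norms,
    present,
    eps_rel: float,
):
    p = params
    fields0 = [st.u0, st.S0, st.Q0]
    scales = [max(np.max(np.abs(f)), 1.0) for f in fields0]
    leak = [1.0 / p.tau_s, 1.0 / p.tau_1, 1.0 / p.tau_2]
    dx = grid.dx
    M = np.zeros((3, 3))
    for j in range(3):
        if not present[j]:
            M[j, j] = -leak[j]
            continue
        eps = eps_rel * scales[j] / max(np.max(np.abs(modes[j])), 1e-30)
        plus = [f.copy() for f in fields0]
        minus = [f.copy() for f in fields0]
        plus[j] = plus[j] + eps * modes[j]
        minus[j] = minus[j] - eps * modes[j]
        dp = field_derivatives(plus[0], plus[1], plus[2], None, p, grid, kernel)
        dm = field_derivatives(minus[0], minus[1], minus[2], None, p, grid, kernel)
        for i in range(3):
            if not present[i]:
                continue
            response = (dp[i] - dm[i]) / (2.0 * eps)
            M[i, j] = dx * float(np.dot(modes[i], response)) / norms[i]
    return M


def build_mode_matrix(
    st: StationaryState,
    params: ModelParams,
    grid: Optional[RingGrid] = None,
    kernel: Optional[Kernel] = None,
    eps_rel: float = 1e-3,
) -> StabilityResult:
    """3x3 displacement-mode matrix of a stationary state.

    Mode shapes: ``du0/dx`` for u (spectral derivative), ``(x - z) S0``
    for S and ``(x - z) Q0`` for Q.  The perturbation amplitude is
    validated by a two-point Richardson check (the matrix is recomputed
    at half the amplitude; the difference is reported as ``fd_error``
    and the half-amplitude matrix is returned).

    Without plasticity (``S0 = Q0 = 0``) the S and Q displacement modes
    do not exist; their diagonal entries are set to the bare leak rates,
    which keeps the spectrum's leading element the (neutral) translation
    mode.
    """
    if grid is None:
        grid = RingGrid()
    if kernel is None:
        kernel = Kernel(grid, params.a)
    dx = grid.dx
    offset = periodic_distance(grid.x, st.z)
    modes = [
        _spectral_ddx(st.u0, grid),
        offset * st.S0,
        offset * st.Q0,
    ]
    norms = [dx * float(np.dot(m, m)) for m in modes]
    if norms[0] < 1e-20:
        raise ValueError("degenerate bump: translation mode has near-zero norm")
    present = [True, norms[1] > 1e-20, norms[2] > 1e-20]

    M1 = _mode_matrix_at_eps(st, params, grid, kernel, modes, norms, present, eps_rel)
    M2 = _mode_matrix_at_eps(st, params, grid, kernel, modes, norms, present, eps_rel / 2.0)
    fd_error = float(np.max(np.abs(M1 - M2)))
    M = M2

    # structural zeros: du/dt never reads Q, dQ/dt never reads S
    for (i, j) in ((0, 2), (2, 1)):
        if abs(M[i, j]) > STRUCTURAL_ZERO_TOL:
            raise AssertionError(
                f"structural zero M[{i},{j}] = {M[i, j]:.3e} exceeds "
                f"{STRUCTURAL_ZERO_TOL}"
            )
        M[i, j] = 0.0

    eigenvalues = np.linalg.eigvals(M)
    lambda_max = float(np.max(eigenvalues.real))
    phase = "moving" if lambda_max > MOVING_PHASE_TOL else "static"
    return StabilityResult(M=M, eigenvalues=eigenvalues, lambda_max=lambda_max,
                           phase=phase, fd_error=fd_error)


def analyze_regime(
    params: ModelParams,
    grid: Optional[RingGrid] = None,
    kernel: Optional[Kernel] = None,
    **solve_kwargs,
) -> StabilityResult:
    """Stationary solve plus mode-matrix analysis for one regime."""
    if grid is None:
        grid = RingGrid()
    if kernel is None:
        kernel = Kernel(grid, params.a)
    st = solve_stationary_state(params, grid, kernel, **solve_kwargs)
    return build_mode_matrix(st, params, grid, kernel)


def classify_phase_map(
    sweep: SweepSpec,
    params: Optional[ModelParams] = None,
    grid: Optional[RingGrid] = None,
    dt: float = 0.5,
    residual_tol: float = 1e-10,
) -> StabilityMap:
    """lambda_max and static/moving labels over the (alpha, beta) grid.

    The stationary states of all cells are relaxed as one batch; the
    mode matrices are then built per cell.  Per-cell failures are
    recorded in ``failures`` and leave NaN in the map."""
    if params is None:
        params = ModelParams()
    if grid is None:
        grid = RingGrid()
    kernel = Kernel(grid, params.a)
    alphas = np.asarray(sweep.alpha_values)
    betas = np.asarray(sweep.beta_values)
    AA, BB = np.meshgrid(alphas, betas, indexing="ij")
    a_col = AA.ravel()[:, None]
    b_col = BB.ravel()[:, None]
    n_cells = a_col.shape[0]
    u, S, Q, residual, collapsed = _solve_stationary_batch(
        params, grid, kernel, alpha=a_col, beta=b_col,
        batch_shape=(n_cells,), dt=dt, residual_tol=residual_tol,
    )
    lam = np.full(n_cells, np.nan)
    moving = np.zeros(n_cells, dtype=bool)
    failures = []
    for c in range(n_cells):
        cell = (float(a_col[c, 0]), float(b_col[c, 0]))
        if collapsed[c]:
            failures.append((cell, "collapse"))
            continue
        if residual[c] > residual_tol:
            failures.append((cell, f"residual {residual[c]:.2e}"))
            continue
        p_cell = params.replace(alpha=cell[0], beta=cell[1])
        st = StationaryState(u0=u[c], S0=S[c], Q0=Q[c],
                             z=float(center_of_mass(u[c], grid)),
                             residual=float(residual[c]))
        try:
            res = build_mode_matrix(st, p_cell, grid, kernel)
        except (AssertionError, ValueError) as err:
            failures.append((cell, str(err)))
            continue
        lam[c] = res.lambda_max
        moving[c] = res.phase == "moving"
    shape = (alphas.size, betas.size)
    return StabilityMap(alpha_values=alphas, beta_values=betas,
                        lambda_max=lam.reshape(shape),
                        phase=moving.reshape(shape), failures=failures)
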