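"""Core definitions of the ring attractor network with NMDAR-based STPP.

The model describes a population of neurons tuned to a periodic feature
(the canonical example being head direction), coupled through
translation-invariant Gaussian excitation and global divisive inhibition.
On top of the classical continuous attractor dynamics of the synaptic
input ``u(x, t)``, two fields implement short-term *postsynaptic*
plasticity (STPP) of NMDA receptors:

``Q(x, t)``
    the proportion of receptors in the glutamate-bound-but-magnesium-
    blocked ("primed") state.  It is charged by moderate total input and
    drained both by leak (time constant ``tau_2``) and by receptor
    opening.

``S(x, t)``
    the transient gain produced when primed receptors open, which decays
    with time constant ``tau_1``.  The synaptic drive of the network is
    ``(1 + S) * I_tot`` instead of ``I_tot``.

The coupled dynamics are::

    tau_s du/dt = -u + (1 + S) * I_tot
         dS/dt = -S/tau_1 + alpha * Q * f_S(r)
         dQ/dt = -Q/tau_2 - alpha * Q * f_S(r) + beta * (1 - Q) * f_Q(I_tot)

where ``r`` is the divisively normalised firing rate, ``f_S`` a normal
CDF of the rate (a proxy for the magnesium-removal efficacy of the
membrane potential) and ``f_Q`` a log-normal density of the total input
(priming requires moderate, not maximal, drive).

Conventions: time is in milliseconds, angles in radians, and the feature
space is the ring (-pi, pi].  All field operations broadcast over leading
batch axes, so a whole parameter sweep can be integrated as one array.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Optional

import numpy as np
from scipy.special import ndtr

TWO_PI = 2.0 * math.pi
SQRT_TWO_PI = math.sqrt(TWO_PI)

#: multiply a speed in rad/ms by this to obtain deg/s
RAD_PER_MS_TO_DEG_PER_S = 180000.0 / math.pi


class CollapseError(RuntimeError):
    """The activity bump decayed to the trivial zero state."""


def _require_positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be strictly positive, got {value!r}")


def _require_nonnegative(name: str, value: float) -> None:
    if value < 0:
        raise ValueError(f"{name} must be non-negative, got {value!r}")


@dataclass(frozen=True)
class ModelParams:
    """Scalar constants of the network and plasticity dynamics.

    Parameters
    ----------
    tau_s : float
        Neuronal (synaptic input) time constant, ms.
    tau_1 : float
        Decay time constant of the enhancing modulation ``S``, ms.
    tau_2 : float
        Decay time constant of the latent (primed) modulation ``Q``, ms.
    a : float
        Range of the excitatory interaction in feature space, rad.
    k : float
        Strength of the global divisive inhibition (dimensionless).
    alpha : float
        Opening rate of primed receptors; drives ``S`` at the expense of
        ``Q``.
    beta : float
        Priming rate (transition into the bound-but-blocked state);
        charges ``Q``.
    r0, sigma_S : float
        Location and scale of the normal CDF ``f_S`` in firing-rate
        units.
    mu_Q, sigma_Q : float
        Location and scale (on the natural-log axis of total input) of
        the log-normal density ``f_Q``.
    """

    tau_s: float = 10.0
    tau_1: float = 50.0
    tau_2: float = 500.0
    a: float = 0.5
    k: float = 0.5
    alpha: float = 0.0
    beta: float = 0.0
    r0: float = 6.0
    sigma_S: float = 2.0
    mu_Q: float = 0.25
    sigma_Q: float = 0.5

    def __post_init__(self) -> None:
        for name in ("tau_s", "tau_1", "tau_2", "a", "sigma_S", "sigma_Q", "k"):
            _require_positive(name, getattr(self, name))
        for name in ("alpha", "beta"):
            _require_nonnegative(name, getattr(self, name))

    def replace(self, **changes) -> "ModelParams":
        d = self.to_dict()
        d.update(changes)
        return ModelParams(**d)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(
                f"unknown key(s) in model section: {sorted(unknown)}"
            )
        return cls(**d)


@dataclass(frozen=True)
class RingGrid:
    """Uniform discretisation of the ring (-pi, pi].

    Nodes sit at ``x_i = -pi + (i + 1) * dx`` for ``i = 0 .. n_points-1``
    with ``dx = 2*pi / n_points``, so the last node is exactly ``pi`` and
    (for even ``n_points``) one node is exactly ``0``.
    """

    n_points: int = 200
    x: np.ndarray = field(init=False, repr=False, compare=False)
    dx: float = field(init=False)

    def __post_init__(self) -> None:
        if self.n_points < 4:
            raise ValueError(f"n_points must be >= 4, got {self.n_points}")
        dx = TWO_PI / self.n_points
        x = -math.pi + dx * np.arange(1, self.n_points + 1)
        x.setflags(write=False)
        object.__setattr__(self, "dx", dx)
        object.__setattr__(self, "x", x)

    @property
    def mirror_index(self) -> np.ndarray:
        """Index permutation mapping a field f(x) to f(-x) on the grid."""
        n = self.n_points
        return np.concatenate([np.arange(n - 2, -1, -1), [n - 1]])

    def mirror(self, f: np.ndarray) -> np.ndarray:
        """Reflect a field about x = 0 (the node at pi maps to itself)."""
        return f[..., self.mirror_index]


@dataclass
class NetworkState:
    """The three fields of the network at one instant."""

    u: np.ndarray
    S: np.ndarray
    Q: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        if not (self.u.shape == self.S.shape == self.Q.shape):
            raise ValueError(
                "u, S, Q must share a shape; got "
                f"{self.u.shape}, {self.S.shape}, {self.Q.shape}"
            )

    @classmethod
    def zeros(cls, grid: RingGrid, t: float = 0.0) -> "NetworkState":
        n = grid.n_points
        return cls(np.zeros(n), np.zeros(n), np.zeros(n), t)

    def copy(self) -> "NetworkState":
        return NetworkState(self.u.copy(), self.S.copy(), self.Q.copy(), self.t)


_STIM_MODES = ("static", "abrupt", "moving", "off")


@dataclass(frozen=True)
class StimulusSpec:
    """External Gaussian input: magnitude and position trajectory.

    ``I_ext(x, t) = A * exp(-dist(x, z0(t))^2 / (4 a^2))`` where the
    centre ``z0(t)`` depends on ``mode``:

    - ``static``: fixed at ``z0_initial``;
    - ``abrupt``: ``z0_initial`` before ``t_jump``, ``z0_after`` from then on;
    - ``moving``: ``z0_initial + v_ext * t``;
    - ``off``: the input field is identically zero.
    """

    A: float = 3.0
    z0_initial: float = 0.0
    v_ext: float = 0.0
    mode: str = "static"
    z0_after: Optional[float] = None
    t_jump: Optional[float] = None

    def __post_init__(self) -> None:
        _require_nonnegative("A", self.A)
        if self.mode not in _STIM_MODES:
            raise ValueError(
                f"mode must be one of {_STIM_MODES}, got {self.mode!r}"
            )
        if self.mode == "abrupt":
            if self.z0_after is None or self.t_jump is None:
                raise ValueError("abrupt mode requires z0_after and t_jump")
        object.__setattr__(self, "z0_initial", wrap_angle(self.z0_initial))
        if self.z0_after is not None:
            object.__setattr__(self, "z0_after", wrap_angle(self.z0_after))

    def position(self, t: float) -> float:
        """Stimulus centre at time ``t`` (unwrapped for moving mode)."""
        if self.mode == "moving":
            return self.z0_initial + self.v_ext * t
        if self.mode == "abrupt" and t >= self.t_jump:
            return self.z0_after
        return self.z0_initial

    def to_dict(self) -> dict:
        return {
            "A": self.A,
            "z0_initial": self.z0_initial,
            "v_ext": self.v_ext,
            "mode": self.mode,
            "z0_after": self.z0_after,
            "t_jump": self.t_jump,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusSpec":
        known = {"A", "z0_initial", "v_ext", "mode", "z0_after", "t_jump"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(
                f"unknown key(s) in stimulus section: {sorted(unknown)}"
            )
        return cls(**d)


def wrap_angle(x):
    """Wrap angles into (-pi, pi]."""
    w = np.pi - np.mod(np.pi - np.asarray(x, dtype=float), TWO_PI)
    if np.ndim(w) == 0:
        return float(w)
    return w


def periodic_distance(x, x_prime):
    """Signed distance x - x' on the ring, wrapped into (-pi, pi].

    Total function; inputs need not be pre-wrapped.  Broadcasts.
    """
    d = np.mod(np.asarray(x, dtype=float) - x_prime, TWO_PI)
    d = np.where(d > np.pi, d - TWO_PI, d)
    if np.ndim(d) == 0:
        return float(d)
    return d


class Kernel:
    """Translation-invariant Gaussian excitatory coupling on the grid.

    ``J(x, x') = exp(-dist(x, x')^2 / (2 a^2)) / (sqrt(2 pi) a)``

    Lateral input is the ring integral ``int J(x, x') r(x') dx'``,
    evaluated either as a circulant matrix-vector product or (the
    default fast path) as an FFT circular convolution; the two are
    equal to round-off.
    """

    def __init__(self, grid: RingGrid, a: float):
        _require_positive("a", a)
        self.grid = grid
        self.a = a
        # kernel profile as a function of node offset m: J(m * dx)
        offsets = periodic_distance(grid.dx * np.arange(grid.n_points), 0.0)
        self.profile = np.exp(-offsets**2 / (2.0 * a * a)) / (SQRT_TWO_PI * a)
        self._fft = np.fft.rfft(self.profile)
        self._dx = grid.dx

    @property
    def matrix(self) -> np.ndarray:
        """Dense (n, n) coupling matrix J[i, j] = J(x_i, x_j)."""
        idx = np.arange(self.grid.n_points)
        return self.profile[(idx[:, None] - idx[None, :]) % self.grid.n_points]

    def apply(self, r: np.ndarray) -> np.ndarray:
        """dx-weighted lateral input ``int J(x, x') r(x') dx'``."""
        n = self.grid.n_points
        return np.fft.irfft(np.fft.rfft(r, axis=-1) * self._fft, n=n, axis=-1) * self._dx

    def apply_dense(self, r: np.ndarray) -> np.ndarray:
        """Reference circulant matrix-vector evaluation (same result)."""
        return r @ self.matrix.T * self._dx


def connection_kernel(grid: RingGrid, a: float) -> np.ndarray:
    """Dense excitatory coupling matrix (see :class:`Kernel`)."""
    return Kernel(grid, a).matrix


def firing_rate(u: np.ndarray, grid: RingGrid, k: float, a: float) -> np.ndarray:
    """Divisively normalised firing rate.

    ``r = H(u) u^2 / (1 + k/(8 sqrt(2 pi) a) * int u^2 dx)`` where the
    Heaviside step gates the numerator only; the normalising integral
    runs over all nodes regardless of the sign of ``u``.
    """
    u = np.asarray(u, dtype=float)
    coeff = k / (8.0 * SQRT_TWO_PI * a)
    denom = 1.0 + coeff * np.sum(u * u, axis=-1, keepdims=True) * grid.dx
    with np.errstate(invalid="ignore"):  # non-finite u propagates as NaN
        return np.where(u > 0.0, u * u, 0.0) / denom


def gating_activation(r: np.ndarray, r0: float, sigma_S: float) -> np.ndarray:
    """Normal CDF of the firing rate; drives the opening of primed
    receptors (magnesium-removal efficacy), values in [0, 1]."""
    _require_positive("sigma_S", sigma_S)
    return ndtr((np.asarray(r, dtype=float) - r0) / sigma_S)


def priming_activation(I_tot: np.ndarray, mu_Q: float, sigma_Q: float) -> np.ndarray:
    """Log-normal density of the total input; drives priming.

    Zero for non-positive input (insufficient drive cannot prime the
    receptors, and the density is undefined there anyway).
    """
    _require_positive("sigma_Q", sigma_Q)
    I = np.asarray(I_tot, dtype=float)
    # Evaluate in log space; clipping non-positive input to a tiny value
    # drives the exponent to -inf, i.e. the returned density to exactly 0.
    logI = np.log(np.maximum(I, 1e-300))
    out = np.exp(-((logI - mu_Q) ** 2) / (2.0 * sigma_Q**2) - logI) / (
        sigma_Q * SQRT_TWO_PI
    )
    return np.where(I > 0.0, out, 0.0)


def external_input(
    grid: RingGrid, stim: StimulusSpec, t: float, a: float = 0.5
) -> np.ndarray:
    """External Gaussian input field at time ``t`` (zero for mode 'off').

    ``a`` is the interaction range of the model; the stimulus shares it.
    """
    if stim.mode == "off" or stim.A == 0.0:
        return np.zeros(grid.n_points)
    z0 = stim.position(t)
    return gaussian_input(grid, stim.A, z0, a)


def gaussian_input(grid: RingGrid, A, z0, a: float = 0.5) -> np.ndarray:
    """``A * exp(-dist(x, z0)^2 / (4 a^2))`` centred at ``z0``.

    ``z0`` (and ``A``) may carry leading batch axes with a trailing
    singleton, e.g. shape (B, 1), producing a (B, n_points) field.
    """
    d = periodic_distance(grid.x, z0)
    return np.asarray(A) * np.exp(-np.asarray(d) ** 2 / (4.0 * a * a))


def total_input(
    r: np.ndarray, kernel: Kernel, I_ext: Optional[np.ndarray] = None
) -> np.ndarray:
    """Total input: lateral excitation plus external drive."""
    I = kernel.apply(r)
    if I_ext is not None:
        if np.shape(I_ext)[-1] != np.shape(I)[-1]:
            raise ValueError(
                f"I_ext length {np.shape(I_ext)[-1]} does not match grid "
                f"size {np.shape(I)[-1]}"
            )
        I = I + I_ext
    return I


def field_derivatives(
    u: np.ndarray,
    S: np.ndarray,
    Q: np.ndarray,
    I_ext: Optional[np.ndarray],
    params: ModelParams,
    grid: RingGrid,
    kernel: Kernel,
    alpha=None,
    beta=None,
):
    """Right-hand sides (du/dt, dS/dt, dQ/dt) of the coupled dynamics.

    Pure function of its arguments.  ``alpha``/``beta`` may be arrays
    broadcastable against the fields, which lets a parameter sweep share
    one vectorised integration.
    """
    p = params
    if alpha is None:
        alpha = p.alpha
    if beta is None:
        beta = p.beta
    r = firing_rate(u, grid, p.k, p.a)
    I_tot = total_input(r, kernel, I_ext)
    fs = gating_activation(r, p.r0, p.sigma_S)
    fq = priming_activation(I_tot, p.mu_Q, p.sigma_Q)
    open_flux = alpha * Q * fs
    du = (-u + (1.0 + S) * I_tot) / p.tau_s
    dS = -S / p.tau_1 + open_flux
    dQ = -Q / p.tau_2 - open_flux + beta * (1.0 - Q) * fq
    return du, dS, dQ


def dynamics_rhs(
    state: NetworkState,
    params: ModelParams,
    stim: StimulusSpec,
    grid: RingGrid,
    kernel: Optional[Kernel] = None,
):
    """Time derivatives of a :class:`NetworkState` under a stimulus."""
    if kernel is None:
        kernel = Kernel(grid, params.a)
    I_ext = external_input(grid, stim, state.t, params.a)
    du, dS, dQ = field_derivatives(
        state.u, state.S, state.Q, I_ext, params, grid, kernel
    )
    if not (np.all(np.isfinite(du)) and np.all(np.isfinite(dS)) and np.all(np.isfinite(dQ))):
        raise FloatingPointError(
            f"non-finite field derivative at t = {state.t} ms"
        )
    return du, dS, dQ
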