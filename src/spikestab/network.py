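"""Noisy population dynamics with Naka-Rushton gains and phase-model spiking.

The model is a small network (2 or 3 nodes) of neural populations whose
activities ``x_i`` (dimensionless, 1.0 = maximal) obey

    tau * dx_i/dt = -x_i + sum_j w_ij * S_ij(x_j) + b_i

where ``tau = 20 ms``, ``w_ij`` is +1/-1/0 (excitatory / inhibitory /
absent connection from population ``j`` to population ``i``), ``b_i`` an
optional constant drive, and ``S_ij`` a first-order Naka-Rushton gain

    S(x) = clip(B + c * x / (theta + x), 0, 1)

with maximum effect ``c``, offset ``B`` and half-saturation ``theta``.
Fluctuations are injected as independent Gaussian perturbations (sd
``sigma``) added to each gain output, redrawn once per integration step of
the classical 4th-order Runge-Kutta scheme (dt = 0.05 ms) and held fixed
through the four stages, which keeps the effective noise dt-consistent and
bit-reproducible from a seed.

Spikes are read out by a phase neuron attached to a node: the population
activity sets the phase velocity, ``tau' * dphi/dt = 2*pi*x``, with
``tau' = 50 ms``, and a spike is emitted whenever the phase crosses an
integer multiple of 2*pi.  Constant activity ``x`` therefore fires at
``x / tau'``: maximal activity corresponds to 20 spikes/s.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .spike_metrics import SpikeTrain

DEFAULT_TAU_MS = 20.0
DEFAULT_DT_MS = 0.05
DEFAULT_STEPS = 60_000
DEFAULT_TAU_PRIME_MS = 50.0
ACTIVITY_BOUND = 10.0

__all__ = [
    "GainFunction",
    "NetworkSpec",
    "Trajectory",
    "PhaseNeuronConfig",
    "NumericalInstabilityError",
    "naka_rushton",
    "simulate",
    "simulate_ensemble",
    "generate_spikes",
]


class NumericalInstabilityError(RuntimeError):
    """Raised when an activity leaves the safety bound |x| <= 10."""


@dataclass(frozen=True)
class GainFunction:
    """First-order Naka-Rushton gain, output limited to [0, 1].

    ``c`` is the maximum effect of input, ``B`` the offset and ``theta`` the
    input at which the unclipped gain rises half way to its maximum effect.
    Negative inputs (transients below rest) are treated as zero drive.
    """

    c: float
    B: float = 0.0
    theta: float = 0.5

    def __post_init__(self) -> None:
        if not self.theta > 0:
            raise ValueError("theta must be positive")

    def __call__(self, x):
        return naka_rushton(x, self)

    def unclipped(self, x):
        x = np.maximum(np.asarray(x, dtype=float), 0.0)
        return self.B + self.c * x / (self.theta + x)

    def deriv(self, x):
        """Derivative of the unclipped branch, c*theta/(theta+x)^2."""
        x = np.maximum(np.asarray(x, dtype=float), 0.0)
        return self.c * self.theta / (self.theta + x) ** 2

    def is_clipped_at(self, x: float, tol: float = 1e-12) -> bool:
        u = float(self.unclipped(x))
        return u <= tol or u >= 1.0 - tol


def naka_rushton(x, g: GainFunction):
    """Evaluate ``clip(B + c*x/(theta+x), 0, 1)``; monotone in x for c > 0."""
    return np.clip(g.unclipped(x), 0.0, 1.0)


@dataclass(frozen=True)
class NetworkSpec:
    """A 2- or 3-node population network.

    ``weights[i, j]`` is the signed connectivity from node ``j`` to node
    ``i`` (+1 excitatory, -1 inhibitory, 0 absent; no self-edges) and
    ``gains[(i, j)]`` the gain function on that edge.  ``bias`` is a
    constant per-node drive (needed e.g. to keep activities positive in
    inhibition-dominated networks).
    """

    weights: np.ndarray
    gains: dict[tuple[int, int], GainFunction]
    tau: float = DEFAULT_TAU_MS
    sigma: float = 0.025
    bias: np.ndarray | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        n = w.shape[0]
        if w.shape != (n, n) or n not in (2, 3):
            raise ValueError("weights must be an n x n matrix with n in {2, 3}")
        if np.any(np.diag(w) != 0):
            raise ValueError("no self-edges allowed")
        if not set(np.unique(w)) <= {-1.0, 0.0, 1.0}:
            raise ValueError("weights must be in {-1, 0, +1}")
        if not self.tau > 0:
            raise ValueError("tau must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        bias = np.zeros(n) if self.bias is None else np.asarray(self.bias, dtype=float)
        if bias.shape != (n,):
            raise ValueError("bias must have one entry per node")
        object.__setattr__(self, "bias", bias)
        edges = {(i, j) for i in range(n) for j in range(n) if w[i, j] != 0}
        if set(self.gains) != edges:
            raise ValueError("gains must be given exactly on the non-zero edges")
        order = sorted(edges)
        object.__setattr__(self, "_edge_arrays", tuple(
            np.array(v, dtype=t)
            for v, t in (
                ([i for i, _ in order], np.int64),
                ([j for _, j in order], np.int64),
                ([w[i, j] for i, j in order], np.float64),
                ([self.gains[e].c for e in order], np.float64),
                ([self.gains[e].B for e in order], np.float64),
                ([self.gains[e].theta for e in order], np.float64),
            )
        ))

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    @property
    def edges(self) -> list[tuple[int, int]]:
        return sorted(self.gains)

    def with_sigma(self, sigma: float) -> "NetworkSpec":
        return replace(self, sigma=sigma)

    def drift(self, x: np.ndarray, gain_noise: np.ndarray | None = None) -> np.ndarray:
        """Deterministic field (plus frozen gain noise), shape-preserving.

        ``x`` has shape (..., n); ``gain_noise`` (if given) has one entry
        per edge in ``self.edges`` order, shape (..., n_edges).
        """
        x = np.asarray(x, dtype=float)
        drive = np.broadcast_to(self.bias, x.shape).copy()
        for k, (i, j) in enumerate(self.edges):
            s = naka_rushton(x[..., j], self.gains[(i, j)])
            if gain_noise is not None:
                s = s + gain_noise[..., k]
            drive[..., i] += self.weights[i, j] * s
        return (-x + drive) / self.tau


@dataclass(frozen=True)
class Trajectory:
    """One integrated run: uniform time grid (ms) and activities (steps+1, n)."""

    t: np.ndarray
    x: np.ndarray
    dt: float
    seed: int | None = None

    @property
    def duration_ms(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass(frozen=True)
class PhaseNeuronConfig:
    tau_prime: float = DEFAULT_TAU_PRIME_MS
    phi0: float = 0.0

    def __post_init__(self) -> None:
        if not self.tau_prime > 0:
            raise ValueError("tau_prime must be positive")


@njit(cache=False)
def _rk4_chunk(x, out, out_offset, noise, dt, tau, bias,
               idx_i, idx_j, w, c, B, th, bound):  # pragma: no cover - jitted
    """Advance ``x`` (m, n) through ``noise.shape[0]`` RK4 steps in place.

    ``noise`` has shape (steps, m, n_edges); the per-step perturbation of
    each gain output is frozen through the four stages.  Writes states into
    ``out[out_offset + k + 1]``.  Returns the 1-based step index at which
    an activity left ``|x| <= bound`` (0 when none did).
    """
    steps = noise.shape[0]
    m, n = x.shape
    n_edges = idx_i.size
    k1 = np.empty((m, n))
    k2 = np.empty((m, n))
    k3 = np.empty((m, n))
    k4 = np.empty((m, n))
    xs = np.empty((m, n))
    for step in range(steps):
        for stage in range(4):
            if stage == 0:
                for a in range(m):
                    for b in range(n):
                        xs[a, b] = x[a, b]
            elif stage == 1:
                for a in range(m):
                    for b in range(n):
                        xs[a, b] = x[a, b] + 0.5 * dt * k1[a, b]
            elif stage == 2:
                for a in range(m):
                    for b in range(n):
                        xs[a, b] = x[a, b] + 0.5 * dt * k2[a, b]
            else:
                for a in range(m):
                    for b in range(n):
                        xs[a, b] = x[a, b] + dt * k3[a, b]
            kk = k1 if stage == 0 else (k2 if stage == 1 else (k3 if stage == 2 else k4))
            for a in range(m):
                for b in range(n):
                    kk[a, b] = (-xs[a, b] + bias[b]) / tau
            for e in range(n_edges):
                i = idx_i[e]
                j = idx_j[e]
                for a in range(m):
                    xj = xs[a, j]
                    if xj < 0.0:
                        xj = 0.0
                    s = B[e] + c[e] * xj / (th[e] + xj)
                    if s < 0.0:
                        s = 0.0
                    elif s > 1.0:
                        s = 1.0
                    kk[a, i] += w[e] * (s + noise[step, a, e]) / tau
        for a in range(m):
            for b in range(n):
                x[a, b] += (dt / 6.0) * (
                    k1[a, b] + 2.0 * k2[a, b] + 2.0 * k3[a, b] + k4[a, b]
                )
                out[out_offset + step + 1, a, b] = x[a, b]
                if abs(x[a, b]) > bound:
                    return out_offset + step + 1
    return 0


_NOISE_CHUNK = 10_000  # steps of pre-drawn noise per kernel call (bounds memory)


def _integrate(
    net: NetworkSpec,
    x0: np.ndarray,
    steps: int,
    dt: float,
    rng: np.random.Generator | None,
) -> np.ndarray:
    """Classical RK4 with per-step frozen gain noise; returns (steps+1, m, n)."""
    x0 = np.atleast_2d(np.asarray(x0, dtype=float))
    m, n = x0.shape
    idx_i, idx_j, w, c, B, th = net._edge_arrays
    out = np.empty((steps + 1, m, n))
    out[0] = x = x0.copy()
    noisy = net.sigma > 0 and rng is not None
    done = 0
    while done < steps:
        chunk = min(_NOISE_CHUNK, steps - done)
        if noisy:
            noise = rng.normal(0.0, net.sigma, size=(chunk, m, idx_i.size))
        else:
            noise = np.zeros((chunk, m, idx_i.size))
        bad = _rk4_chunk(x, out, done, noise, dt, net.tau, net.bias,
                         idx_i, idx_j, w, c, B, th, ACTIVITY_BOUND)
        if bad:
            raise NumericalInstabilityError(
                f"activity exceeded |x| = {ACTIVITY_BOUND} at step {bad}; "
                f"check gain parameters (tau={net.tau}, sigma={net.sigma})"
            )
        done += chunk
    return out


def simulate(
    net: NetworkSpec,
    steps: int = DEFAULT_STEPS,
    seed: int | None = None,
    x0: np.ndarray | None = None,
    dt: float = DEFAULT_DT_MS,
) -> Trajectory:
    """Integrate one noisy trajectory; bit-reproducible from ``seed``.

    ``x0`` defaults to the zero state.  Noise is only drawn when
    ``net.sigma > 0``; passing ``seed=None`` with a noisy network draws
    from fresh OS entropy (not reproducible).
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    rng = np.random.default_rng(seed)
    start = np.zeros(net.n) if x0 is None else np.asarray(x0, dtype=float)
    xs = _integrate(net, start[None, :], steps, dt, rng)[:, 0, :]
    t = np.arange(steps + 1) * dt
    return Trajectory(t=t, x=xs, dt=dt, seed=seed)


def simulate_ensemble(
    net: NetworkSpec,
    repeats: int,
    steps: int = DEFAULT_STEPS,
    seed: int | None = None,
    x0: np.ndarray | None = None,
    dt: float = DEFAULT_DT_MS,
) -> list[Trajectory]:
    """``repeats`` independent runs, vectorised over the ensemble.

    Noise streams across repeats are independent but jointly reproducible
    from ``seed``.  All runs share ``x0``.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    rng = np.random.default_rng(seed)
    start = np.zeros(net.n) if x0 is None else np.asarray(x0, dtype=float)
    x0s = np.tile(start, (repeats, 1))
    xs = _integrate(net, x0s, steps, dt, rng)
    t = np.arange(steps + 1) * dt
    return [Trajectory(t=t, x=xs[:, r, :], dt=dt, seed=seed) for r in range(repeats)]


def generate_spikes(
    traj: Trajectory,
    cfg: PhaseNeuronConfig = PhaseNeuronConfig(),
    node: int = 0,
    neuron_id: str = "",
    trial_id: str = "",
) -> SpikeTrain:
    """Phase-model spike readout of one node of a trajectory.

    Integrates ``tau' * dphi/dt = 2*pi*max(x, 0)`` (the phase never
    decreases) by the trapezoid rule on the trajectory grid and emits a
    spike at each crossing of an integer multiple of 2*pi, with the
    crossing time located by linear interpolation inside the step.
    """
    x = np.maximum(traj.x[:, node], 0.0)
    if x.size < 2:
        raise ValueError("trajectory must contain at least two samples")
    # phase in units of full cycles: d(phi/2pi)/dt = x / tau'
    incr = 0.5 * (x[:-1] + x[1:]) * traj.dt / cfg.tau_prime
    cycles = cfg.phi0 / (2.0 * np.pi) + np.concatenate(([0.0], np.cumsum(incr)))
    first = int(np.floor(cycles[0])) + 1
    last = int(np.floor(cycles[-1] * (1.0 + 1e-12) + 1e-9))
    if last < first:
        times = np.empty(0)
    else:
        targets = np.arange(first, last + 1, dtype=float)
        idx = np.searchsorted(cycles, targets, side="left")
        idx = np.clip(idx, 1, cycles.size - 1)
        c0 = cycles[idx - 1]
        c1 = cycles[idx]
        frac = np.where(c1 > c0, (targets - c0) / np.maximum(c1 - c0, 1e-300), 1.0)
        times = traj.t[idx - 1] + frac * traj.dt
        times = np.minimum(times, traj.t[-1])
        # strictly increasing guard against degenerate flat segments
        keep = np.concatenate(([True], np.diff(times) > 0))
        times = times[keep]
    return SpikeTrain(
        times=times,
        t0=float(traj.t[0]),
        t1=float(traj.t[-1]) + traj.dt,
        neuron_id=neuron_id,
        trial_id=trial_id,
    )
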