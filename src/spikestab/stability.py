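"""Fixed points and attractor-stability indices: MLE and stiffness.

A point attractor of the population dynamics is a root of the noise-free
field where all eigenvalues of the Jacobian have negative real part.  Two
scalar stability indices are computed for each fixed point:

maximum Lyapunov exponent (MLE)
    The maximum real part of the Jacobian eigenvalues.  For a 2-node
    network with effective couplings ``eta_ij = w_ij * S'_ij(x*_j)`` the
    eigenvalues are ``(-1 +/- sqrt(eta12*eta21)) / tau``, so for any
    excitation-inhibition pairing (``eta12*eta21 < 0``) the square root is
    imaginary and the MLE sits constant at ``-1/tau``: the MLE is blind to
    the stability changes of oscillatory (complex-eigenvalue) attractors.

stiffness
    ``s = prod_i(-lambda_i) = det(-J)``, the constant term of the
    characteristic polynomial, evaluated here by LU determinant without an
    eigen-decomposition.  In the spring-pendulum analogy of the 2-node
    linearisation this is the spring constant: a larger stiffness means a
    deeper local potential, hence smaller stationary fluctuations under a
    given noise level.  It is real and positive for every point attractor,
    including complex-eigenvalue (focus) attractors, and equals
    ``(1 - eta12*eta21)/tau^2`` for 2-node networks.  A tau-normalised
    dimensionless form ``s * tau^n`` is reported alongside.

Both indices go to zero-crossing / zero respectively as the attractor
approaches a (real-eigenvalue) bifurcation, which is what ties them to the
critical fluctuations measured elsewhere in this package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import GainFunction, NetworkSpec

NONHYPERBOLIC_TOL = 1e-9  # |Re lambda| below this (1/ms) -> non-hyperbolic
RESIDUAL_TOL = 1e-8
DEDUP_TOL = 1e-6

__all__ = [
    "FixedPointReport",
    "NotAnAttractorError",
    "jacobian",
    "effective_couplings",
    "find_fixed_points",
    "mle",
    "stiffness",
    "mle_two_node_closed_form",
    "stiffness_mle_concordance",
]


class NotAnAttractorError(ValueError):
    """Stiffness is defined for point attractors only (all Re(lambda) < 0)."""


@dataclass(frozen=True)
class FixedPointReport:
    """Location, linearisation and stability indices of one fixed point."""

    location: np.ndarray
    jacobian: np.ndarray  # 1/ms
    eigenvalues: np.ndarray  # complex, 1/ms
    mle: float  # 1/ms
    classification: str  # stable node | stable focus | saddle | unstable | non-hyperbolic
    tau: float
    clipped_edges: tuple[tuple[int, int], ...] = ()
    residual: float = 0.0

    @property
    def n(self) -> int:
        return self.location.size

    @property
    def is_attractor(self) -> bool:
        return self.classification in ("stable node", "stable focus")

    @property
    def stiffness(self) -> float:
        return stiffness(self)

    @property
    def stiffness_normalized(self) -> float:
        return stiffness(self) * self.tau**self.n

    @property
    def mle_normalized(self) -> float:
        """MLE in units of 1/tau (dimensionless, -1 for an isolated node)."""
        return self.mle * self.tau

    def to_dict(self) -> dict:
        d = dict(
            location=[float(v) for v in self.location],
            eigenvalues=[[float(ev.real), float(ev.imag)] for ev in self.eigenvalues],
            mle=float(self.mle),
            mle_normalized=float(self.mle_normalized),
            classification=self.classification,
            clipped_edges=[list(e) for e in self.clipped_edges],
            residual=float(self.residual),
        )
        if self.is_attractor:
            d["stiffness"] = float(self.stiffness)
            d["stiffness_normalized"] = float(self.stiffness_normalized)
        return d


def _classify(eigenvalues: np.ndarray) -> str:
    re = eigenvalues.real
    im = eigenvalues.imag
    if np.any(np.abs(re) < NONHYPERBOLIC_TOL):
        return "non-hyperbolic"
    if np.all(re < 0):
        return "stable focus" if np.any(np.abs(im) > NONHYPERBOLIC_TOL) else "stable node"
    if np.all(re > 0):
        return "unstable"
    return "saddle"


def jacobian(net: NetworkSpec, x: np.ndarray) -> tuple[np.ndarray, tuple[tuple[int, int], ...]]:
    """Analytic Jacobian of the noise-free field at ``x`` (units 1/ms).

    ``J_ij = (-delta_ij + w_ij * S'_ij(x_j)) / tau``.  On edges whose gain
    is clipped at ``x_j`` (unclipped value outside (0, 1)) the derivative
    of the flat branch, 0, is used and the edge is flagged.
    """
    x = np.asarray(x, dtype=float)
    n = net.n
    J = -np.eye(n) / net.tau
    clipped: list[tuple[int, int]] = []
    for (i, j), g in net.gains.items():
        if g.is_clipped_at(x[j]):
            clipped.append((i, j))
            continue
        J[i, j] += net.weights[i, j] * g.deriv(x[j]) / net.tau
    return J, tuple(sorted(clipped))


def effective_couplings(net: NetworkSpec, x: np.ndarray) -> dict[tuple[int, int], float]:
    """``eta_ij = w_ij * S'_ij(x_j)`` at a state ``x`` (0 on clipped edges)."""
    x = np.asarray(x, dtype=float)
    out = {}
    for (i, j), g in net.gains.items():
        out[(i, j)] = 0.0 if g.is_clipped_at(x[j]) else float(net.weights[i, j] * g.deriv(x[j]))
    return out


def _batch_jacobian_tau(net: NetworkSpec, x: np.ndarray) -> np.ndarray:
    """``tau * J`` at every row of ``x`` (m, n) -> (m, n, n), vectorised."""
    m, n = x.shape
    Js = np.tile(-np.eye(n), (m, 1, 1))
    for (i, j), g in net.gains.items():
        u = g.unclipped(x[:, j])
        active = (u > 1e-12) & (u < 1.0 - 1e-12)
        Js[:, i, j] += np.where(active, net.weights[i, j] * g.deriv(x[:, j]), 0.0)
    return Js


def report_at(net: NetworkSpec, x: np.ndarray, residual: float = 0.0) -> FixedPointReport:
    J, clipped = jacobian(net, x)
    eig = np.linalg.eigvals(J)
    return FixedPointReport(
        location=np.asarray(x, dtype=float),
        jacobian=J,
        eigenvalues=eig,
        mle=float(np.max(eig.real)),
        classification=_classify(eig),
        tau=net.tau,
        clipped_edges=clipped,
        residual=residual,
    )


def find_fixed_points(
    net: NetworkSpec,
    grid: int = 21,
    lo: float = -0.1,
    hi: float = 1.1,
    max_iter: int = 80,
) -> list[FixedPointReport]:
    """Roots of the noise-free field, Newton-iterated from a ``grid^n`` seed
    lattice over (slightly widened) [0, 1]^n, de-duplicated at 1e-6.

    Each converged root (field residual < 1e-8) is returned with a full
    stability report, sorted by location.  An empty list means no Newton
    start converged.
    """
    n = net.n
    axes = [np.linspace(lo, hi, grid)] * n
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, n)
    x = pts.copy()
    eye = np.eye(n)
    for _ in range(max_iter):
        f = net.drift(x) * net.tau  # solve -x + drive(x) = 0
        Js = _batch_jacobian_tau(net, x)
        # damped Newton step; near-singular Jacobians (clip corners,
        # bifurcation points) are regularised rather than excluded
        Js = Js + 1e-12 * eye
        try:
            step = np.linalg.solve(Js, f[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.einsum("mij,mj->mi", np.linalg.pinv(Js), f)
        x = x - np.clip(step, -0.25, 0.25)
        x = np.clip(x, lo - 0.5, hi + 0.5)
    res = np.linalg.norm(net.drift(x) * net.tau, axis=-1)
    ok = x[res < RESIDUAL_TOL]
    res_ok = res[res < RESIDUAL_TOL]
    roots: list[tuple[np.ndarray, float]] = []
    for xm, rm in zip(ok, res_ok):
        if not any(np.max(np.abs(xm - r)) < DEDUP_TOL for r, _ in roots):
            roots.append((xm, rm))
    roots.sort(key=lambda pair: tuple(np.round(pair[0], 9)))
    return [report_at(net, xm, residual=float(rm)) for xm, rm in roots]


def mle(report: FixedPointReport) -> float:
    """Maximum real part of the Jacobian eigenvalues, in 1/ms."""
    return float(np.max(report.eigenvalues.real))


def stiffness(report: FixedPointReport, normalized: bool = False) -> float:
    """``det(-J)``, the characteristic polynomial's constant term (1/ms^n).

    Defined for point attractors only; raises :class:`NotAnAttractorError`
    otherwise.  With ``normalized=True`` returns the dimensionless
    ``det(-J) * tau^n``.
    """
    if not np.all(report.eigenvalues.real < -NONHYPERBOLIC_TOL):
        raise NotAnAttractorError(
            "stiffness is defined for point attractors "
            f"(all eigenvalue real parts < 0); got {report.classification}"
        )
    s = float(np.linalg.det(-report.jacobian))
    return s * report.tau**report.n if normalized else s


def mle_two_node_closed_form(eta12: float, eta21: float, tau: float) -> float:
    """``(-1 + Re sqrt(eta12*eta21)) / tau`` for the 2-node linearisation."""
    root = np.sqrt(complex(eta12 * eta21))
    return float((-1.0 + root.real) / tau)


def stiffness_mle_concordance(
    reports: list[FixedPointReport],
) -> tuple[float, list[FixedPointReport]]:
    """Check ``MLE = (-1 + sqrt(1 - s*tau^2)) / tau`` on real-eigenvalue
    2-node attractors (mutual excitation / mutual inhibition).

    Returns the maximum absolute deviation over the checked reports and the
    list of reports skipped because their eigenvalues are complex (there
    the MLE, which discards imaginary parts, is not in one-to-one
    correspondence with stiffness).  The stiffness is evaluated as
    ``det(-J)`` directly so the check extends to the bifurcation endpoint
    ``s = 0``, where the fixed point is no longer an attractor but the
    closed form still holds.
    """
    max_dev = 0.0
    skipped: list[FixedPointReport] = []
    for rep in reports:
        if rep.n != 2:
            raise ValueError("concordance check is defined for 2-node reports")
        if np.any(np.abs(rep.eigenvalues.imag) > NONHYPERBOLIC_TOL):
            skipped.append(rep)
            continue
        s_norm = float(np.linalg.det(-rep.jacobian)) * rep.tau**2
        predicted = (-1.0 + np.sqrt(max(1.0 - s_norm, 0.0))) / rep.tau
        max_dev = max(max_dev, abs(rep.mle - predicted))
    return max_dev, skipped
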