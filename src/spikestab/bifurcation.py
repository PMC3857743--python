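"""Parameter-sweep experiments linking attractor stability to firing irregularity.

Two families of presets are provided.

*Stability sweeps* hold a point attractor fixed at moderate activity while a
gain parameter moves the attractor's stability index over a range:

``fig4_mutual_excitation`` / ``fig4_mutual_inhibition``
    Two mutually excitatory (inhibitory) populations with the attractor
    pinned at (0.5, 0.5); steepening the gain of node X2 raises the
    effective coupling product toward the bifurcation at 1, driving the
    MLE from -0.7/tau toward 0 while leaving the attractor - and hence the
    firing rate - unchanged.
``s4_exc_inh``
    An excitation-inhibition loop whose eigenvalues are complex, so the
    MLE sits at -1/tau for every sweep point; the normalised stiffness
    moves from 2.0 down toward 1.0 instead.
``s6_three_node`` / ``s6_three_node_exc``
    Three bidirectionally coupled populations (pair signs
    inhibition-excitation-excitation, or all-excitatory) tuned for a point
    attractor at (0.5, 0.5, 0.5), i.e. ~10 spikes/s through the phase
    model; the symmetric coupling gives real eigenvalues and a stiffness
    that falls to 0 as the leading eigenvalue approaches the axis.

*Bifurcation scenarios* carry the network from a quiet attractor up to and
past a criticality, with the path point just before the crossing marked
``critical_index`` and the past-critical point ``post_index``:

``pitchfork``
    Symmetric mutual inhibition; the symmetric attractor loses stability
    when the coupling product crosses 1 and two winner-take-all attractors
    branch off.
``saddle_node``
    Asymmetric mutual excitation; lowering the maximum effect of one gain
    makes the tracked high-activity attractor collide with a saddle and
    vanish, and the state jumps to the remaining low attractor.
``hopf``
    A three-node directed loop with one inhibitory edge: the ring gain
    product is negative, so a complex pair crosses the imaginary axis
    (at ring slope 2) and a limit cycle appears.

``run_sweep`` simulates each path point from its tracked attractor with
per-step gain noise, reads out spikes for every node through the phase
model, and reports LvR (R = 11 ms) and firing rate with SEM over seeded
repeats alongside the fixed-point stability report.  Past the criticality
the run is started from the destination attractor when one exists (the
post-transition state), or from the last tracked location when none does
(Hopf: onto the limit cycle).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .network import (
    GainFunction,
    NetworkSpec,
    PhaseNeuronConfig,
    simulate,
    simulate_ensemble,
    generate_spikes,
)
from .spike_metrics import DEFAULT_R_MS, extract_isis, lvr
from .stability import FixedPointReport, find_fixed_points

TRACK_RADIUS = 0.25  # branch continuity tolerance in activity units
# (the fold preset's attractor drifts by up to ~0.17 between path points;
# post-critical jumps to another attractor are >= ~0.32, so the radius
# separates branch drift from basin hopping)

SCENARIO_NAMES = (
    "fig4_mutual_excitation",
    "fig4_mutual_inhibition",
    "s4_exc_inh",
    "s6_three_node",
    "s6_three_node_exc",
    "pitchfork",
    "saddle_node",
    "hopf",
)

__all__ = [
    "ScenarioSpec",
    "SweepPoint",
    "PathValidationError",
    "preset",
    "run_sweep",
    "classify_bifurcation",
    "scenario_summary",
    "SCENARIO_NAMES",
]


class PathValidationError(RuntimeError):
    """The tracked attractor was lost before the declared critical point."""


@dataclass(frozen=True)
class ScenarioSpec:
    """An ordered parameter path plus the indices that structure it.

    ``networks[k]`` is the network at path point ``k`` (ordered from far
    from criticality toward / past it), ``params[k]`` a human-readable
    record of the swept parameter.  ``critical_index`` / ``post_index``
    are None for pure stability sweeps.
    """

    name: str
    networks: tuple[NetworkSpec, ...]
    params: tuple[dict, ...]
    tracked_start: np.ndarray
    sigma: float
    critical_index: int | None = None
    post_index: int | None = None
    initial_index: int = 0


@dataclass(frozen=True)
class SweepPoint:
    """Per-path-point stability report plus spiking statistics.

    ``lvr_values`` and ``rate_values`` have shape (repeats, n_nodes); the
    irregularity is LvR with R = 11 ms over each repeat's full train (NaN
    when a repeat yielded fewer than 2 ISIs on a node).
    """

    params: dict
    report: FixedPointReport | None
    start: np.ndarray
    lvr_values: np.ndarray
    rate_values: np.ndarray
    repeats: int

    @property
    def lvr_mean(self) -> np.ndarray:
        return np.nanmean(self.lvr_values, axis=0)

    @property
    def lvr_sem(self) -> np.ndarray:
        n = np.sum(np.isfinite(self.lvr_values), axis=0)
        return np.nanstd(self.lvr_values, axis=0, ddof=1) / np.sqrt(np.maximum(n, 1))

    @property
    def rate_mean(self) -> np.ndarray:
        return np.nanmean(self.rate_values, axis=0)

    @property
    def rate_sem(self) -> np.ndarray:
        return np.nanstd(self.rate_values, axis=0, ddof=1) / np.sqrt(self.repeats)


# ---------------------------------------------------------------------------
# Preset construction.  Gain parameters are derived from constraints: the
# attractor location (which sets the firing rate through the phase model)
# and the gain slope at the attractor (which sets the effective coupling
# eta, hence MLE and stiffness).  theta is held at 0.5 throughout.
# ---------------------------------------------------------------------------

def gain_through(value: float, slope: float, at: float = 0.5, theta: float = 0.5) -> GainFunction:
    """Naka-Rushton gain with prescribed value and slope at activity ``at``."""
    c = slope * (theta + at) ** 2 / theta
    B = value - c * at / (theta + at)
    return GainFunction(c=c, B=B, theta=theta)


def _two_node(sign: int, slopes: tuple[float, float], sigma: float) -> NetworkSpec:
    w = np.array([[0, sign], [sign, 0]], dtype=float)
    bias = np.zeros(2) if sign > 0 else np.ones(2)
    return NetworkSpec(
        weights=w,
        gains={(0, 1): gain_through(0.5, slopes[0]), (1, 0): gain_through(0.5, slopes[1])},
        sigma=sigma,
        bias=bias,
    )


def _s6_network(eta: float, signs: tuple[int, int, int], sigma: float) -> NetworkSpec:
    """Bidirectional 3-node net, pair signs (0-1, 0-2, 1-2), attractor (.5,.5,.5)."""
    s01, s02, s12 = signs
    W = np.array([[0, s01, s02], [s01, 0, s12], [s02, s12, 0]], dtype=float)
    gains = {
        (i, j): gain_through(0.25, eta) for i in range(3) for j in range(3) if W[i, j] != 0
    }
    bias = 0.5 - 0.25 * W.sum(axis=1)
    return NetworkSpec(weights=W, gains=gains, sigma=sigma, bias=bias)


def _hopf_network(rho: float, sigma: float) -> NetworkSpec:
    """Directed 3-ring 0 <- 1 <- 2 <- 0 with the 1 -> 0 edge inhibitory."""
    W = np.zeros((3, 3))
    W[0, 1] = -1.0
    W[1, 2] = 1.0
    W[2, 0] = 1.0
    gains = {e: gain_through(0.5, rho) for e in [(0, 1), (1, 2), (2, 0)]}
    return NetworkSpec(weights=W, gains=gains, sigma=sigma, bias=np.array([1.0, 0.0, 0.0]))


def _saddle_node_network(c01: float, sigma: float) -> NetworkSpec:
    return NetworkSpec(
        weights=np.array([[0, 1], [1, 0]], dtype=float),
        gains={
            (0, 1): GainFunction(c=c01, B=-0.9, theta=0.5),
            (1, 0): GainFunction(c=1.0, B=-0.2, theta=0.5),
        },
        sigma=sigma,
        bias=np.array([0.25, 0.0]),
    )


def preset(name: str, sigma: float | None = None) -> ScenarioSpec:
    """Build one of the named scenario presets (see module docstring)."""
    half = np.array([0.5, 0.5])
    if name == "fig4_mutual_excitation" or name == "fig4_mutual_inhibition":
        sign = 1 if name.endswith("excitation") else -1
        sig = 0.025 if sigma is None else sigma
        eta1 = 0.3
        products = (0.09, 0.2, 0.35, 0.5, 0.65, 0.8, 0.9, 0.96)
        nets = tuple(_two_node(sign, (eta1, p / eta1), sig) for p in products)
        params = tuple({"coupling_product": p} for p in products)
        return ScenarioSpec(name, nets, params, half, sig)
    if name == "s4_exc_inh":
        sig = 0.025 if sigma is None else sigma
        mags = (1.0, 0.75, 0.5, 0.25, 0.05)
        nets = []
        for q in mags:
            s = np.sqrt(q)
            nets.append(
                NetworkSpec(
                    weights=np.array([[0, 1], [-1, 0]], dtype=float),
                    gains={(0, 1): gain_through(0.5, s), (1, 0): gain_through(0.5, s)},
                    sigma=sig,
                    bias=np.array([0.0, 1.0]),
                )
            )
        params = tuple({"coupling_product": -q, "stiffness_norm": 1.0 + q} for q in mags)
        return ScenarioSpec(name, tuple(nets), params, half, sig)
    if name in ("s6_three_node", "s6_three_node_exc"):
        sig = 0.01 if sigma is None else sigma
        if name == "s6_three_node":
            signs, etas = (-1, 1, 1), (0.1, 0.3, 0.5, 0.7, 0.85, 0.95)
        else:
            signs, etas = (1, 1, 1), (0.05, 0.15, 0.25, 0.35, 0.425, 0.475)
        nets = tuple(_s6_network(eta, signs, sig) for eta in etas)
        params = tuple({"pair_slope": eta} for eta in etas)
        return ScenarioSpec(name, nets, params, np.full(3, 0.5), sig)
    if name == "pitchfork":
        sig = 0.025 if sigma is None else sigma
        products = (0.2, 0.5, 0.8, 0.95, 0.99, 1.3)
        nets = tuple(_two_node(-1, (np.sqrt(p), np.sqrt(p)), sig) for p in products)
        params = tuple({"coupling_product": p} for p in products)
        return ScenarioSpec(name, nets, params, half, sig, critical_index=4, post_index=5)
    if name == "saddle_node":
        sig = 0.025 if sigma is None else sigma
        c01s = (3.5, 3.35, 3.22, 3.14, 3.0533, 3.0)
        nets = tuple(_saddle_node_network(c, sig) for c in c01s)
        params = tuple({"c01": c} for c in c01s)
        return ScenarioSpec(
            name, nets, params, np.array([1.05, 0.48]), sig, critical_index=4, post_index=5
        )
    if name == "hopf":
        sig = 0.025 if sigma is None else sigma
        rhos = (0.8, 1.4, 1.8, 1.95, 2.2)
        nets = tuple(_hopf_network(r, sig) for r in rhos)
        params = tuple({"ring_slope": r} for r in rhos)
        return ScenarioSpec(
            name, nets, params, np.full(3, 0.5), sig, critical_index=3, post_index=4
        )
    raise ValueError(f"unknown scenario {name!r}; presets: {', '.join(SCENARIO_NAMES)}")


# ---------------------------------------------------------------------------
# Sweep execution
# ---------------------------------------------------------------------------

def _track(
    reports: list[FixedPointReport], prev: np.ndarray
) -> tuple[FixedPointReport | None, FixedPointReport | None]:
    """(attractor on the tracked branch or None, nearest attractor overall)."""
    atts = [r for r in reports if r.is_attractor]
    if not atts:
        return None, None
    nearest = min(atts, key=lambda r: float(np.max(np.abs(r.location - prev))))
    on_branch = nearest if np.max(np.abs(nearest.location - prev)) < TRACK_RADIUS else None
    return on_branch, nearest


def run_sweep(
    spec: ScenarioSpec,
    repeats: int = 20,
    seed: int | None = 0,
    steps: int = 60_000,
    dt: float = 0.05,
    sigma: float | None = None,
    phase_cfg: PhaseNeuronConfig = PhaseNeuronConfig(),
    R: float = DEFAULT_R_MS,
) -> list[SweepPoint]:
    """Simulate every path point and measure irregularity and rate per node.

    ``sigma`` overrides the scenario's noise level (pass 0.0 for the
    noise-free control).  Pre-critical points must carry a point attractor
    on the tracked branch, else :class:`PathValidationError` is raised.
    """
    if repeats < 2:
        raise ValueError("repeats must be >= 2 (SEM over repeats)")
    seeds = np.random.SeedSequence(seed).spawn(len(spec.networks))
    points: list[SweepPoint] = []
    prev = np.asarray(spec.tracked_start, dtype=float)
    critical = spec.critical_index if spec.critical_index is not None else len(spec.networks)
    for k, (net, params) in enumerate(zip(spec.networks, spec.params)):
        if sigma is not None:
            net = net.with_sigma(sigma)
        reports = find_fixed_points(net)
        on_branch, nearest = _track(reports, prev)
        if k <= critical and on_branch is None:
            raise PathValidationError(
                f"{spec.name}: no point attractor within {TRACK_RADIUS} of the tracked "
                f"branch at path point {k} ({params}); last location {prev}"
            )
        # past the criticality: measure the settled post-transition state -
        # the destination attractor when one exists, else start on the old
        # branch and let the flow (e.g. a limit cycle) take over
        tracked = on_branch if on_branch is not None else nearest
        start = tracked.location if tracked is not None else prev
        ens = simulate_ensemble(net, repeats, steps=steps, seed=seeds[k], x0=start, dt=dt)
        lvr_vals = np.full((repeats, net.n), np.nan)
        rate_vals = np.zeros((repeats, net.n))
        for r, traj in enumerate(ens):
            for node in range(net.n):
                train = generate_spikes(traj, phase_cfg, node)
                rate_vals[r, node] = train.times.size / (traj.duration_ms / 1000.0)
                res = lvr(extract_isis(train), R=R)
                if res.defined:
                    lvr_vals[r, node] = res.value
        points.append(
            SweepPoint(
                params=dict(params),
                report=tracked,
                start=start,
                lvr_values=lvr_vals,
                rate_values=rate_vals,
                repeats=repeats,
            )
        )
        prev = start
    return points


# ---------------------------------------------------------------------------
# Bifurcation classification (fixed-point counting + eigenstructure)
# ---------------------------------------------------------------------------

def _oscillates_post(net: NetworkSpec, start: np.ndarray, steps: int = 60_000) -> bool:
    """Noise-free run from a perturbed start: sustained oscillation?"""
    x0 = np.asarray(start, float) + 1e-3
    traj = simulate(net.with_sigma(0.0), steps=steps, x0=x0)
    tail = traj.x[int(0.75 * traj.x.shape[0]):]
    return bool(np.max(np.std(tail, axis=0)) > 1e-3)


def classify_bifurcation(spec: ScenarioSpec) -> tuple[str, dict]:
    """Identify the criticality a scenario path crosses.

    Compares the fixed-point structure at the last pre-critical path point
    with the structure past the criticality:

    - the tracked attractor vanishes (no nearby root remains) after
      colliding with a saddle -> ``saddle-node``;
    - the tracked point persists as a saddle via a real eigenvalue
      crossing, with new attractors branching off -> ``pitchfork``;
    - the tracked point persists with a complex leading pair crossing the
      axis, and the post-critical flow oscillates -> ``hopf``;
    - anything else (including paths with no declared criticality) ->
      ``none`` with diagnostics.
    """
    diag: dict = {}
    if spec.critical_index is None or spec.post_index is None:
        return "none", {"reason": "path declares no criticality"}
    pre_idx = max(spec.critical_index - 1, 0)
    pre_net = spec.networks[pre_idx].with_sigma(0.0)
    post_net = spec.networks[spec.post_index].with_sigma(0.0)
    pre_reports = find_fixed_points(pre_net)
    post_reports = find_fixed_points(post_net)

    prev = np.asarray(spec.tracked_start, float)
    for net in spec.networks[: pre_idx + 1]:
        on_branch, _ = _track(find_fixed_points(net.with_sigma(0.0)), prev)
        if on_branch is None:
            return "none", {"reason": f"tracked attractor lost before point {pre_idx}"}
        prev = on_branch.location
    tracked_pre, _ = _track(pre_reports, prev)
    loc = tracked_pre.location
    lead = tracked_pre.eigenvalues[np.argmax(tracked_pre.eigenvalues.real)]
    complex_lead = bool(abs(lead.imag) > 1e-9)
    diag["pre_mle_norm"] = tracked_pre.mle_normalized
    diag["pre_leading_imag"] = float(lead.imag)

    near_post = [r for r in post_reports if np.max(np.abs(r.location - loc)) < TRACK_RADIUS]
    n_att_pre = sum(r.is_attractor for r in pre_reports)
    n_att_post = sum(r.is_attractor for r in post_reports)
    diag["n_attractors_pre"] = n_att_pre
    diag["n_attractors_post"] = n_att_post

    if not near_post:
        pre_saddles = [
            r for r in pre_reports
            if r.classification == "saddle" and np.max(np.abs(r.location - loc)) < 0.5
        ]
        diag["pre_saddle_nearby"] = bool(pre_saddles)
        if pre_saddles and len(post_reports) <= len(pre_reports) - 2:
            return "saddle-node", diag
        return "none", diag
    persist = near_post[0]
    diag["post_classification"] = persist.classification
    if complex_lead and not persist.is_attractor:
        if _oscillates_post(post_net, loc):
            diag["oscillates"] = True
            return "hopf", diag
        diag["oscillates"] = False
        return "none", diag
    if (not complex_lead) and persist.classification == "saddle" and n_att_post >= n_att_pre + 1:
        return "pitchfork", diag
    return "none", diag


# ---------------------------------------------------------------------------
# Scenario summary: initial vs critical vs post-transition contrasts
# ---------------------------------------------------------------------------

def _nanmean(a: np.ndarray) -> float:
    """nanmean that returns NaN silently on all-NaN input."""
    a = np.asarray(a, float).ravel()
    a = a[np.isfinite(a)]
    return float(a.mean()) if a.size else float("nan")


def _nansem(a: np.ndarray) -> float:
    a = np.asarray(a, float).ravel()
    a = a[np.isfinite(a)]
    return float(a.std(ddof=1) / np.sqrt(a.size)) if a.size >= 2 else float("nan")


def scenario_summary(points: list[SweepPoint], spec: ScenarioSpec) -> dict:
    """Delta-LvR contrasts between the initial, critical and post points.

    For each node: mean change in LvR from the initial path point (with
    SEM over repeats) at the critical and post-transition points, with
    one-sided Welch t-tests for the critical-point elevation and for the
    post-transition change relative to critical.  The node-averaged
    post-vs-critical contrast carries the pitchfork/saddle-node signature
    (variability drops once the state settles in the destination
    attractor) and its absence carries the Hopf signature (sustained
    elevation on the limit cycle).
    """
    if spec.critical_index is None or spec.post_index is None:
        raise ValueError("scenario_summary needs a path with critical/post indices")
    init = points[spec.initial_index]
    crit = points[spec.critical_index]
    post = points[spec.post_index] if spec.post_index < len(points) else None
    out: dict = {"scenario": spec.name, "nodes": [], "warnings": []}
    n_nodes = init.lvr_values.shape[1]
    for node in range(n_nodes):
        base = _nanmean(init.lvr_values[:, node])
        d_crit = crit.lvr_values[:, node] - base
        entry = {
            "node": node,
            "baseline_lvr": base,
            "delta_critical_mean": _nanmean(d_crit),
            "delta_critical_sem": _nansem(d_crit),
            "p_critical_elevated": float(
                stats.ttest_ind(
                    crit.lvr_values[:, node][np.isfinite(crit.lvr_values[:, node])],
                    init.lvr_values[:, node][np.isfinite(init.lvr_values[:, node])],
                    equal_var=False,
                    alternative="greater",
                ).pvalue
            ),
        }
        if post is not None:
            d_post = post.lvr_values[:, node] - base
            entry["delta_post_mean"] = _nanmean(d_post)
            entry["delta_post_sem"] = _nansem(d_post)
        out["nodes"].append(entry)
    if post is None:
        out["warnings"].append("missing post-critical point; partial table")
        return out
    with np.errstate(invalid="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            crit_avg = np.nanmean(crit.lvr_values, axis=1)
            post_avg = np.nanmean(post.lvr_values, axis=1)
            init_avg = np.nanmean(init.lvr_values, axis=1)
    out["node_avg_delta_critical"] = _nanmean(crit_avg) - _nanmean(init_avg)
    out["node_avg_delta_post"] = _nanmean(post_avg) - _nanmean(init_avg)
    out["p_post_below_critical"] = float(
        stats.ttest_ind(
            post_avg[np.isfinite(post_avg)],
            crit_avg[np.isfinite(crit_avg)],
            equal_var=False,
            alternative="less",
        ).pvalue
    )
    out["p_post_above_initial"] = float(
        stats.ttest_ind(
            post_avg[np.isfinite(post_avg)],
            init_avg[np.isfinite(init_avg)],
            equal_var=False,
            alternative="greater",
        ).pvalue
    )
    out["post_decreased"] = bool(out["p_post_below_critical"] < 0.05)
    out["post_sustained"] = bool(
        out["p_post_above_initial"] < 0.05 and not out["post_decreased"]
    )
    return out
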