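"""Trial-structured synthetic spike trains with known ground truth.

No public dataset exists for the delayed path-planning task, so the
selectivity and irregularity pipelines are exercised on generated cohorts
whose response classes, transition times and irregularity schedules are
known by construction.

Spike trains are time-rescaled gamma renewal processes: a unit-rate gamma
renewal sequence with shape ``kappa`` is drawn in operational time and
mapped through the cumulative intensity of a piecewise-constant rate
profile ``r(t)``.  This factorises rate and irregularity exactly - the
rate profile alone fixes the expected counts, while ``kappa`` alone fixes
the local ISI variability (Lv ~ 3/(2*kappa + 1): 1 for Poisson, -> 0 for
clock-like trains) - which is precisely the factorisation the rate-robust
irregularity measures are designed to exploit.

Trial timeline (ms, relative to final-goal onset): start display at
-1000, final-goal onset at 0, delay from 1000, go cue at 2400.  An F-I
profile fires at ``baseline + amplitude`` when the final goal matches its
preferred quadrant before its programmed transition time and switches to
the immediate goal afterwards; its ``kappa`` dips (irregularity rises) in
a window just before the transition and recovers after, emulating the
critical-fluctuation schedule that the epoch contrasts are meant to
detect.  Final-goal profiles keep their final-goal tuning throughout;
unselective profiles fire at baseline everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .selectivity import TrialDataset

T_START_DISPLAY = -1000.0
T_FINAL_GOAL = 0.0
T_DELAY = 1000.0
T_GO = 2400.0

DEFAULT_BASELINE_RATE = 5.7  # spikes/s, matches the task's preparatory-period scale
DEFAULT_AMPLITUDE = 10.0  # spikes/s added on preferred-goal trials
DEFAULT_KAPPA = 1.0  # Poisson-like baseline irregularity
DEFAULT_KAPPA_DIP = 0.5  # gamma shape inside the pre-transition dip window
KAPPA_DIP_SPAN_MS = 400.0  # dip covers [transition - span, transition)

__all__ = [
    "NeuronProfile",
    "CohortSpec",
    "gamma_train",
    "make_trial_table",
    "make_fi_neuron",
    "make_cohort",
]


@dataclass(frozen=True)
class NeuronProfile:
    """Ground-truth description of one synthetic neuron."""

    neuron_id: str
    functional_class: str  # "F-I" | "final-goal" | "unselective"
    baseline_rate: float = DEFAULT_BASELINE_RATE
    amplitude: float = DEFAULT_AMPLITUDE
    preferred_final: tuple[int, int] = (1, 1)  # (h, v) in {-1, +1}
    preferred_imm: tuple[int, int] = (1, 1)
    transition_ms: float | None = None  # F-I only
    kappa_baseline: float = DEFAULT_KAPPA
    kappa_dip: float | None = DEFAULT_KAPPA_DIP
    kappa_dip_window: tuple[float, float] | None = None  # default: before transition

    def __post_init__(self) -> None:
        if self.baseline_rate < 0 or self.amplitude < 0:
            raise ValueError("rates must be non-negative")
        if self.kappa_baseline <= 0:
            raise ValueError("kappa must be positive")
        if self.functional_class == "F-I":
            if self.transition_ms is None or not (
                T_START_DISPLAY < self.transition_ms < T_GO
            ):
                raise ValueError("F-I profile needs a transition inside the period")
        elif self.transition_ms is not None:
            raise ValueError("only F-I profiles carry a transition time")


@dataclass(frozen=True)
class CohortSpec:
    """Composition of a synthetic cohort (defaults mirror the task's cohort sizes)."""

    n_fi: int = 148
    n_final_goal: int = 259
    n_unselective: int = 480
    n_trials: int = 200
    seed: int = 0
    baseline_rate: float = DEFAULT_BASELINE_RATE
    amplitude: float = DEFAULT_AMPLITUDE
    kappa_baseline: float = DEFAULT_KAPPA
    kappa_dip: float | None = DEFAULT_KAPPA_DIP
    inhibitory_fraction: float = 0.25
    transition_range_ms: tuple[float, float] = (1300.0, 1500.0)

    def __post_init__(self) -> None:
        if min(self.n_fi, self.n_final_goal, self.n_unselective) < 0:
            raise ValueError("class counts must be non-negative")
        if self.n_fi + self.n_final_goal + self.n_unselective < 1 or self.n_trials < 8:
            raise ValueError("need >= 1 neuron overall and >= 8 trials")


def gamma_train(
    edges: np.ndarray,
    rates: np.ndarray,
    kappas: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample one spike train on [edges[0], edges[-1]) by time rescaling.

    ``rates`` (spikes/s) and ``kappas`` are piecewise-constant on the
    segments between ``edges`` (ms).  Operational time advances by
    unit-mean gamma intervals whose shape is the ``kappa`` in force at the
    previous spike; real times come from inverting the cumulative
    intensity.  An all-zero rate profile yields an empty train.
    """
    edges = np.asarray(edges, dtype=float)
    rates = np.asarray(rates, dtype=float)
    kappas = np.asarray(kappas, dtype=float)
    if edges.size != rates.size + 1 or rates.size != kappas.size:
        raise ValueError("need len(edges) = len(rates) + 1 = len(kappas) + 1")
    if np.any(rates < 0) or np.any(kappas <= 0):
        raise ValueError("rates must be >= 0 and kappas > 0")
    lam = np.concatenate(([0.0], np.cumsum(rates / 1000.0 * np.diff(edges))))
    total = lam[-1]
    if total <= 0:
        return np.empty(0)

    def to_time(op: float) -> float:
        seg = int(np.searchsorted(lam, op, side="right") - 1)
        seg = min(seg, rates.size - 1)
        return edges[seg] + (op - lam[seg]) / (rates[seg] / 1000.0)

    times = []
    op = 0.0
    t_now = edges[0]
    while True:
        seg = int(np.clip(np.searchsorted(edges, t_now, side="right") - 1, 0, kappas.size - 1))
        k = kappas[seg]
        op += rng.gamma(k, 1.0 / k)
        if op >= total:
            break
        t_now = to_time(op)
        times.append(t_now)
    out = np.array(times)
    return out[np.concatenate(([True], np.diff(out) > 0))] if out.size else out


def make_trial_table(n_trials: int, rng: np.random.Generator) -> pd.DataFrame:
    """Balanced random +/-1 goal factors with the fixed event timeline."""
    def balanced(n: int) -> np.ndarray:
        half = np.concatenate([np.ones(n // 2 + n % 2), -np.ones(n // 2)])
        return rng.permutation(half).astype(int)

    return pd.DataFrame(
        dict(
            trial_id=[f"tr{k:04d}" for k in range(n_trials)],
            final_goal_h=balanced(n_trials),
            final_goal_v=balanced(n_trials),
            imm_goal_h=balanced(n_trials),
            imm_goal_v=balanced(n_trials),
            t_start_display_ms=T_START_DISPLAY,
            t_final_goal_ms=T_FINAL_GOAL,
            t_delay_ms=T_DELAY,
            t_go_ms=T_GO,
        )
    )


def _segments_for_trial(profile: NeuronProfile, trial: pd.Series):
    """Merged piecewise-constant (edges, rates, kappas) for one trial."""
    match_final = (
        trial["final_goal_h"] == profile.preferred_final[0]
        and trial["final_goal_v"] == profile.preferred_final[1]
    )
    match_imm = (
        trial["imm_goal_h"] == profile.preferred_imm[0]
        and trial["imm_goal_v"] == profile.preferred_imm[1]
    )
    rate_changes: list[tuple[float, float]] = [(T_START_DISPLAY, profile.baseline_rate)]
    if profile.functional_class == "final-goal":
        rate_changes = [(T_START_DISPLAY, profile.baseline_rate + profile.amplitude * match_final)]
    elif profile.functional_class == "F-I":
        rate_changes = [
            (T_START_DISPLAY, profile.baseline_rate + profile.amplitude * match_final),
            (profile.transition_ms, profile.baseline_rate + profile.amplitude * match_imm),
        ]
    kappa_changes: list[tuple[float, float]] = [(T_START_DISPLAY, profile.kappa_baseline)]
    if profile.kappa_dip is not None and profile.functional_class == "F-I":
        window = profile.kappa_dip_window
        if window is None:
            window = (profile.transition_ms - KAPPA_DIP_SPAN_MS, profile.transition_ms)
        kappa_changes += [(window[0], profile.kappa_dip), (window[1], profile.kappa_baseline)]
        kappa_changes.sort()
    edges = np.unique(
        np.concatenate(
            [[t for t, _ in rate_changes], [t for t, _ in kappa_changes], [T_GO]]
        )
    )
    def value_at(changes, t):
        v = changes[0][1]
        for tc, vc in changes:
            if tc <= t:
                v = vc
        return v
    mids = 0.5 * (edges[:-1] + edges[1:])
    rates = np.array([value_at(rate_changes, t) for t in mids])
    kappas = np.array([value_at(kappa_changes, t) for t in mids])
    return edges, rates, kappas


def make_fi_neuron(
    profile: NeuronProfile,
    trials: pd.DataFrame,
    rng: np.random.Generator,
    resolution_ms: float = 1.0,
) -> pd.DataFrame:
    """Spike rows (neuron_id, trial_id, spike_time_ms) for one profile.

    Despite the name this renders any profile class; F-I profiles switch
    their tuning and run their kappa dip, final-goal profiles stay tuned
    to the final goal, unselective profiles fire at baseline.

    Spike times are quantised to ``resolution_ms`` (default 1 ms, the
    resolution of extracellular recordings) and ties merged, which also
    emulates the absolute refractoriness of real units: the continuous
    renewal process underneath can produce arbitrarily short intervals
    that no recorded spike train contains.
    """
    for col in ("final_goal_h", "imm_goal_h"):
        if trials[col].nunique() < 2:
            raise ValueError(f"degenerate goal coverage in {col}")
    rows = []
    for _, trial in trials.iterrows():
        edges, rates, kappas = _segments_for_trial(profile, trial)
        times = gamma_train(edges, rates, kappas, rng)
        if resolution_ms:
            times = np.unique(np.round(times / resolution_ms) * resolution_ms)
        for t in times:
            rows.append((profile.neuron_id, trial["trial_id"], float(t)))
    return pd.DataFrame(rows, columns=["neuron_id", "trial_id", "spike_time_ms"])


def _waveform_features(
    neuron_ids: list[str], inhibitory: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """Two-component waveform-duration mixture; narrow norms = inhibitory."""
    n = len(neuron_ids)
    norms = np.where(
        inhibitory,
        rng.normal(0.3, 0.03, size=n),
        rng.normal(0.8, 0.05, size=n),
    )
    norms = np.clip(norms, 0.05, None)
    angle = rng.normal(np.pi / 4.0, 0.05, size=n)
    return pd.DataFrame(
        dict(
            neuron_id=neuron_ids,
            trough_peak_ms=norms * np.cos(angle),
            onset_return_ms=norms * np.sin(angle),
        )
    )


def make_cohort(spec: CohortSpec) -> tuple[TrialDataset, pd.DataFrame, pd.DataFrame]:
    """Full synthetic cohort: dataset, ground-truth table, waveform features.

    All neurons share one trial table (a simultaneous-recording layout).
    The ground-truth table (neuron_id, functional_class, transition_ms,
    putative_type, preferred goals) is for scoring only; the analysis
    modules never read it.
    """
    rng = np.random.default_rng(spec.seed)
    trials = make_trial_table(spec.n_trials, rng)
    quadrants = [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    profiles: list[NeuronProfile] = []
    counter = 0
    for cls, count in (
        ("F-I", spec.n_fi),
        ("final-goal", spec.n_final_goal),
        ("unselective", spec.n_unselective),
    ):
        for _ in range(count):
            transition = (
                float(rng.uniform(*spec.transition_range_ms)) if cls == "F-I" else None
            )
            profiles.append(
                NeuronProfile(
                    neuron_id=f"n{counter:04d}",
                    functional_class=cls,
                    baseline_rate=spec.baseline_rate,
                    amplitude=spec.amplitude if cls != "unselective" else 0.0,
                    preferred_final=quadrants[rng.integers(4)],
                    preferred_imm=quadrants[rng.integers(4)],
                    transition_ms=transition,
                    kappa_baseline=spec.kappa_baseline,
                    kappa_dip=spec.kappa_dip,
                )
            )
            counter += 1
    spike_frames = [make_fi_neuron(p, trials, rng) for p in profiles]
    spikes = (
        pd.concat(spike_frames, ignore_index=True)
        if spike_frames
        else pd.DataFrame(columns=["neuron_id", "trial_id", "spike_time_ms"])
    )
    inhibitory = rng.random(len(profiles)) < spec.inhibitory_fraction
    waveforms = _waveform_features([p.neuron_id for p in profiles], inhibitory, rng)
    truth = pd.DataFrame(
        dict(
            neuron_id=[p.neuron_id for p in profiles],
            functional_class=[p.functional_class for p in profiles],
            transition_ms=[p.transition_ms for p in profiles],
            putative_type=np.where(inhibitory, "inhibitory", "excitatory"),
            preferred_final_h=[p.preferred_final[0] for p in profiles],
            preferred_final_v=[p.preferred_final[1] for p in profiles],
            preferred_imm_h=[p.preferred_imm[0] for p in profiles],
            preferred_imm_v=[p.preferred_imm[1] for p in profiles],
        )
    )
    return TrialDataset(trials=trials, spikes=spikes), truth, waveforms
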