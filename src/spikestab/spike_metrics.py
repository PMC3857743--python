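"""Rate-robust irregularity measures on interspike-interval (ISI) sequences.

All measures contrast *consecutive* ISIs, which makes them insensitive to
slow firing-rate modulation: a pure rate change rescales neighbouring
intervals together and leaves the pairwise contrast unchanged.  The measures
implemented here are

``lvr``
    Local variation with refractoriness correction ``R`` (default 11 ms).
    The correction term ``1 + 4R/(I_i + I_{i+1})`` compensates for the
    regularising effect of the refractory period at high rates, which is
    what makes LvR essentially uncorrelated with rate in cortical data.
``lv``
    Local variation; identical to ``lvr`` with ``R = 0``.  Expected value
    is 0 for a perfectly regular train, 1 for a Poisson process and
    ``3/(2*kappa + 1)`` for a gamma renewal process of shape ``kappa``.
``ir``
    Mean absolute log ratio of consecutive ISIs.
``si``
    Negative mean half-log of the ratio of geometric to arithmetic pair
    means; non-negative by the AM-GM inequality, 0 only for locally
    regular trains.

Windowed estimation pools consecutive-ISI pairs across trials: a pair
``(I_i, I_{i+1})`` contributes to a window iff all three spikes that define
it fall inside the window, and the reported value is the measure's scale
factor times the mean per-pair summand over the pooled pairs.  At cortical
rates of a few spikes per second this pooled estimator is the only one
defined at the 100-ms window lengths used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

DEFAULT_R_MS = 11.0  #: refractoriness constant for LvR, ms

__all__ = [
    "SpikeTrain",
    "IrregularityResult",
    "extract_isis",
    "lvr",
    "lv",
    "ir",
    "si",
    "windowed_irregularity",
    "firing_rate",
    "windowed_table",
    "MEASURES",
    "DEFAULT_R_MS",
]


@dataclass(frozen=True)
class SpikeTrain:
    """An ordered set of spike times (ms) from one neuron in one trial.

    Times are kept at their native (millisecond-scale) resolution and must
    be strictly increasing and contained in the half-open segment
    ``[t0, t1)``.
    """

    times: np.ndarray
    t0: float = -np.inf
    t1: float = np.inf
    neuron_id: str = ""
    trial_id: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.ndim != 1:
            raise ValueError("spike times must be one-dimensional")
        if times.size and (np.any(times < self.t0) or np.any(times >= self.t1)):
            raise ValueError("spike times outside segment bounds [t0, t1)")
        if times.size > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("spike times must be strictly increasing")

    def in_window(self, t_a: float, t_b: float) -> np.ndarray:
        """Spike times falling in the half-open window ``[t_a, t_b)``."""
        t = self.times
        return t[(t >= t_a) & (t < t_b)]


@dataclass(frozen=True)
class IrregularityResult:
    """Value of one irregularity measure plus the evidence behind it.

    ``value`` is NaN (an explicitly undefined result, never 0) when fewer
    than one consecutive-ISI pair was available.
    """

    measure: str
    value: float
    n_pairs: int
    R: float | None = None

    @property
    def defined(self) -> bool:
        return self.n_pairs >= 1 and np.isfinite(self.value)


def extract_isis(train: SpikeTrain | Sequence[float]) -> np.ndarray:
    """Successive differences of a sorted spike-time sequence, in ms.

    Returns an empty array for trains with fewer than two spikes.  Raises
    ``ValueError`` for unsorted or duplicate times (zero ISIs break every
    measure below).
    """
    times = train.times if isinstance(train, SpikeTrain) else np.asarray(train, float)
    if times.size > 1 and np.any(np.diff(times) <= 0):
        raise ValueError("spike times must be strictly increasing (no duplicates)")
    if times.size < 2:
        return np.empty(0)
    return np.diff(times)


# ---------------------------------------------------------------------------
# Per-pair summands.  Each measure is  scale * mean(summand over pairs);
# factoring the summand out is what allows pooling pairs across trials.
# ---------------------------------------------------------------------------

def _check_isis(isis: np.ndarray) -> np.ndarray:
    isis = np.asarray(isis, dtype=float)
    if np.any(isis <= 0):
        raise ValueError("ISIs must be strictly positive")
    return isis


def _lvr_summand(a: np.ndarray, b: np.ndarray, R: float) -> np.ndarray:
    s = a + b
    # 1 - 4ab/s^2 == ((a-b)/s)^2 algebraically; the squared form cannot go
    # negative by rounding for near-equal pairs
    return ((a - b) / s) ** 2 * (1.0 + 4.0 * R / s)


def _lv_summand(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return ((a - b) / (a + b)) ** 2


def _ir_summand(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.abs(np.log(b / a))


def _si_summand(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    # >= 0 by AM-GM; floored at 0 against one-ulp rounding for equal pairs
    return np.maximum(-np.log(4.0 * a * b / (a + b) ** 2), 0.0)


#: measure name -> (scale factor, summand function taking (I_i, I_{i+1}, R))
MEASURES: dict[str, tuple[float, Callable[..., np.ndarray]]] = {
    "lvr": (3.0, lambda a, b, R: _lvr_summand(a, b, R)),
    "lv": (3.0, lambda a, b, R: _lv_summand(a, b)),
    "ir": (1.0, lambda a, b, R: _ir_summand(a, b)),
    "si": (0.5, lambda a, b, R: _si_summand(a, b)),
}


def _measure_from_pairs(
    measure: str, a: np.ndarray, b: np.ndarray, R: float
) -> IrregularityResult:
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; choose from {sorted(MEASURES)}")
    scale, summand = MEASURES[measure]
    n_pairs = a.size
    if n_pairs == 0:
        return IrregularityResult(measure, np.nan, 0, R if measure == "lvr" else None)
    value = float(scale * np.mean(summand(a, b, R)))
    return IrregularityResult(measure, value, n_pairs, R if measure == "lvr" else None)


def _from_isis(measure: str, isis: Iterable[float], R: float) -> IrregularityResult:
    isis = _check_isis(np.asarray(list(isis) if not isinstance(isis, np.ndarray) else isis))
    return _measure_from_pairs(measure, isis[:-1], isis[1:], R)


def lvr(isis: Iterable[float], R: float = DEFAULT_R_MS) -> IrregularityResult:
    """Local variation with refractoriness constant ``R`` (ms).

    ``LvR = 3/(n-1) * sum_i [1 - 4 I_i I_{i+1} / (I_i+I_{i+1})^2]
                          * [1 + 4R / (I_i+I_{i+1})]``

    With ``R = 0`` this reduces exactly to :func:`lv`.
    """
    if R < 0:
        raise ValueError("R must be non-negative")
    return _from_isis("lvr", isis, R)


def lv(isis: Iterable[float]) -> IrregularityResult:
    """Local variation: ``3/(n-1) * sum (I_i - I_{i+1})^2 / (I_i + I_{i+1})^2``."""
    return _from_isis("lv", isis, 0.0)


def ir(isis: Iterable[float]) -> IrregularityResult:
    """Mean absolute log consecutive-ISI ratio: ``1/(n-1) * sum |ln(I_{i+1}/I_i)|``."""
    return _from_isis("ir", isis, 0.0)


def si(isis: Iterable[float]) -> IrregularityResult:
    """``-1/(2(n-1)) * sum ln[4 I_i I_{i+1} / (I_i + I_{i+1})^2]`` (>= 0 by AM-GM)."""
    return _from_isis("si", isis, 0.0)


def windowed_irregularity(
    trains: Iterable[SpikeTrain],
    window: tuple[float, float],
    measure: str = "lvr",
    R: float = DEFAULT_R_MS,
) -> IrregularityResult:
    """Pooled irregularity of a set of aligned trains inside ``[t_a, t_b)``.

    A consecutive-ISI pair contributes iff all three of its defining spikes
    fall inside the window (no partial-interval truncation, which would
    censor long intervals at the edges).  Pairs are pooled across trains
    and the measure is the mean per-pair summand times the measure's scale
    factor.  Returns an undefined (NaN) result with ``n_pairs = 0`` when no
    pair is available.
    """
    t_a, t_b = window
    if not t_b > t_a:
        raise ValueError("window must have positive length")
    firsts: list[np.ndarray] = []
    seconds: list[np.ndarray] = []
    for train in trains:
        isis = np.diff(train.in_window(t_a, t_b))
        if isis.size >= 2:
            _check_isis(isis)
            firsts.append(isis[:-1])
            seconds.append(isis[1:])
    if not firsts:
        return _measure_from_pairs(measure, np.empty(0), np.empty(0), R)
    return _measure_from_pairs(measure, np.concatenate(firsts), np.concatenate(seconds), R)


def firing_rate(trains: Sequence[SpikeTrain], window: tuple[float, float]) -> float:
    """Mean spike count across trains divided by window length, in spikes/s."""
    t_a, t_b = window
    if not t_b > t_a:
        raise ValueError("window must have positive length")
    trains = list(trains)
    if not trains:
        raise ValueError("empty trial set")
    counts = [train.in_window(t_a, t_b).size for train in trains]
    return float(np.mean(counts) / (t_b - t_a) * 1000.0)


def windowed_table(
    trains_by_neuron: dict[str, Sequence[SpikeTrain]],
    windows: Sequence[tuple[float, float]],
    measures: Sequence[str] = ("lvr",),
    R: float = DEFAULT_R_MS,
) -> pd.DataFrame:
    """Long-format table of windowed irregularity per neuron.

    Columns: neuron_id, window_start, window_end, measure, value, n_pairs.
    """
    rows = []
    for neuron_id, trains in trains_by_neuron.items():
        for t_a, t_b in windows:
            for measure in measures:
                res = windowed_irregularity(trains, (t_a, t_b), measure, R)
                rows.append(
                    dict(
                        neuron_id=neuron_id,
                        window_start=t_a,
                        window_end=t_b,
                        measure=measure,
                        value=res.value,
                        n_pairs=res.n_pairs,
                    )
                )
    return pd.DataFrame(rows)
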