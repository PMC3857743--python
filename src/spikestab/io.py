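"""CSV loading, validation and result serialisation.

Input schemas (all times in ms, aligned to final-goal onset at 0):

spikes.csv
    neuron_id, trial_id, spike_time_ms
trials.csv
    trial_id, final_goal_h, final_goal_v, imm_goal_h, imm_goal_v,
    t_start_display_ms, t_final_goal_ms, t_delay_ms, t_go_ms
waveforms.csv
    neuron_id, trough_peak_ms, onset_return_ms

Validation errors carry 1-based data-row numbers so a malformed line in a
hand-edited file can be found directly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .network import GainFunction, NetworkSpec
from .selectivity import EVENT_COLUMNS, GOAL_COLUMNS, TrialDataset

__all__ = [
    "SchemaError",
    "load_spike_data",
    "load_waveforms",
    "network_from_dict",
    "load_run_config",
    "write_dataset",
    "write_manifest",
    "file_checksum",
]


class SchemaError(ValueError):
    """A CSV file does not match its declared schema."""


def _require_columns(df: pd.DataFrame, columns: tuple[str, ...], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing} (found {list(df.columns)})")


def load_spike_data(spikes_path, trials_path) -> TrialDataset:
    """Load and validate a spike table + trial table into a TrialDataset.

    Checks: non-empty files, schema, goal factors in {-1, +1}, strictly
    ordered event times, every spike referencing a known trial, and
    no duplicate spike times within a neuron/trial (1-ms resolution data
    cannot contain ties).
    """
    spikes = pd.read_csv(spikes_path)
    trials = pd.read_csv(trials_path)
    if trials.empty:
        raise SchemaError(f"{trials_path}: empty trial table")
    if spikes.empty:
        raise SchemaError(f"{spikes_path}: empty spike table")
    _require_columns(spikes, ("neuron_id", "trial_id", "spike_time_ms"), spikes_path)
    _require_columns(trials, ("trial_id", *GOAL_COLUMNS, *EVENT_COLUMNS), trials_path)

    if trials["trial_id"].duplicated().any():
        dup = trials["trial_id"][trials["trial_id"].duplicated()].iloc[0]
        raise SchemaError(f"{trials_path}: duplicate trial_id {dup!r}")
    goals = trials[list(GOAL_COLUMNS)]
    bad = goals[~goals.isin([-1, 1]).all(axis=1)]
    if len(bad):
        raise SchemaError(
            f"{trials_path}: goal factors must be -1/+1; first bad data row {bad.index[0] + 1}"
        )
    ev = trials[list(EVENT_COLUMNS)].to_numpy(float)
    bad_rows = np.flatnonzero(np.any(np.diff(ev, axis=1) <= 0, axis=1))
    if bad_rows.size:
        raise SchemaError(
            f"{trials_path}: event times not strictly ordered at data row {bad_rows[0] + 1}"
        )

    known = set(trials["trial_id"])
    unknown = ~spikes["trial_id"].isin(known)
    if unknown.any():
        row = int(np.flatnonzero(unknown)[0])
        raise SchemaError(
            f"{spikes_path}: data row {row + 1} references unknown trial_id "
            f"{spikes['trial_id'].iloc[row]!r}"
        )
    if not np.issubdtype(spikes["spike_time_ms"].dtype, np.number):
        raise SchemaError(f"{spikes_path}: spike_time_ms must be numeric")
    dup = spikes.duplicated(subset=["neuron_id", "trial_id", "spike_time_ms"])
    if dup.any():
        row = int(np.flatnonzero(dup)[0])
        raise SchemaError(
            f"{spikes_path}: duplicate spike time at data row {row + 1} "
            "(zero ISIs are not representable)"
        )
    return TrialDataset(trials=trials, spikes=spikes)


def load_waveforms(path) -> pd.DataFrame:
    wf = pd.read_csv(path)
    _require_columns(wf, ("neuron_id", "trough_peak_ms", "onset_return_ms"), path)
    if wf.empty:
        raise SchemaError(f"{path}: empty waveform table")
    return wf


def network_from_dict(cfg: dict) -> NetworkSpec:
    """Build a NetworkSpec from a plain config mapping (YAML/JSON shape).

    Expected keys: ``nodes`` (2 or 3), ``edges`` (list of mappings with
    ``from``/``to`` 1-based node indices, ``sign`` +/-1 and the gain
    parameters ``c``, ``B``, ``theta``), optional ``tau``, ``sigma`` and
    ``bias``.
    """
    try:
        n = int(cfg["nodes"])
        weights = np.zeros((n, n))
        gains = {}
        for edge in cfg["edges"]:
            i = int(edge["to"]) - 1
            j = int(edge["from"]) - 1
            weights[i, j] = float(edge["sign"])
            gains[(i, j)] = GainFunction(
                c=float(edge["c"]),
                B=float(edge.get("B", 0.0)),
                theta=float(edge.get("theta", 0.5)),
            )
    except (KeyError, TypeError, IndexError) as exc:
        raise SchemaError(f"malformed network config: {exc!r}") from exc
    bias = np.asarray(cfg.get("bias", np.zeros(n)), dtype=float)
    return NetworkSpec(
        weights=weights,
        gains=gains,
        tau=float(cfg.get("tau", 20.0)),
        sigma=float(cfg.get("sigma", 0.025)),
        bias=bias,
    )


def load_run_config(path) -> dict:
    """Load a YAML (or JSON) run configuration.

    Returns the raw mapping; if a ``network`` key is present it is
    replaced by the built :class:`NetworkSpec`.  Command-line options take
    precedence over config values (the CLI only falls back to the config
    for options the user did not pass).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: run config must be a mapping")
    if "network" in cfg:
        cfg["network"] = network_from_dict(cfg["network"])
    return cfg


def write_dataset(
    dataset: TrialDataset,
    out_dir,
    truth: pd.DataFrame | None = None,
    waveforms: pd.DataFrame | None = None,
) -> dict[str, str]:
    """Write a dataset (and optional ground truth / waveforms) as CSV files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    dataset.spikes.to_csv(out / "spikes.csv", index=False)
    written["spikes"] = str(out / "spikes.csv")
    dataset.trials.to_csv(out / "trials.csv", index=False)
    written["trials"] = str(out / "trials.csv")
    if waveforms is not None:
        waveforms.to_csv(out / "waveforms.csv", index=False)
        written["waveforms"] = str(out / "waveforms.csv")
    if truth is not None:
        truth.to_csv(out / "ground_truth.csv", index=False)
        written["ground_truth"] = str(out / "ground_truth.csv")
    return written


def file_checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path, config: dict, outputs: dict[str, str]) -> dict:
    """JSON manifest: config echo, package version, output checksums."""
    from . import __version__

    manifest = dict(
        version=__version__,
        config=config,
        outputs={name: dict(path=str(p), sha256=file_checksum(p)) for name, p in outputs.items()},
    )
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest
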