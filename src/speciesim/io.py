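"""Configuration files, run outputs and the reproducibility manifest.

Configs are YAML (JSON is a YAML subset and parses too): the top-level keys
are :class:`~speciesim.params.ModelParams` fields plus an optional nested
``stop_rule`` mapping with :class:`~speciesim.params.StopRule` fields.
Unknown keys are rejected by name. A run directory holds:

* ``trajectory.csv`` - one row per (replicate, generation): mean similarity
  and richness under both cut-offs;
* ``events.csv``     - speciation/extinction log at both cut-offs;
* ``state_rep<r>_{Q,D,labels}.csv`` - optional final-state archive;
* ``manifest.json``  - exact parameters and seeds for bit-identical re-runs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .engine import Trajectory
from .params import ConfigError, ModelParams, StopRule

__all__ = ["load_config", "save_config", "write_outputs", "config_to_dict"]

_PARAM_FIELDS = {f.name for f in dataclasses.fields(ModelParams)}
_STOP_FIELDS = {f.name for f in dataclasses.fields(StopRule)}


def load_config(path) -> tuple[ModelParams, StopRule]:
    """Parse and validate a config file; defaults are filled in.

    Raises :class:`ConfigError` naming the offending field on schema
    violations (unknown key, missing required key, out-of-range value).
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping of parameter names to values")

    stop_raw = raw.pop("stop_rule", {})
    if not isinstance(stop_raw, dict):
        raise ConfigError("stop_rule must be a mapping")
    unknown = set(raw) - _PARAM_FIELDS
    if unknown:
        raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
    unknown = set(stop_raw) - _STOP_FIELDS
    if unknown:
        raise ConfigError(f"unknown stop_rule field(s): {sorted(unknown)}")
    for required in ("mu", "mode"):
        if required not in raw:
            raise ConfigError(f"config is missing required field {required!r}")
    try:
        params = ModelParams(**raw)
        stop = StopRule(**stop_raw)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigError(str(exc)) from exc
    return params, stop


def config_to_dict(params: ModelParams, stop_rule: StopRule) -> dict:
    d = dataclasses.asdict(params)
    d["stop_rule"] = dataclasses.asdict(stop_rule)
    return d


def save_config(params: ModelParams, stop_rule: StopRule, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config_to_dict(params, stop_rule), sort_keys=True)
    )


def _events_frame(trajectories: list[Trajectory]) -> pd.DataFrame:
    rows = []
    for r, traj in enumerate(trajectories):
        for cutoff, spec_events, ext_events in (
            ("transient", traj.speciations_transient, traj.extinctions_transient),
            ("equilibrium", traj.speciations_eq, traj.extinctions_eq),
        ):
            for e in spec_events:
                rows.append(
                    dict(
                        replicate=r,
                        cutoff=cutoff,
                        event_type="speciation",
                        generation=e.generation,
                        label=e.new_label,
                        parent_label=e.parent_label,
                        abundance=e.incipient_abundance,
                        lifespan=np.nan,
                    )
                )
            for e in ext_events:
                rows.append(
                    dict(
                        replicate=r,
                        cutoff=cutoff,
                        event_type="extinction",
                        generation=e.generation,
                        label=e.label,
                        parent_label=np.nan,
                        abundance=np.nan,
                        lifespan=e.lifespan_generations,
                    )
                )
    columns = [
        "replicate",
        "cutoff",
        "event_type",
        "generation",
        "label",
        "parent_label",
        "abundance",
        "lifespan",
    ]
    return pd.DataFrame(rows, columns=columns)


def _trajectory_frame(trajectories: list[Trajectory]) -> pd.DataFrame:
    frames = []
    for r, traj in enumerate(trajectories):
        frames.append(
            pd.DataFrame(
                {
                    "replicate": r,
                    "generation": np.arange(1, traj.generations + 1),
                    "q_bar": traj.q_bar,
                    "richness_transient": traj.richness_transient,
                    "richness_eq": traj.richness_eq,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_outputs(
    trajectories: list[Trajectory], outdir, save_final_state: bool = True
) -> dict:
    """Write the CSV products and manifest for a set of replicates.

    Returns the manifest dict (also written to ``manifest.json``). Re-running
    with the manifest's params and seeds reproduces every file byte for byte.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not trajectories:
        manifest = {
            "package_version": __version__,
            "replicates": 0,
            "files": [],
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest

    files = []
    traj_path = outdir / "trajectory.csv"
    _trajectory_frame(trajectories).to_csv(traj_path, index=False)
    files.append(traj_path.name)
    events_path = outdir / "events.csv"
    _events_frame(trajectories).to_csv(events_path, index=False)
    files.append(events_path.name)

    if save_final_state:
        for r, traj in enumerate(trajectories):
            state = traj.final_state
            if state is None:
                continue
            for name, arr, fmt in (
                ("Q", state.q, "%.10g"),
                ("D", state.d, "%.10g"),
                ("labels", state.labels, "%d"),
            ):
                p = outdir / f"state_rep{r}_{name}.csv"
                np.savetxt(p, np.atleast_1d(arr), fmt=fmt, delimiter=",")
                files.append(p.name)

    first = trajectories[0]
    manifest = {
        "package_version": __version__,
        "params": dataclasses.asdict(first.params),
        "stop_rule": dataclasses.asdict(first.stop_rule),
        "replicates": len(trajectories),
        "seeds": [t.seed for t in trajectories],
        "converged": [bool(t.converged) for t in trajectories],
        "generations": [int(t.generations) for t in trajectories],
        "files": files,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return manifest
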