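"""Scenario (de)serialization, trajectory export and fixture generation.

Scenario files are YAML mappings; a file may either name a library
scenario (``scenario: continuous``) and override fields, or spell out a
full configuration.  CSV is the canonical trajectory interchange (one
column per state variable plus derived observables); an HDF5 container is
available for long traces.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError
from .simulator import ScenarioConfig, TimeSeries, scenario_library, \
    SCENARIO_LABELS
from .state import STATE_NAMES
from .vessel import VasomotionProtocol

__all__ = ["load_config", "save_config", "write_timeseries",
           "read_timeseries", "generate_fixtures", "RunManifest"]

_CONFIG_KEYS = {f.name for f in dataclasses.fields(ScenarioConfig)}


def _config_to_dict(config: ScenarioConfig) -> dict:
    d = dataclasses.asdict(config)
    if d.get("vasomotion") is None:
        d.pop("vasomotion", None)
    return d


def load_config(path: str | Path) -> ScenarioConfig:
    """Read and validate a scenario file.

    Unknown keys are rejected with a message naming the key; a
    ``scenario`` key pulls defaults from the published scenario library
    before overrides are applied.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: scenario file must be a mapping")

    base: dict = {}
    if "scenario" in raw:
        name = raw.pop("scenario")
        library = scenario_library()
        if name not in library:
            raise ConfigError(
                f"{path}: unknown scenario {name!r}; "
                f"expected one of {sorted(library)}")
        base = _config_to_dict(library[name])
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")
    base.update(raw)
    if isinstance(base.get("vasomotion"), dict):
        try:
            base["vasomotion"] = VasomotionProtocol(**base["vasomotion"])
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"{path}: invalid vasomotion protocol: {exc}")
    try:
        return ScenarioConfig(**base)
    except (TypeError, ConfigError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def save_config(config: ScenarioConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_config_to_dict(config), fh, sort_keys=False)


def write_timeseries(series: TimeSeries, path: str | Path,
                     format: str = "csv") -> None:
    """Export a sampled trajectory.

    ``csv`` writes one header row (state glossary plus derived
    observables) and is lossless at the sampled points; ``hdf5`` writes a
    compact binary container for long traces.
    """
    path = Path(path)
    if format == "csv":
        series.to_dataframe().to_csv(path, index=False,
                                     float_format="%.17g")
    elif format == "hdf5":
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("t", data=series.t)
            fh.create_dataset("y", data=series.y)
            fh.attrs["state_names"] = list(STATE_NAMES)
            fh.attrs["config"] = json.dumps(_config_to_dict(series.config))
    else:
        raise ValueError(f"unknown format {format!r}")


def read_timeseries(path: str | Path):
    """Round-trip reader for the CSV export (returns a DataFrame)."""
    import pandas as pd

    return pd.read_csv(path)


@dataclasses.dataclass
class RunManifest:
    """Everything needed to re-run a simulation bit-identically."""

    config: dict
    seed: int
    package_version: str
    solver: dict

    @classmethod
    def for_run(cls, series: TimeSeries) -> "RunManifest":
        from . import __version__

        cfg = series.config
        return cls(config=_config_to_dict(cfg), seed=cfg.seed,
                   package_version=__version__,
                   solver={"method": cfg.solver_method, "rtol": cfg.rtol,
                           "atol": cfg.atol, "max_step": cfg.max_step})

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def generate_fixtures(out_dir: str | Path) -> list[Path]:
    """Emit the five published scenarios with their expected firing-regime
    labels, plus small synthetic traces used by unit tests.

    Regeneration is idempotent: contents depend only on the library
    defaults.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, cfg in scenario_library().items():
        path = out_dir / f"{name}.yaml"
        save_config(cfg, path)
        written.append(path)
    labels_path = out_dir / "expected_labels.json"
    with open(labels_path, "w") as fh:
        json.dump(SCENARIO_LABELS, fh, indent=2, sort_keys=True)
    written.append(labels_path)

    # synthetic template spike train: N spikes at 80 Hz on a flat baseline
    t = np.arange(0.0, 0.5, 1e-4)
    v = np.full_like(t, -70.0)
    spike_times = np.arange(0.05, 0.3, 1.0 / 80.0)
    for ts in spike_times:
        mask = (t >= ts) & (t < ts + 1e-3)
        v[mask] = 30.0
    trace_path = out_dir / "synthetic_spike_trace.csv"
    np.savetxt(trace_path, np.column_stack([t, v]), delimiter=",",
               header="t,V_m", comments="")
    written.append(trace_path)
    return written
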