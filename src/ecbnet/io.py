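"""Configuration files, trace stores and run manifests.

Configs are YAML/JSON mappings of :class:`~ecbnet.network.NetworkConfig`
fields (with a nested ``params`` mapping for synapse constants); unknown keys
are rejected.  Traces are written to HDF5 with one dataset per recorded
variable plus metadata tables, and a JSON manifest captures the resolved
configuration, seed, package version and per-file checksums so a run can be
reproduced bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .network import NetworkConfig, SimulationResult
from .params import GoodwinParams, SynapseParams

__all__ = ["RunManifest", "load_config", "save_config", "config_to_dict",
           "write_results", "read_results"]


def config_to_dict(config: NetworkConfig) -> dict:
    d = dataclasses.asdict(config)
    d["exc_rate_range"] = list(d["exc_rate_range"])
    d["inh_rate_range"] = list(d["inh_rate_range"])
    return d


def _config_from_dict(data: dict) -> NetworkConfig:
    data = dict(data)
    p = data.pop("params", {}) or {}
    if not isinstance(p, dict):
        raise ValueError("'params' must be a mapping")
    gw = p.pop("goodwin", {}) or {}
    _check_keys(gw, GoodwinParams, "params.goodwin")
    _check_keys(p, SynapseParams, "params")
    _check_keys(data, NetworkConfig, "config")
    params = SynapseParams(goodwin=GoodwinParams(**gw), **p)
    for key in ("exc_rate_range", "inh_rate_range"):
        if key in data:
            data[key] = tuple(data[key])
    return NetworkConfig(params=params, **data)


def _check_keys(data: dict, cls, where: str) -> None:
    allowed = {f.name for f in dataclasses.fields(cls)}
    if cls is SynapseParams:
        allowed.discard("goodwin")
    if cls is NetworkConfig:
        allowed.discard("params")
    unknown = sorted(set(data) - allowed)
    if unknown:
        raise ValueError(f"unknown {where} keys: {', '.join(unknown)}")


def load_config(path) -> NetworkConfig:
    """Load and validate a YAML/JSON configuration file.

    An empty file yields the full default configuration; every model constant
    can be overridden through the ``params`` (and ``params.goodwin``) blocks.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    return _config_from_dict(data)


def save_config(config: NetworkConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))


@dataclass
class RunManifest:
    """Reproducibility record for one simulation run."""

    config: dict
    seed: int
    version: str = __version__
    started: str = ""
    finished: str = ""
    files: dict = field(default_factory=dict)  # name -> sha256

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_results(result: SimulationResult, out_dir,
                  summaries: pd.DataFrame | None = None) -> RunManifest:
    """Write traces (HDF5), metadata/summaries (CSV) and a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = time.strftime("%Y-%m-%dT%H:%M:%S")

    traces = out / "traces.h5"
    with h5py.File(traces, "w") as f:
        f.create_dataset("times", data=result.times)
        g = f.create_group("traces")
        for name, arr in result.data.items():
            g.create_dataset(name, data=arr)
        sp = f.create_group("neuron_spikes")
        for i, s in enumerate(result.neuron_spikes):
            sp.create_dataset(str(i), data=np.asarray(s, dtype=float))
    result.glut_meta.to_csv(out / "glut_synapses.csv", index=False)
    result.gaba_meta.to_csv(out / "gaba_synapses.csv", index=False)
    files = ["traces.h5", "glut_synapses.csv", "gaba_synapses.csv"]
    if summaries is not None:
        summaries.to_csv(out / "summaries.csv", index=False)
        files.append("summaries.csv")

    manifest = RunManifest(
        config=config_to_dict(result.config),
        seed=result.config.seed,
        started=started,
        finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
        files={name: _sha256(out / name) for name in files},
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


def read_results(out_dir):
    """Re-read a written run: (config, times, traces, neuron spike arrays)."""
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    config = _config_from_dict(manifest["config"])
    with h5py.File(out / "traces.h5", "r") as f:
        times = f["times"][...]
        data = {name: ds[...] for name, ds in f["traces"].items()}
        spikes = [f["neuron_spikes"][k][...]
                  for k in sorted(f["neuron_spikes"], key=int)]
    return config, times, data, spikes
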