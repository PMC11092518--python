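"""HDF5 persistence for simulation results and connectivity exports."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .engine import ProbeTrace, SimResult, SpikeRecord
from .errors import FormatError
from .synapses import SynapseGroup

__all__ = ["save_run", "load_run", "edges_to_csv", "edges_from_csv"]


def save_run(result: SimResult, path: str | Path) -> None:
    """Write spikes, probe traces and the run manifest to one HDF5 file."""
    with h5py.File(path, "w") as f:
        f.attrs["manifest"] = json.dumps(result.manifest)
        sp = f.create_group("spikes")
        sp.attrs["duration_ms"] = result.spikes.duration_ms
        for name, times in result.spikes.times_ms.items():
            g = sp.create_group(name)
            g.create_dataset("time_ms", data=times)
            g.create_dataset("index", data=result.spikes.indices[name])
        pr = f.create_group("probes")
        for i, trace in enumerate(result.probes):
            g = pr.create_group(str(i))
            g.attrs["population"] = trace.population
            g.attrs["neuron"] = trace.neuron
            g.attrs["sheet_pos"] = list(trace.sheet_pos)
            g.create_dataset("t_ms", data=trace.t_ms)
            g.create_dataset("v", data=trace.v)
            cur = g.create_group("currents")
            for key, arr in trace.currents.items():
                # "/" in channel keys would create nested groups
                cur.create_dataset(key.replace("/", "|"), data=arr)


def load_run(path: str | Path) -> SimResult:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such run archive")
    with h5py.File(path, "r") as f:
        manifest = json.loads(f.attrs["manifest"])
        times = {name: g["time_ms"][:] for name, g in f["spikes"].items()}
        indices = {name: g["index"][:] for name, g in f["spikes"].items()}
        record = SpikeRecord(
            times_ms=times,
            indices=indices,
            duration_ms=float(f["spikes"].attrs["duration_ms"]),
        )
        probes = []
        for key in sorted(f["probes"], key=int):
            g = f["probes"][key]
            probes.append(
                ProbeTrace(
                    population=g.attrs["population"],
                    neuron=int(g.attrs["neuron"]),
                    sheet_pos=tuple(g.attrs["sheet_pos"]),
                    t_ms=g["t_ms"][:],
                    v=g["v"][:],
                    currents={k.replace("|", "/"): d[:] for k, d in g["currents"].items()},
                )
            )
    return SimResult(spikes=record, probes=probes, manifest=manifest)


def edges_to_csv(group: SynapseGroup, path: str | Path) -> None:
    pd.DataFrame(
        {"pre_index": group.pre, "post_index": group.post, "weight": group.weight}
    ).to_csv(path, index=False)


def edges_from_csv(path: str | Path, n_pre: int, n_post: int, params, **kwargs) -> SynapseGroup:
    df = pd.read_csv(path)
    missing = {"pre_index", "post_index", "weight"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return SynapseGroup(
        name=kwargs.pop("name", str(path)),
        pre=df["pre_index"].to_numpy(),
        post=df["post_index"].to_numpy(),
        weight=df["weight"].to_numpy(),
        n_pre=n_pre,
        n_post=n_post,
        params=params,
        **kwargs,
    )
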