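"""Serialization: rasters and rate traces as CSV, events as JSON,
networks as HDF5, run logs with config echo.

CSV dialect: comma-separated, header row, '.' decimal, no index column.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import sparse

from .analysis import ReplayEvent
from .network import NetworkModel, ConnectivityParams
from .lif import CellParams
from .simulator import SimResult

__all__ = [
    "write_raster_csv", "read_raster_csv", "write_rate_csv",
    "write_events_json", "read_events_json", "write_voltage_csv",
    "network_to_hdf5", "network_from_hdf5", "write_outputs",
]


def write_raster_csv(result: SimResult, path) -> None:
    rows = []
    for pop, arr in (("PC", result.pc_spikes), ("INH", result.inh_spikes)):
        if arr.size:
            rows.append(pd.DataFrame({
                "pop": pop,
                "neuron_id": arr[:, 0].astype(int),
                "t_ms": arr[:, 1],
            }))
    df = (pd.concat(rows, ignore_index=True) if rows
          else pd.DataFrame(columns=["pop", "neuron_id", "t_ms"]))
    df.to_csv(path, index=False)


def read_raster_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_rate_csv(result: SimResult, path) -> None:
    t = np.arange(result.n_steps) * result.dt
    pd.DataFrame({"t_ms": t, "pc_rate_hz": result.pc_rate}).to_csv(
        path, index=False)


def write_voltage_csv(t: np.ndarray, v: np.ndarray, path) -> None:
    pd.DataFrame({"time_ms": t, "v_mV": v}).to_csv(path, index=False)


def write_events_json(events: list[ReplayEvent], path) -> None:
    payload = [
        {
            "t_start_ms": ev.t_start,
            "t_end_ms": ev.t_end,
            "n_spikes": ev.n_spikes,
            "speed_mps": ev.speed,
            "blowup": ev.blowup,
        }
        for ev in events
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_events_json(path) -> list[dict]:
    return json.loads(Path(path).read_text())


def _write_sparse(group: h5py.Group, name: str, mat: sparse.spmatrix):
    coo = mat.tocoo()
    g = group.create_group(name)
    g.create_dataset("row", data=coo.row)
    g.create_dataset("col", data=coo.col)
    g.create_dataset("data", data=coo.data)
    g.attrs["shape"] = coo.shape


def _read_sparse(group: h5py.Group) -> sparse.csr_matrix:
    return sparse.coo_matrix(
        (group["data"][:], (group["row"][:], group["col"][:])),
        shape=tuple(group.attrs["shape"]),
    ).tocsr()


def network_to_hdf5(model: NetworkModel, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("peaks", data=model.peaks)
        f.create_dataset("gate_weight", data=model.gate_weight)
        _write_sparse(f, "w_rec", model.w_rec)
        _write_sparse(f, "w_inh_from_pc", model.w_inh_from_pc)
        _write_sparse(f, "w_pc_from_inh", model.w_pc_from_inh)
        f.attrs["bounds"] = model.bounds
        for obj, prefix in ((model.conn, "conn"), (model.pc_params, "pc"),
                            (model.inh_params, "inh")):
            for k, v in vars(obj).items():
                f.attrs[f"{prefix}.{k}"] = v


def network_from_hdf5(path) -> NetworkModel:
    with h5py.File(path, "r") as f:
        def collect(prefix, cls):
            kwargs = {
                k.split(".", 1)[1]: f.attrs[k]
                for k in f.attrs if k.startswith(prefix + ".")
            }
            return cls(**kwargs)
        return NetworkModel(
            peaks=f["peaks"][:],
            w_rec=_read_sparse(f["w_rec"]),
            w_inh_from_pc=_read_sparse(f["w_inh_from_pc"]),
            w_pc_from_inh=_read_sparse(f["w_pc_from_inh"]),
            gate_weight=f["gate_weight"][:],
            conn=collect("conn", ConnectivityParams),
            pc_params=collect("pc", CellParams),
            inh_params=collect("inh", CellParams),
            bounds=float(f.attrs["bounds"]),
        )


def write_outputs(result: SimResult, events: list[ReplayEvent] | None,
                  config, out_dir) -> Path:
    """Write the standard output bundle for one run.

    raster.csv, rate.csv, events.json (if events given), config.yaml echo
    and run.log (seed, library versions).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_raster_csv(result, out / "raster.csv")
    write_rate_csv(result, out / "rate.csv")
    if events is not None:
        write_events_json(events, out / "events.json")
    if config is not None:
        config.to_yaml(out / "config.yaml")
    (out / "run.log").write_text(
        f"seed={result.seed}\n"
        f"duration_ms={result.duration}\n"
        f"python={platform.python_version()}\n"
        f"numpy={np.__version__}\n"
    )
    return out
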