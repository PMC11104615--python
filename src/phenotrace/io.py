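"""HDF5 container and CSV exchange formats, plus run fingerprints.

One HDF5 group per sample with datasets ``/traces`` (cells × 3 × T),
``/time``, ``/positions``, ``/labels``, and optional ``/impact_calcium``;
labels are also exportable as CSV. A short content fingerprint travels with
every derived artifact so pipeline stages refuse mixed runs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .preprocess import TraceMatrix
from .synthetic import CellTrace, GeneratorConfig, SyntheticDataset
from .vae import LatentTable


def fingerprint(*arrays: np.ndarray) -> str:
    """Short stable hash of array contents (shape-sensitive)."""
    h = hashlib.sha256()
    for a in arrays:
        a = np.ascontiguousarray(a)
        h.update(str(a.shape).encode())
        h.update(a.tobytes())
    return h.hexdigest()[:16]


class FingerprintMismatch(RuntimeError):
    pass


def check_fingerprint(expected: str, actual: str, context: str) -> None:
    if expected != actual:
        raise FingerprintMismatch(
            f"{context}: fingerprint {actual} does not match upstream {expected}; "
            "artifacts come from different runs"
        )


def load_generator_config(path: str | Path) -> GeneratorConfig:
    """Read a GeneratorConfig from YAML."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "phenotype_names" in raw:
        raw["phenotype_names"] = tuple(raw["phenotype_names"])
    if "phenotype_weights" in raw and raw["phenotype_weights"] is not None:
        raw["phenotype_weights"] = tuple(raw["phenotype_weights"])
    if "impact_xy" in raw:
        raw["impact_xy"] = tuple(raw["impact_xy"])
    return GeneratorConfig(**raw)


def save_dataset(dataset: SyntheticDataset, path: str | Path, group: str = "sample") -> None:
    with h5py.File(path, "w") as fh:
        g = fh.create_group(group)
        g.create_dataset("traces", data=dataset.trace_array())
        g.create_dataset("time", data=dataset.time_grid())
        g.create_dataset("positions", data=dataset.positions)
        g.create_dataset("labels", data=np.asarray(dataset.labels, dtype="S"))
        g.create_dataset("sites", data=np.array([t.site for t in dataset.traces], dtype="S"))
        g.create_dataset("impact_cell_ids", data=dataset.impact_cell_ids)
        g.create_dataset("impact_calcium", data=dataset.impact_calcium)
        g.create_dataset("sharpness_truth", data=dataset.sharpness_truth)
        g.attrs["impact_xy"] = dataset.impact_xy
        if dataset.config is not None:
            g.attrs["seed"] = dataset.config.seed
            g.attrs["noise_sd"] = dataset.config.noise_sd
        g.attrs["fingerprint"] = fingerprint(dataset.trace_array())


def load_dataset(path: str | Path, group: str = "sample") -> SyntheticDataset:
    with h5py.File(path, "r") as fh:
        g = fh[group]
        traces_arr = g["traces"][...]
        time = g["time"][...]
        positions = g["positions"][...]
        labels = g["labels"][...].astype(str)
        sites = g["sites"][...].astype(str)
        traces = [
            CellTrace(
                cell_id=i,
                time=time,
                values=traces_arr[i],
                position=tuple(positions[i]),
                site=sites[i],
            )
            for i in range(len(traces_arr))
        ]
        return SyntheticDataset(
            traces=traces,
            labels=labels,
            positions=positions,
            impact_xy=tuple(g.attrs["impact_xy"]),
            impact_cell_ids=g["impact_cell_ids"][...],
            impact_calcium=g["impact_calcium"][...],
            sharpness_truth=g["sharpness_truth"][...],
        )


def save_matrix(matrix: TraceMatrix, path: str | Path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=matrix.data)
        fh.create_dataset("time", data=matrix.time)
        fh.create_dataset("cell_ids", data=np.asarray(matrix.cell_ids))
        if matrix.positions is not None:
            fh.create_dataset("positions", data=matrix.positions)
        if matrix.sites is not None:
            fh.create_dataset("sites", data=np.asarray(matrix.sites, dtype="S"))
        if matrix.labels is not None:
            fh.create_dataset("labels", data=np.asarray(matrix.labels, dtype="S"))
        fh.attrs["channel_order"] = list(matrix.channel_order)
        fh.attrs["fingerprint"] = fingerprint(matrix.data)


def load_matrix(path: str | Path) -> TraceMatrix:
    with h5py.File(path, "r") as fh:
        return TraceMatrix(
            data=fh["data"][...],
            time=fh["time"][...],
            cell_ids=fh["cell_ids"][...],
            positions=fh["positions"][...] if "positions" in fh else None,
            sites=fh["sites"][...].astype(str) if "sites" in fh else None,
            labels=fh["labels"][...].astype(str) if "labels" in fh else None,
            channel_order=tuple(fh.attrs["channel_order"]),
        )


def matrix_fingerprint(path: str | Path) -> str:
    with h5py.File(path, "r") as fh:
        return str(fh.attrs["fingerprint"])


def save_latents(table: LatentTable, path: str | Path, data_fingerprint: str | None = None) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("cell_ids", data=np.asarray(table.cell_ids))
        fh.create_dataset("mu", data=table.mu)
        fh.create_dataset("var", data=table.var)
        if data_fingerprint is not None:
            fh.attrs["data_fingerprint"] = data_fingerprint


def load_latents(path: str | Path) -> tuple[LatentTable, str | None]:
    with h5py.File(path, "r") as fh:
        table = LatentTable(fh["cell_ids"][...], fh["mu"][...], fh["var"][...])
        fp = str(fh.attrs["data_fingerprint"]) if "data_fingerprint" in fh.attrs else None
        return table, fp


def load_trace_csv(path: str | Path, cell_id: int = 0) -> CellTrace:
    """Read one external cell trace from CSV with columns time, ch1..ch3.

    ``time`` is in hours; ch1..ch3 follow the fixed channel order
    (calcium, mito, nmp).
    """
    df = pd.read_csv(path)
    required = ["time", "ch1", "ch2", "ch3"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"trace CSV missing columns: {missing}")
    return CellTrace(
        cell_id=cell_id,
        time=df["time"].to_numpy(dtype=float),
        values=df[["ch1", "ch2", "ch3"]].to_numpy(dtype=float).T,
    )


def export_labels_csv(labels: np.ndarray, cell_ids: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"cell_id": cell_ids, "label": labels}).to_csv(path, index=False)


def write_report(report: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(report, indent=2, default=_default))
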