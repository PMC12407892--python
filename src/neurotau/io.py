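"""Readers and writers for the interchange formats.

Spikes travel as two-column TSV (unit_id, spike_time_s); trial tables and
per-neuron results as CSV; voxel grids as an .npz container with a JSON
sidecar (dims, voxel size, feature names); reports as JSON. All writes
are atomic (temp file + rename).
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from .anatomy import NeuronPlacements, VoxelGrid
from .selectivity import TrialTable
from .spikes import SpikeTrain

__all__ = [
    "read_spike_tsv", "write_spike_tsv",
    "read_trial_csv", "write_trial_csv",
    "write_timescale_csv", "read_timescale_csv",
    "write_grid", "read_grid",
    "write_placements_csv", "read_placements_csv",
    "write_json", "read_json", "atomic_write_text",
]

MAX_COMPONENTS = 4


def atomic_write_text(path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=".tmp-")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_spike_tsv(trains, path) -> None:
    rows = []
    for t in trains:
        rows.append(pd.DataFrame({"unit_id": t.unit_id,
                                  "spike_time_s": t.spike_times}))
    df = pd.concat(rows, ignore_index=True) if rows else \
        pd.DataFrame(columns=["unit_id", "spike_time_s"])
    atomic_write_text(path, df.to_csv(sep="\t", index=False))


def read_spike_tsv(path, duration: float) -> dict:
    """Spike TSV -> {unit_id: SpikeTrain} with the given duration."""
    df = pd.read_csv(path, sep="\t")
    if not {"unit_id", "spike_time_s"} <= set(df.columns):
        raise ValueError("spike TSV needs columns unit_id, spike_time_s")
    out = {}
    for uid, grp in df.groupby("unit_id", sort=False):
        out[uid] = SpikeTrain(unit_id=uid,
                              spike_times=np.sort(np.asarray(
                                  grp["spike_time_s"], dtype=float)),
                              duration=duration)
    return out


def write_trial_csv(table: TrialTable, path) -> None:
    atomic_write_text(path, table.df.to_csv(index=False))


def read_trial_csv(path) -> TrialTable:
    return TrialTable(pd.read_csv(path))


def write_timescale_csv(records, path) -> None:
    """Per-neuron fit table: unit_id, M, tau_1..4, c_1..4, r2, tau_eff, qc_pass."""
    rows = []
    for rec in records:
        row = {"unit_id": rec.unit_id, "M": rec.M, "r2": rec.r_squared,
               "tau_eff": rec.tau_eff if np.sum(rec.coeffs) > 0 else np.nan,
               "qc_pass": rec.qc_pass}
        for i in range(MAX_COMPONENTS):
            row[f"tau_{i + 1}"] = rec.taus[i] if i < rec.M else np.nan
            row[f"c_{i + 1}"] = rec.coeffs[i] if i < rec.M else np.nan
        rows.append(row)
    cols = (["unit_id", "M"]
            + [f"tau_{i + 1}" for i in range(MAX_COMPONENTS)]
            + [f"c_{i + 1}" for i in range(MAX_COMPONENTS)]
            + ["r2", "tau_eff", "qc_pass"])
    df = pd.DataFrame(rows, columns=cols)
    atomic_write_text(path, df.to_csv(index=False))


def read_timescale_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_grid(grid: VoxelGrid, prefix) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.savez(str(prefix) + ".npz", fields=grid.fields)
    sidecar = {"dims": list(grid.dims),
               "voxel_size_um": grid.voxel_size_um,
               "feature_names": list(grid.feature_names)}
    atomic_write_text(str(prefix) + ".json", json.dumps(sidecar, indent=2))


def read_grid(prefix) -> VoxelGrid:
    with np.load(str(prefix) + ".npz") as z:
        fields = z["fields"]
    with open(str(prefix) + ".json") as fh:
        sidecar = json.load(fh)
    return VoxelGrid(fields=fields, voxel_size_um=sidecar["voxel_size_um"],
                     feature_names=tuple(sidecar["feature_names"]))


def write_placements_csv(placements: NeuronPlacements, path) -> None:
    df = pd.DataFrame({"unit_id": placements.unit_ids,
                       "voxel_index": placements.voxel_indices,
                       "tau_eff": placements.tau_eff})
    atomic_write_text(path, df.to_csv(index=False))


def read_placements_csv(path) -> NeuronPlacements:
    df = pd.read_csv(path)
    return NeuronPlacements(unit_ids=np.asarray(df["unit_id"]),
                            voxel_indices=np.asarray(df["voxel_index"]),
                            tau_eff=np.asarray(df["tau_eff"]))


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_json(obj, path) -> None:
    atomic_write_text(path, json.dumps(_jsonify(obj), indent=2))


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
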