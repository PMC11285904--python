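"""Plain-text serialization of datasets and populations.

Snapshot datasets are written as long-format tab-separated text
(columns: cell_id, time_index, time, species, value) plus a YAML
metadata sidecar, and round-trip bit-exactly (values are printed with
17 significant digits).  Species are canonicalized to the
(Nanog, Oct4-Sox2, Fgf4, Gata6) order on read regardless of row order
in the file.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import SPECIES
from .simulate import SnapshotDataset
from .smc import Population

__all__ = [
    "write_snapshot",
    "read_snapshot",
    "write_population",
    "read_population",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.yaml")


def write_snapshot(dataset: SnapshotDataset, path) -> None:
    path = Path(path)
    S, T, n = dataset.values.shape
    sp, t_idx, cell = np.meshgrid(
        np.arange(S), np.arange(T), np.arange(n), indexing="ij"
    )
    df = pd.DataFrame(
        {
            "cell_id": cell.ravel(),
            "time_index": t_idx.ravel(),
            "time": dataset.time_grid[t_idx.ravel()],
            "species": np.array(SPECIES)[sp.ravel()],
            "value": dataset.values.ravel(),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    meta = {
        "time_grid": [float(f"{t:.17g}") for t in dataset.time_grid],
        "n_cells": int(n),
        "n_times": int(T),
        "meta": _to_plain(dataset.meta),
    }
    _sidecar(path).write_text(yaml.safe_dump(meta, sort_keys=False))


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def read_snapshot(path) -> SnapshotDataset:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except Exception as e:  # noqa: BLE001 - rewrap with file context
        raise ValueError(f"{path}: cannot parse snapshot file: {e}") from e
    required = {"cell_id", "time_index", "time", "species", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = set(df["species"].unique()) - set(SPECIES)
    if bad:
        raise ValueError(f"{path}: unknown species {sorted(bad)}")
    n = int(df["cell_id"].max()) + 1
    T = int(df["time_index"].max()) + 1
    values = np.full((len(SPECIES), T, n), np.nan)
    sp_code = df["species"].map({s: i for i, s in enumerate(SPECIES)}).to_numpy()
    values[sp_code, df["time_index"].to_numpy(), df["cell_id"].to_numpy()] = (
        df["value"].to_numpy()
    )
    if np.any(np.isnan(values)):
        raise ValueError(f"{path}: incomplete tensor (missing entries)")
    meta_path = _sidecar(path)
    meta: dict = {}
    if meta_path.exists():
        raw = yaml.safe_load(meta_path.read_text()) or {}
        time_grid = np.asarray(raw.get("time_grid"), dtype=float)
        meta = raw.get("meta", {}) or {}
    else:
        time_grid = (
            df.drop_duplicates("time_index").sort_values("time_index")["time"]
            .to_numpy(dtype=float)
        )
    return SnapshotDataset(values=values, time_grid=time_grid, meta=meta)


def write_population(pop: Population, names, path) -> None:
    """One generation as tab-separated text: particles, weights, distances."""
    path = Path(path)
    df = pd.DataFrame(pop.thetas, columns=list(names))
    df["weight"] = pop.weights
    df["distance"] = pop.distances
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    _sidecar(path).write_text(
        yaml.safe_dump(
            {
                "tolerance": float(pop.tolerance),
                "generation": int(pop.generation),
                "n_sims": int(pop.n_sims),
                "status": pop.status,
            },
            sort_keys=False,
        )
    )


def read_population(path) -> tuple[Population, list]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    names = [c for c in df.columns if c not in ("weight", "distance")]
    side = yaml.safe_load(_sidecar(path).read_text())
    pop = Population(
        thetas=df[names].to_numpy(),
        weights=df["weight"].to_numpy(),
        distances=df["distance"].to_numpy(),
        tolerance=float(side["tolerance"]),
        generation=int(side["generation"]),
        n_sims=int(side["n_sims"]),
        status=str(side["status"]),
    )
    return pop, names
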