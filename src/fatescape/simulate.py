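"""Stochastic simulation and snapshot sampling.

Two simulators are provided for the 4-gene jump process: the exact
Gillespie direct method and a chemical-Langevin (Euler–Maruyama)
approximation in which each reaction channel contributes drift
``nu_i * a_i(x)`` and noise ``nu_i * sqrt(a_i(x)) dW_i``.

Snapshot datasets mimic single-cell experiments: an ensemble of
independent cells simulated from a common initial condition and read
out at a fixed grid of times, with no trajectory linkage used
downstream.  The reference scheme is 300 cells at 10 evenly spaced
time points (a 4 × 10 × 300 tensor).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _kernels
from .model import SPECIES, VECTOR_FIELDS, ModelParameters

__all__ = [
    "Trajectory",
    "SnapshotDataset",
    "default_time_grid",
    "gillespie_trajectory",
    "cle_trajectory",
    "sample_snapshots",
    "generate_reference",
    "simulate_dataset",
]

#: Default initial state (N, O, F, G): a single Oct4–Sox2 molecule seeds
#: the cascade from the undifferentiated origin.
DEFAULT_X0 = (0.0, 1.0, 0.0, 0.0)

#: Default simulation horizon, in the time units of the rate equations
#: (= 1/gamma, long enough for fate commitment).
DEFAULT_T_END = 100.0


@dataclass
class Trajectory:
    """One cell's state path: ``states[i]`` is the state at ``times[i]``.

    For Gillespie output the path is piecewise constant between events;
    for the Langevin approximation it is a discretized diffusion.
    """

    times: np.ndarray
    states: np.ndarray  # (n_times, 4)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.times.shape[0], 4):
            raise ValueError("states must be (len(times), 4)")

    @property
    def t_end(self) -> float:
        return float(self.times[-1])

    def state_at(self, t: float) -> np.ndarray:
        """State at time ``t`` under the left-continuous hold convention
        (the state after the last recorded time <= t)."""
        if t > self.times[-1]:
            raise ValueError(f"time {t} beyond trajectory end {self.times[-1]}")
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        return self.states[max(idx, 0)]


@dataclass
class SnapshotDataset:
    """Snapshot tensor ``values`` of shape (4 species, T times, n cells)."""

    values: np.ndarray
    time_grid: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        if self.values.ndim != 3 or self.values.shape[0] != len(SPECIES):
            raise ValueError("values must have shape (4, T, n_cells)")
        if self.values.shape[1] != self.time_grid.shape[0]:
            raise ValueError("time grid length must match values.shape[1]")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("snapshot values must be finite and >= 0")

    @property
    def n_cells(self) -> int:
        return self.values.shape[2]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    def slice_at(self, t_index: int) -> np.ndarray:
        """Cells × species matrix at one time index."""
        return self.values[:, t_index, :].T.copy()

    def final_slice(self) -> np.ndarray:
        return self.slice_at(self.n_times - 1)


def default_time_grid(T: int = 10, t_end: float = DEFAULT_T_END) -> np.ndarray:
    """T evenly spaced sample times on (0, t_end]: t_k = k * t_end / T."""
    if T < 1:
        raise ValueError("T must be >= 1")
    return np.arange(1, T + 1) * (t_end / T)


def _child_seeds(seed: int, n: int) -> np.ndarray:
    """Per-cell seeds from the master seed.

    Stream i is a deterministic function of (seed, i) alone, so adding
    cells or reordering calls never reshuffles existing streams.
    """
    ss = np.random.SeedSequence(seed)
    return np.array([c.generate_state(1)[0] for c in ss.spawn(n)], dtype=np.int64)


def gillespie_trajectory(
    params: ModelParameters,
    x0: Sequence[float] = DEFAULT_X0,
    t_end: float = DEFAULT_T_END,
    seed: int = 0,
) -> Trajectory:
    """Statistically exact sample path of the jump process (direct method).

    ``x0`` must be integer-valued; the returned record starts at t = 0
    and is padded with the final state at ``t_end``.  A state with zero
    total propensity freezes (valid absorbing behavior, not an error).
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 < 0) or x0.shape != (4,):
        raise ValueError("x0 must be 4 nonnegative components")
    if np.any(x0 != np.round(x0)):
        raise ValueError("x0 must be integer-valued for the jump process")
    times, states = _kernels.gillespie_events(
        params.to_vector(), x0, float(t_end), int(seed) & 0x7FFFFFFF
    )
    return Trajectory(times=times, states=states)


def cle_trajectory(
    params: ModelParameters,
    x0: Sequence[float] = DEFAULT_X0,
    t_end: float = DEFAULT_T_END,
    dt: float = 0.01,
    seed: int = 0,
    noise_scale: float = 1.0,
) -> Trajectory:
    """Chemical-Langevin path via Euler–Maruyama.

    Each reaction contributes drift ``nu_i a_i(x)`` and independent noise
    ``nu_i sqrt(a_i(x)) dW_i``; states are clipped at zero after every
    step, which also zeroes propensities that would otherwise go
    negative.  ``noise_scale=0`` reduces to the explicit-Euler ODE path.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 < 0) or x0.shape != (4,):
        raise ValueError("x0 must be 4 nonnegative components")
    rng = np.random.default_rng(seed)
    n_steps = int(np.ceil(t_end / dt))
    times = np.minimum(np.arange(n_steps + 1) * dt, t_end)
    pv = params.to_vector()
    states = np.empty((n_steps + 1, 4))
    x = x0.copy()
    states[0] = x
    for k in range(n_steps):
        h = times[k + 1] - times[k]
        a = _kernels.propensities_vec(x, pv)
        drift = a[:4] - a[4:]
        if noise_scale != 0.0:
            z = rng.standard_normal(8)
            noise = np.sqrt(a * h) * z
            x = x + drift * h + noise_scale * (noise[:4] - noise[4:])
        else:
            x = x + drift * h
        x = np.maximum(x, 0.0)
        states[k + 1] = x
    return Trajectory(times=times, states=states)


def sample_snapshots(
    trajectories: Sequence[Trajectory], time_grid: Sequence[float]
) -> SnapshotDataset:
    """Read an ensemble of trajectories out on a common time grid.

    Entry (s, t, i) is trajectory i's state after the last recorded time
    at or before ``time_grid[t]`` (piecewise-constant hold).
    """
    grid = np.asarray(time_grid, dtype=float)
    n = len(trajectories)
    if n == 0:
        raise ValueError("need at least one trajectory")
    values = np.empty((4, grid.shape[0], n))
    for i, tr in enumerate(trajectories):
        if tr.t_end < grid.max():
            raise ValueError(
                f"trajectory {i} ends at {tr.t_end} < max grid time {grid.max()}"
            )
        for t_idx, t in enumerate(grid):
            values[:, t_idx, i] = tr.state_at(t)
    return SnapshotDataset(values=values, time_grid=grid)


def simulate_dataset(
    params: ModelParameters,
    n_cells: int = 300,
    time_grid: np.ndarray | None = None,
    x0: Sequence[float] = DEFAULT_X0,
    seed: int = 0,
) -> SnapshotDataset:
    """Gillespie snapshot ensemble: ``n_cells`` independent cells sampled
    on ``time_grid`` (default: 10 evenly spaced points on (0, 100])."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if time_grid is None:
        time_grid = default_time_grid()
    grid = np.asarray(time_grid, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    pv = params.to_vector()
    seeds = _child_seeds(seed, n_cells) & 0x7FFFFFFF
    values = _kernels.gillespie_ensemble(pv, x0, grid, seeds)
    return SnapshotDataset(
        values=values,
        time_grid=grid,
        meta={
            "seed": int(seed),
            "n_cells": int(n_cells),
            "x0": [float(v) for v in x0],
            "LIF": float(params.LIF),
            "params": dict(zip(VECTOR_FIELDS, params.to_vector().tolist())),
        },
    )


def generate_reference(
    params: ModelParameters | None = None,
    n_cells: int = 300,
    T: int = 10,
    t_end: float = DEFAULT_T_END,
    seed: int = 0,
    x0: Sequence[float] = DEFAULT_X0,
) -> SnapshotDataset:
    """Reference snapshot data at the true parameters.

    Defaults reproduce the study conditions: 300 Gillespie cells,
    10 evenly spaced time points, LIF = 50.
    """
    if params is None:
        params = ModelParameters()
    if T < 1:
        raise ValueError("T must be >= 1")
    ds = simulate_dataset(
        params, n_cells=n_cells, time_grid=default_time_grid(T, t_end), x0=x0,
        seed=seed,
    )
    ds.meta["role"] = "reference"
    ds.meta["t_end"] = float(t_end)
    return ds
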