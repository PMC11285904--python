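"""Validation experiments for the inference pipeline.

Three checks are provided:

* **Distance separation** — can a metric tell "same parameters" from
  "prior parameters"?  Replicate datasets at the true parameters are
  compared with each other and with prior-predictive datasets; the
  histogram overlap of the two distance distributions should be small,
  and the median same-parameter distance is the natural final ABC
  tolerance for that metric.
* **Posterior predictive check** — the pluripotency statistic
  ``S(X) = log(p / (1 - p))``, with ``p`` the fraction of cells ending
  in the high-Nanog K-means cluster, is compared between the reference
  and datasets simulated from posterior draws (tail probability and
  mean squared error).
* **Euclidean summary baseline** — a conventional summary-statistic
  distance (per species/time moments, or the pluripotency statistic
  itself) against which the distribution-level metrics are judged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import iqr
from sklearn.cluster import KMeans

from .distances import snapshot_distance
from .model import SPECIES, ModelParameters
from .simulate import DEFAULT_X0, SnapshotDataset, simulate_dataset
from .smc import Population, PriorSpec

__all__ = [
    "SeparationResult",
    "PPCResult",
    "separation_experiment",
    "suggest_epsilon",
    "pluripotency_statistic",
    "posterior_predictive_check",
    "euclidean_summary_distance",
    "overlap_coefficient",
]


def overlap_coefficient(a, b) -> float:
    """Histogram-intersection overlap of two samples in [0, 1].

    Shared Freedman–Diaconis bins over the pooled range; the overlap is
    ``sum_i min(p_i, q_i)`` of the probability-normalized histograms.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    lo, hi = pooled.min(), pooled.max()
    if hi <= lo:
        return 1.0
    width = 2.0 * iqr(pooled) / len(pooled) ** (1.0 / 3.0)
    n_bins = int(np.ceil((hi - lo) / width)) if width > 0 else 10
    n_bins = min(max(n_bins, 1), 10_000)
    edges = np.linspace(lo, hi, n_bins + 1)
    pa, _ = np.histogram(a, bins=edges)
    pb, _ = np.histogram(b, bins=edges)
    return float(np.minimum(pa / len(a), pb / len(b)).sum())


@dataclass
class SeparationResult:
    """Distance distributions under replicate vs prior parameters."""

    metric: str
    distances_true_vs_true: np.ndarray
    distances_prior_vs_true: np.ndarray
    n_replicates: int
    overlap: float
    meta: dict = field(default_factory=dict)

    @property
    def suggested_epsilon(self) -> float:
        """Median same-parameter distance: the calibrated final tolerance."""
        return float(np.median(self.distances_true_vs_true))


def separation_experiment(
    params_true: ModelParameters | None = None,
    prior: PriorSpec | None = None,
    metric: str = "sinkhorn",
    n_rep: int = 50,
    n_cells: int = 100,
    seed: int = 0,
    time_grid: np.ndarray | None = None,
    x0=DEFAULT_X0,
    metric_options: dict | None = None,
) -> SeparationResult:
    """Distance-separation calibration.

    Computes ``n_rep`` distances between independent replicate pairs at
    the true parameters, and ``n_rep`` distances between
    prior-predictive datasets and a fixed true-parameter reference.
    """
    if n_rep < 2:
        raise ValueError("n_rep must be >= 2")
    if params_true is None:
        params_true = ModelParameters()
    if prior is None:
        prior = PriorSpec.from_reference(params_true)
    metric_options = dict(metric_options or {})
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])

    def sim(params, i):
        # dataset stream i depends only on (seed, i)
        child = np.random.SeedSequence(seed, spawn_key=(1, i))
        return simulate_dataset(
            params, n_cells=n_cells, time_grid=time_grid, x0=x0,
            seed=int(child.generate_state(1)[0]) & 0x7FFFFFFF,
        )

    d_tt = np.empty(n_rep)
    for r in range(n_rep):
        A = sim(params_true, 2 * r)
        B = sim(params_true, 2 * r + 1)
        d_tt[r] = snapshot_distance(A, B, metric=metric, **metric_options)

    reference = sim(params_true, 2 * n_rep)
    d_pt = np.empty(n_rep)
    for r in range(n_rep):
        theta = prior.sample(rng)
        cand = sim(prior.to_params(theta, params_true), 2 * n_rep + 1 + r)
        d_pt[r] = snapshot_distance(reference, cand, metric=metric, **metric_options)

    return SeparationResult(
        metric=metric,
        distances_true_vs_true=d_tt,
        distances_prior_vs_true=d_pt,
        n_replicates=n_rep,
        overlap=overlap_coefficient(d_tt, d_pt),
        meta={"n_cells": n_cells, "seed": seed},
    )


def suggest_epsilon(result: SeparationResult) -> float:
    """Suggested final ABC tolerance: the median replicate distance."""
    return result.suggested_epsilon


def pluripotency_statistic(
    data: SnapshotDataset, dims=("Nanog", "Gata6"), seed: int = 0
) -> float:
    """Logit of the pluripotent-cell fraction at the final time point.

    Cells are split by K-means (k = 2) on the selected gene pair; the
    cluster with the higher Nanog centroid is the pluripotent one and
    ``p`` its cell fraction.  ``p`` is clipped to
    [1/(2n), 1 - 1/(2n)] so the logit stays finite even when one
    cluster is empty or the cells coincide.
    """
    pts = data.final_slice()
    idx = [SPECIES.index(d) if isinstance(d, str) else int(d) for d in dims]
    pts = pts[:, idx]
    n = pts.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells at the final time point")
    clip = 1.0 / (2.0 * n)
    if np.allclose(pts, pts[0]):
        p = 1.0 - clip  # all cells identical: degenerate single cluster
    else:
        km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(pts)
        nanog_axis = 0  # first selected dim is the pluripotency marker
        hi = int(np.argmax(km.cluster_centers_[:, nanog_axis]))
        p = float(np.mean(km.labels_ == hi))
        p = min(max(p, clip), 1.0 - clip)
    return float(np.log(p / (1.0 - p)))


@dataclass
class PPCResult:
    """Posterior predictive distribution of the pluripotency statistic."""

    S_reference: float
    S_posterior_draws: np.ndarray
    tail_prob: float  # Pr(S(X) > S(D))
    mse: float  # mean squared deviation of draws from S_reference
    n_failures: int = 0
    meta: dict = field(default_factory=dict)


def posterior_predictive_check(
    population: Population,
    reference: SnapshotDataset,
    n_draws: int = 50,
    seed: int = 0,
    base_params: ModelParameters | None = None,
    prior: PriorSpec | None = None,
    n_cells: int | None = None,
    x0=DEFAULT_X0,
) -> PPCResult:
    """Simulate from posterior draws and compare the pluripotency statistic.

    Particles are resampled by weight; each simulated dataset yields one
    draw of ``S``.  ``prior`` supplies the parameter-name mapping (its
    ``to_params``); simulator failures are counted and skipped.
    """
    if population.size == 0:
        raise ValueError("population is empty")
    if base_params is None:
        base_params = ModelParameters()
    if prior is None:
        prior = PriorSpec.from_reference(base_params)
    m = n_cells if n_cells is not None else reference.n_cells
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    sim_ss = np.random.SeedSequence(seed, spawn_key=(1,))
    S_ref = pluripotency_statistic(reference)
    draws = []
    failures = 0
    children = sim_ss.spawn(n_draws)
    for i in range(n_draws):
        j = rng.choice(population.size, p=population.weights)
        params = prior.to_params(population.thetas[j], base_params)
        try:
            ds = simulate_dataset(
                params, n_cells=m, time_grid=reference.time_grid, x0=x0,
                seed=int(children[i].generate_state(1)[0]) & 0x7FFFFFFF,
            )
            draws.append(pluripotency_statistic(ds))
        except (ValueError, FloatingPointError):
            failures += 1
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise RuntimeError("all posterior predictive simulations failed")
    return PPCResult(
        S_reference=S_ref,
        S_posterior_draws=draws,
        tail_prob=float(np.mean(draws > S_ref)),
        mse=float(np.mean((draws - S_ref) ** 2)),
        n_failures=failures,
        meta={"n_draws": n_draws, "seed": seed},
    )


def euclidean_summary_distance(
    D1: SnapshotDataset, D2: SnapshotDataset, summary: str = "moments"
) -> float:
    """Summary-statistic baseline distance between snapshot datasets.

    ``"moments"``: Euclidean norm of the difference of the stacked
    per-species, per-time-point (mean, mean-square) summary vectors.
    ``"logit_p"``: absolute difference of the pluripotency statistics.
    """
    if D1.values.shape[:2] != D2.values.shape[:2]:
        raise ValueError("datasets disagree on species/time shape")
    if summary == "moments":
        s1 = np.concatenate(
            [D1.values.mean(axis=2).ravel(), (D1.values ** 2).mean(axis=2).ravel()]
        )
        s2 = np.concatenate(
            [D2.values.mean(axis=2).ravel(), (D2.values ** 2).mean(axis=2).ravel()]
        )
        return float(np.linalg.norm(s1 - s2))
    if summary == "logit_p":
        return float(abs(pluripotency_statistic(D1) - pluripotency_statistic(D2)))
    raise ValueError(f"unknown summary {summary!r}")
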