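"""Likelihood-free inference: ABC rejection and ABC–SMC.

The sampler is generic over a ``simulate(theta, seed) -> dataset``
callable and a ``distance(dataset) -> float`` callable (the reference
data live in the distance closure), so the same machinery serves both
the 4-gene snapshot problem and analytically tractable toy problems.

ABC–SMC follows the standard sequential scheme: an initial rejection
generation at a pilot-calibrated tolerance, then repeated
resample–perturb–reweight sweeps with the tolerance set to the 30%
quantile (configurable) of the previous generation's accepted
distances, until a target tolerance is reached or the simulation
budget (default 10^7) is exhausted.

Two perturbation kernels are available.  The default is a multivariate
Gaussian with covariance twice the weighted posterior covariance: in
this model several parameters are strongly correlated (compensating
rate pairs), and proposals that respect the posterior correlation keep
the late-generation acceptance rate workable.  A component-wise
Gaussian kernel (per-parameter SD = sqrt(2 × weighted variance)) is
available via ``kernel="component"``.
"""

from __future__ import annotations

import inspect
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .distances import snapshot_distance
from .model import PARAM_NAMES, ModelParameters
from .simulate import DEFAULT_X0, SnapshotDataset, simulate_dataset

__all__ = [
    "PriorSpec",
    "Population",
    "sample_prior",
    "perturb",
    "abc_rejection",
    "abc_smc",
    "make_grn_problem",
]

DEFAULT_MAX_SIMS = 10_000_000


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform priors, one interval per inferred parameter."""

    names: tuple
    low: np.ndarray
    high: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "low", np.asarray(self.low, dtype=float))
        object.__setattr__(self, "high", np.asarray(self.high, dtype=float))
        if not (len(self.names) == self.low.shape[0] == self.high.shape[0]):
            raise ValueError("names, low, high must have equal length")
        if np.any(self.low >= self.high):
            raise ValueError("prior requires low < high for every parameter")
        if np.any(self.low < 0):
            raise ValueError("kinetic constants require nonnegative bounds")

    @property
    def dim(self) -> int:
        return len(self.names)

    @property
    def range(self) -> np.ndarray:
        return self.high - self.low

    @classmethod
    def from_reference(
        cls,
        params: ModelParameters | None = None,
        names: Sequence[str] = PARAM_NAMES,
        factor: float = 10.0,
    ) -> "PriorSpec":
        """Bounds [theta*/factor, factor*theta*] around a reference set."""
        if params is None:
            params = ModelParameters()
        ref = np.array([getattr(params, k) for k in names], dtype=float)
        if np.any(ref <= 0):
            raise ValueError("reference values must be > 0 to scale bounds")
        return cls(names=tuple(names), low=ref / factor, high=ref * factor)

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(self.low, self.high)

    def contains(self, theta: np.ndarray) -> bool:
        theta = np.asarray(theta, dtype=float)
        return bool(np.all(theta >= self.low) and np.all(theta <= self.high))

    def to_params(
        self, theta: np.ndarray, base: ModelParameters | None = None
    ) -> ModelParameters:
        """Model parameters with the inferred subset set from ``theta``."""
        if base is None:
            base = ModelParameters()
        return base.replace(**dict(zip(self.names, np.asarray(theta, float).tolist())))


def sample_prior(prior: PriorSpec, seed: int | np.random.Generator = 0) -> np.ndarray:
    """One independent uniform draw from the prior (reproducible by seed)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return prior.sample(rng)


@dataclass
class Population:
    """One ABC generation: weighted particles with realized distances."""

    thetas: np.ndarray  # (N, p)
    weights: np.ndarray  # (N,), sums to 1
    distances: np.ndarray  # (N,)
    tolerance: float
    generation: int
    n_sims: int  # cumulative simulations consumed up to this generation
    status: str = "ok"  # "ok" | "max_sims"
    kernel_sd: np.ndarray | None = None  # proposal SDs used to build this generation

    def __post_init__(self):
        self.thetas = np.atleast_2d(np.asarray(self.thetas, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        if self.weights.shape[0] != self.thetas.shape[0]:
            raise ValueError("weights/thetas length mismatch")
        if self.thetas.shape[0] and abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")

    @property
    def size(self) -> int:
        return self.thetas.shape[0]

    def weighted_mean(self) -> np.ndarray:
        return self.weights @ self.thetas

    def weighted_var(self) -> np.ndarray:
        mu = self.weighted_mean()
        return self.weights @ (self.thetas - mu) ** 2

    def credible_interval(self, level: float = 0.95) -> np.ndarray:
        """Per-parameter weighted quantile interval, shape (p, 2)."""
        lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
        out = np.empty((self.thetas.shape[1], 2))
        for k in range(self.thetas.shape[1]):
            order = np.argsort(self.thetas[:, k])
            cw = np.cumsum(self.weights[order])
            cw /= cw[-1]
            out[k, 0] = self.thetas[order, k][np.searchsorted(cw, lo_q)]
            out[k, 1] = self.thetas[order, k][min(np.searchsorted(cw, hi_q),
                                                  self.size - 1)]
        return out


def _kernel_sd(thetas: np.ndarray, weights: np.ndarray, prior: PriorSpec) -> np.ndarray:
    """Component-wise Gaussian kernel SD: sqrt(2 x weighted variance),
    with a 1%-of-prior-range floor for degenerate components."""
    mu = weights @ thetas
    var = weights @ (thetas - mu) ** 2
    sd = np.sqrt(2.0 * var)
    fallback = 0.01 * prior.range
    return np.where(sd > 0, sd, fallback)


def perturb(
    theta: np.ndarray,
    previous: Population,
    seed: int | np.random.Generator = 0,
    prior: PriorSpec | None = None,
) -> np.ndarray:
    """Component-wise Gaussian perturbation of one particle.

    The kernel SD is adapted to the previous population's weighted
    spread (sqrt of twice the weighted variance); components with zero
    spread fall back to 1% of the prior range (the prior defaults to
    the population's empirical bounding box if not given).
    """
    if previous.size == 0:
        raise ValueError("previous population is empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if prior is None:
        lo = previous.thetas.min(axis=0)
        hi = previous.thetas.max(axis=0)
        span = np.where(hi > lo, hi - lo, np.maximum(np.abs(hi), 1.0))
        prior = PriorSpec(
            names=tuple(f"p{k}" for k in range(previous.thetas.shape[1])),
            low=np.zeros_like(span),
            high=span,
        )
    sd = _kernel_sd(previous.thetas, previous.weights, prior)
    return np.asarray(theta, dtype=float) + sd * rng.standard_normal(len(sd))


class _SimSeeds:
    """Deterministic per-simulation seed stream keyed by the master seed."""

    def __init__(self, seed_seq: np.random.SeedSequence):
        self._ss = seed_seq
        self._cache: list[int] = []

    def __getitem__(self, i: int) -> int:
        while len(self._cache) <= i:
            # spawn() continues the child numbering across calls
            block = self._ss.spawn(256)
            self._cache.extend(int(c.generate_state(1)[0]) & 0x7FFFFFFF for c in block)
        return self._cache[i]


def abc_rejection(
    simulate: Callable[[np.ndarray, int], object],
    distance: Callable[[object], float],
    prior: PriorSpec,
    epsilon: float,
    N: int,
    max_sims: int = DEFAULT_MAX_SIMS,
    seed: int = 0,
    trace: list | None = None,
) -> Population:
    """Plain ABC rejection: draw from the prior until N acceptances.

    Accepted particles carry equal weights 1/N and their realized
    distances.  If ``max_sims`` is exhausted first, the partial
    population is returned with ``status="max_sims"`` (not an error).
    When ``trace`` is a list, one record (generation, simulation seed,
    parameters, realized distance) is appended per simulated candidate
    — an append-only run ledger for post-hoc diagnostics.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if not epsilon > 0:
        raise ValueError("epsilon must be > 0")
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    sim_seeds = _SimSeeds(np.random.SeedSequence(seed, spawn_key=(1,)))
    call = _distance_caller(distance)
    accepted, dists = [], []
    n_sims = 0
    while len(accepted) < N and n_sims < max_sims:
        theta = prior.sample(rng)
        s = sim_seeds[n_sims]
        d = call(simulate(theta, s), epsilon if np.isfinite(epsilon) else None)
        n_sims += 1
        if trace is not None:
            trace.append(
                {"generation": 0, "seed": s, "theta": theta.tolist(),
                 "distance": d}
            )
        if d <= epsilon:
            accepted.append(theta)
            dists.append(d)
    n_acc = len(accepted)
    status = "ok" if n_acc == N else "max_sims"
    if n_acc == 0:
        return Population(
            thetas=np.empty((0, prior.dim)), weights=np.empty(0),
            distances=np.empty(0), tolerance=float(epsilon), generation=0,
            n_sims=n_sims, status=status,
        )
    return Population(
        thetas=np.array(accepted),
        weights=np.full(n_acc, 1.0 / n_acc),
        distances=np.array(dists),
        tolerance=float(epsilon),
        generation=0,
        n_sims=n_sims,
        status=status,
    )


def _kernel_chol(
    thetas: np.ndarray, weights: np.ndarray, range_vec: np.ndarray
) -> np.ndarray:
    """Cholesky factor of the multivariate kernel covariance
    (2 × weighted posterior covariance, diagonally regularized)."""
    mu = weights @ thetas
    D = thetas - mu
    cov = 2.0 * (D * weights[:, None]).T @ D
    # degenerate components fall back to 1% of the support range
    floor = np.where(np.diag(cov) <= 0, (0.01 * range_vec) ** 2, 0.0)
    jitter = 1e-12 * max(np.trace(cov), 1.0)
    while True:
        try:
            return np.linalg.cholesky(cov + np.diag(floor + jitter))
        except np.linalg.LinAlgError:
            jitter *= 100


def _log_mixture_density(x, centers, weights, L: np.ndarray) -> float:
    """log sum_j w_j N(x | centers_j, L L^T)."""
    from scipy.linalg import solve_triangular

    diff = np.asarray(x)[None, :] - centers
    y = solve_triangular(L, diff.T, lower=True)
    logk = -0.5 * np.sum(y ** 2, axis=0) - np.sum(np.log(np.diag(L))) \
        - 0.5 * len(x) * np.log(2 * np.pi)
    m = logk.max()
    return float(m + np.log(np.sum(weights * np.exp(logk - m))))


def _log_kernel_density(
    theta: np.ndarray, prev: Population, sd: np.ndarray
) -> float:
    """log sum_j w_j K(theta | theta_j) for the product-Gaussian kernel."""
    z = (theta[None, :] - prev.thetas) / sd[None, :]
    logk = -0.5 * np.sum(z ** 2, axis=1) - np.sum(np.log(sd)) \
        - 0.5 * len(sd) * np.log(2 * np.pi)
    m = logk.max()
    return float(m + np.log(np.sum(prev.weights * np.exp(logk - m))))


def _distance_caller(distance: Callable) -> Callable:
    """Wrap ``distance`` so a ``cutoff`` keyword is forwarded when the
    callable supports one (early rejection) and dropped otherwise."""
    try:
        params = inspect.signature(distance).parameters
        accepts = "cutoff" in params or any(
            p.kind is inspect.Parameter.VAR_KEYWORD for p in params.values()
        )
    except (TypeError, ValueError):
        accepts = False
    if accepts:
        return lambda ds, cutoff: float(distance(ds, cutoff=cutoff))
    return lambda ds, cutoff: float(distance(ds))


def abc_smc(
    simulate: Callable[[np.ndarray, int], object],
    distance: Callable[[object], float],
    prior: PriorSpec,
    epsilon_target: float,
    N: int,
    quantile_alpha: float = 0.3,
    max_sims: int = DEFAULT_MAX_SIMS,
    seed: int = 0,
    pilot_factor: int = 10,
    max_generations: int = 50,
    kernel: str = "mvn",
    defensive_beta: float = 0.1,
    callback: Callable[[Population], None] | None = None,
    trace: list | None = None,
) -> list[Population]:
    """Sequential ABC with an adaptive quantile tolerance schedule.

    Generation 0 performs rejection at the ``quantile_alpha`` quantile
    of a pilot of ``pilot_factor * N`` prior-predictive distances (the
    pilot draws double as generation-0 candidates).  Each later
    tolerance is the same quantile of the previous generation's
    accepted distances; particles are proposed by weighted resampling
    plus Gaussian perturbation and reweighted by prior density over
    proposal density.  Stops once a generation's tolerance is at or
    below ``epsilon_target``, the simulation budget is hit, or the
    schedule stalls.

    ``defensive_beta`` mixes a fraction of fresh prior draws into the
    proposal (defensive importance sampling): the importance weights
    are then bounded by 1/beta, which keeps the effective sample size
    of the weighted population from collapsing in 16 dimensions.  Set
    it to 0 for the plain resample-perturb proposal (faster tolerance
    descent; weighted posterior summaries become unreliable).

    ``callback`` is invoked with each completed generation;
    ``trace``, if a list, receives one record (generation, simulation
    seed, parameters, realized distance) per simulated candidate — an
    append-only run ledger for post-hoc diagnostics.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    if not 0 < quantile_alpha < 1:
        raise ValueError("quantile_alpha must be in (0, 1)")
    if kernel not in ("mvn", "component"):
        raise ValueError("kernel must be 'mvn' or 'component'")
    if not 0 <= defensive_beta < 1:
        raise ValueError("defensive_beta must be in [0, 1)")
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    sim_seeds = _SimSeeds(np.random.SeedSequence(seed, spawn_key=(1,)))
    call = _distance_caller(distance)
    n_sims = 0

    # --- pilot / generation 0 ------------------------------------------
    # The first `warm` draws are evaluated in full; afterwards a cutoff
    # at the warmup median censors clearly-bad candidates early.  A
    # censored value is a partial sum above the cutoff, hence above the
    # final eps0 (a lower quantile), so the schedule start is unbiased
    # and censored draws can never enter generation 0.
    n_pilot = min(pilot_factor * N, max_sims)
    warm = min(max(2 * N, 50), n_pilot)
    pilot_thetas = np.empty((n_pilot, prior.dim))
    pilot_d = np.empty(n_pilot)
    censored = np.zeros(n_pilot, dtype=bool)
    cutoff0 = None
    for i in range(n_pilot):
        pilot_thetas[i] = prior.sample(rng)
        s = sim_seeds[n_sims]
        pilot_d[i] = call(simulate(pilot_thetas[i], s), cutoff0)
        censored[i] = cutoff0 is not None and pilot_d[i] > cutoff0
        n_sims += 1
        if trace is not None:
            trace.append(
                {"generation": 0, "seed": s,
                 "theta": pilot_thetas[i].tolist(), "distance": pilot_d[i]}
            )
        if i == warm - 1:
            cutoff0 = float(np.quantile(pilot_d[: i + 1], 0.5))
    eps0 = float(np.quantile(pilot_d, quantile_alpha))
    keep = np.flatnonzero((pilot_d <= eps0) & ~censored)[:N]
    pop = Population(
        thetas=pilot_thetas[keep],
        weights=np.full(len(keep), 1.0 / len(keep)),
        distances=pilot_d[keep],
        tolerance=eps0,
        generation=0,
        n_sims=n_sims,
        status="ok" if len(keep) == N else "max_sims",
    )
    populations = [pop]
    if callback is not None:
        callback(pop)
    if pop.status != "ok" or eps0 <= epsilon_target:
        return populations

    # --- sequential generations ----------------------------------------
    for gen in range(1, max_generations + 1):
        prev = populations[-1]
        eps = float(np.quantile(prev.distances, quantile_alpha))
        if not eps < prev.tolerance:
            prev.status = "stalled"
            break
        if kernel == "mvn":
            L = _kernel_chol(prev.thetas, prev.weights, prior.range)
            sd = np.sqrt(np.sum(L ** 2, axis=1))  # marginal SDs, bookkeeping
        else:
            sd = _kernel_sd(prev.thetas, prev.weights, prior)
        thetas = np.empty((N, prior.dim))
        dists = np.empty(N)
        logw = np.empty(N)
        log_prior_dens = -float(np.sum(np.log(prior.range)))
        i = 0
        budget_hit = False
        while i < N:
            if n_sims >= max_sims:
                budget_hit = True
                break
            if defensive_beta > 0 and rng.random() < defensive_beta:
                theta = prior.sample(rng)
            else:
                j = rng.choice(prev.size, p=prev.weights)
                if kernel == "mvn":
                    theta = prev.thetas[j] + L @ rng.standard_normal(prior.dim)
                else:
                    theta = prev.thetas[j] + sd * rng.standard_normal(prior.dim)
                if not prior.contains(theta):
                    continue  # zero prior weight: re-propose, no sim consumed
            s = sim_seeds[n_sims]
            d = call(simulate(theta, s), eps)
            n_sims += 1
            if trace is not None:
                trace.append(
                    {"generation": gen, "seed": s, "theta": theta.tolist(),
                     "distance": d}
                )
            if d <= eps:
                thetas[i] = theta
                dists[i] = d
                if kernel == "mvn":
                    log_mix = _log_mixture_density(theta, prev.thetas,
                                                   prev.weights, L)
                else:
                    log_mix = _log_kernel_density(theta, prev, sd)
                if defensive_beta > 0:
                    log_q = np.logaddexp(
                        np.log1p(-defensive_beta) + log_mix,
                        np.log(defensive_beta) + log_prior_dens,
                    )
                else:
                    log_q = log_mix
                # uniform prior: w = pi(theta) / q(theta)
                logw[i] = log_prior_dens - log_q
                i += 1
        if i == 0:
            break
        w = np.exp(logw[:i] - logw[:i].max())
        w /= w.sum()
        pop = Population(
            thetas=thetas[:i],
            weights=w,
            distances=dists[:i],
            tolerance=eps,
            generation=gen,
            n_sims=n_sims,
            status="max_sims" if budget_hit else "ok",
            kernel_sd=sd,
        )
        populations.append(pop)
        if callback is not None:
            callback(pop)
        if budget_hit or eps <= epsilon_target:
            break
    return populations


def make_grn_problem(
    reference: SnapshotDataset,
    metric: str = "sinkhorn",
    metric_options: dict | None = None,
    base_params: ModelParameters | None = None,
    names: Sequence[str] = PARAM_NAMES,
    n_cells: int | None = None,
    x0: Sequence[float] = DEFAULT_X0,
    prior_factor: float = 10.0,
):
    """Wire the 4-gene snapshot problem for the ABC samplers.

    Returns ``(simulate, distance, prior)``: candidate datasets are
    simulated with the same time grid as the reference (``n_cells``
    defaults to the reference's), and the distance is the per-time-point
    sum under ``metric``.  The prior spans [theta*/10, 10·theta*] around
    ``base_params`` for the inferred ``names``.
    """
    if base_params is None:
        base_params = ModelParameters()
    metric_options = dict(metric_options or {})
    prior = PriorSpec.from_reference(base_params, names=names, factor=prior_factor)
    m = n_cells if n_cells is not None else reference.n_cells
    grid = reference.time_grid.copy()

    def simulate(theta: np.ndarray, seed: int) -> SnapshotDataset:
        params = prior.to_params(theta, base_params)
        return simulate_dataset(params, n_cells=m, time_grid=grid, x0=x0, seed=seed)

    def distance(dataset: SnapshotDataset, cutoff: float | None = None) -> float:
        return snapshot_distance(
            reference, dataset, metric=metric, cutoff=cutoff, **metric_options
        )

    return simulate, distance, prior
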