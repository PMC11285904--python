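"""Posterior variance decomposition and sloppy/stiff classification.

The posterior sample covariance is eigendecomposed (PCA on parameter
space) and each parameter's sensitivity score is the fraction of total
posterior variance it carries,

    s_k = sum_j q_{k,j}^2 lambda_j / sum_i lambda_i,

which algebraically equals Sigma_kk / trace(Sigma).  Parameters whose
score exceeds a 1% threshold are classified as *sloppy* (weakly
constrained by the data, high posterior variance share); the rest are
*stiff*.  Scores are reported either on the raw parameter scale
(default — small-magnitude rates naturally score low) or standardized
by the prior range so that the partition is unit-free.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import numpy as np
from scipy.stats import spearmanr

__all__ = [
    "SensitivityReport",
    "posterior_covariance",
    "sensitivity_scores",
    "classify_sloppy",
    "pairwise_posterior_summary",
    "sensitivity_report",
]

SLOPPY_THRESHOLD = 0.01


def _check_samples(samples, weights=None):
    X = np.atleast_2d(np.asarray(samples, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if weights is None:
        w = np.full(X.shape[0], 1.0 / X.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape[0] != X.shape[0]:
            raise ValueError("weights length mismatch")
        if abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("weights must sum to 1")
    return X, w


def posterior_covariance(samples, weights=None) -> np.ndarray:
    """Weighted method-of-moments covariance (normalized by total weight).

    With equal weights this is the 1/n sample covariance.  Symmetric
    positive semidefinite by construction.
    """
    X, w = _check_samples(samples, weights)
    mu = w @ X
    D = X - mu
    S = (D * w[:, None]).T @ D
    if not np.all(np.isfinite(S)):
        raise ValueError("non-finite covariance")
    return 0.5 * (S + S.T)


def sensitivity_scores(
    samples, weights=None, standardize: bool = False, scale: np.ndarray | None = None
) -> np.ndarray:
    """Per-parameter share of total posterior variance, via PCA.

    Eigendecomposes the covariance and accumulates each parameter's
    squared loadings weighted by the eigenvalues; the result sums to 1.
    With ``standardize=True`` parameters are first divided by ``scale``
    (e.g. the prior ranges; defaults to per-parameter standard
    deviation), making the scores invariant to unit changes.
    """
    X, w = _check_samples(samples, weights)
    if standardize:
        if scale is None:
            scale = np.sqrt(np.diag(posterior_covariance(X, w)))
            scale = np.where(scale > 0, scale, 1.0)
        X = X / np.asarray(scale, dtype=float)[None, :]
    S = posterior_covariance(X, w)
    lam, Q = np.linalg.eigh(S)
    # s_k = sum_j Q[k, j]^2 lam[j] / sum(lam)  (== S_kk / tr S)
    total = lam.sum()
    if total <= 0:
        raise ValueError("covariance has zero trace; degenerate posterior")
    s = (Q ** 2) @ lam / total
    return s


def classify_sloppy(s, threshold: float = SLOPPY_THRESHOLD) -> list[str]:
    """Label "sloppy" iff the score strictly exceeds the threshold."""
    s = np.asarray(s, dtype=float)
    if np.any(s < 0) or np.any(s > 1):
        raise ValueError("scores must lie in [0, 1]")
    return ["sloppy" if v > threshold else "stiff" for v in s]


@dataclass
class SensitivityReport:
    """Covariance, spectrum, per-parameter scores and labels."""

    names: tuple
    covariance: np.ndarray
    eigenvalues: np.ndarray  # sorted descending
    eigenvectors: np.ndarray  # columns matched to eigenvalues
    scores: np.ndarray
    labels: list
    threshold: float

    def to_table(self) -> str:
        """Structured-text table: parameter, score, percent, label."""
        buf = StringIO()
        buf.write("parameter\tscore\tpercent\tlabel\n")
        for name, s, lab in zip(self.names, self.scores, self.labels):
            buf.write(f"{name}\t{s:.6g}\t{100 * s:.3f}\t{lab}\n")
        return buf.getvalue()


def sensitivity_report(
    samples,
    weights=None,
    names=None,
    standardize: bool = False,
    threshold: float = SLOPPY_THRESHOLD,
) -> SensitivityReport:
    """Full sensitivity analysis of one posterior sample."""
    X, w = _check_samples(samples, weights)
    p = X.shape[1]
    if names is None:
        names = tuple(f"p{k}" for k in range(p))
    S = posterior_covariance(X, w)
    lam, Q = np.linalg.eigh(S)
    order = np.argsort(lam)[::-1]
    lam, Q = lam[order], Q[:, order]
    s = sensitivity_scores(X, w, standardize=standardize)
    return SensitivityReport(
        names=tuple(names),
        covariance=S,
        eigenvalues=lam,
        eigenvectors=Q,
        scores=s,
        labels=classify_sloppy(s, threshold),
        threshold=threshold,
    )


def pairwise_posterior_summary(samples, bins: int = 30):
    """Spearman rank-correlation matrix plus marginal histogram data.

    Returns ``(rho, hists)`` where ``rho`` is the p×p rank correlation
    matrix and ``hists`` a list of (counts, bin_edges) per parameter,
    the ingredients of a corner plot.
    """
    X = np.atleast_2d(np.asarray(samples, dtype=float))
    if X.shape[0] < 10:
        raise ValueError("need at least 10 samples for a pairwise summary")
    p = X.shape[1]
    if p == 1:
        rho = np.ones((1, 1))
    elif p == 2:
        r = float(spearmanr(X[:, 0], X[:, 1]).statistic)
        rho = np.array([[1.0, r], [r, 1.0]])
    else:
        rho = np.atleast_2d(spearmanr(X).statistic)
    hists = [np.histogram(X[:, k], bins=bins) for k in range(p)]
    return rho, hists
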