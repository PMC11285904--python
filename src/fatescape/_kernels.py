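"""Numba-compiled numerical cores.

Hot loops live here: the Gillespie direct method (full event record and
snapshot-grid variants) and the log-domain Sinkhorn fixed-point
iterations.  The propensity evaluation is duplicated from
:mod:`fatescape.model` in jit-friendly form; a unit test pins the two
implementations against each other on random states.

Parameter vectors follow :data:`fatescape.model.VECTOR_FIELDS`:
(a0, a1, b0, b1, b2, b3, c0, c1, c2, c3, c4, e0, e1, e2, k0, gamma,
LIF, I3, alpha).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "propensities_vec",
    "gillespie_grid",
    "gillespie_events",
    "sinkhorn_potentials",
    "sinkhorn_symmetric",
]


@njit(cache=True)
def propensities_vec(x, p):
    """8 reaction propensities at state ``x`` for parameter vector ``p``."""
    N, O, F, G = x[0], x[1], x[2], x[3]
    a = np.empty(8)
    ko = p[14] * O
    num = ko * (p[6] + p[7] * N * N + p[8] * p[16])
    den = 1.0 + ko * (p[7] * N * N + p[8] * p[16] + p[9] * F * F) + p[10] * O * G * G
    a[0] = num / den
    a[1] = p[18] + (p[11] + p[12] * O) / (1.0 + p[12] * O + p[13] * G * G)
    a[2] = (p[0] + p[1] * O) / (1.0 + p[1] * O)
    a[3] = (p[2] + p[3] * G * G + p[5] * O) / (1.0 + p[3] * G * G + p[4] * N * N + p[5] * O)
    a[4] = p[15] * N
    a[5] = p[15] * O
    a[6] = p[15] * F
    a[7] = p[15] * G
    return a


@njit(cache=True)
def gillespie_grid(p, x0, grid, seed):
    """Direct-method jump process recorded only at the sorted ``grid`` times.

    Returns a (4, len(grid)) array with the state held from the last
    event at or before each grid time (left-continuous hold; an event
    exactly at a grid time is included).
    """
    np.random.seed(seed)
    x = x0.copy()
    t = 0.0
    T = grid.shape[0]
    out = np.empty((4, T))
    gi = 0
    while gi < T:
        a = propensities_vec(x, p)
        s = a[0] + a[1] + a[2] + a[3] + a[4] + a[5] + a[6] + a[7]
        if s <= 0.0:
            # absorbing state: hold forever
            while gi < T:
                out[:, gi] = x
                gi += 1
            break
        tnew = t - np.log(np.random.random()) / s
        while gi < T and grid[gi] < tnew:
            out[:, gi] = x
            gi += 1
        if gi >= T:
            break
        u = np.random.random() * s
        c = 0.0
        j = 7
        for k in range(8):
            c += a[k]
            if u <= c:
                j = k
                break
        if j < 4:
            x[j] += 1.0
        else:
            x[j - 4] -= 1.0
        t = tnew
    return out


@njit(cache=True)
def gillespie_ensemble(p, x0, grid, seeds):
    """Independent :func:`gillespie_grid` cells stacked as (4, T, n)."""
    n = seeds.shape[0]
    out = np.empty((4, grid.shape[0], n))
    for i in range(n):
        out[:, :, i] = gillespie_grid(p, x0, grid, seeds[i])
    return out


@njit(cache=True)
def gillespie_events(p, x0, t_end, seed):
    """Direct-method jump process with the full event record.

    Returns (times, states) where times[0] = 0 with the initial state,
    each subsequent row is the state just after an event, and the final
    row repeats the last state at ``t_end`` so the record always covers
    the requested horizon.  Uses the same RNG call sequence as
    :func:`gillespie_grid`, so equal seeds give equal event paths.
    """
    np.random.seed(seed)
    cap = 4096
    times = np.empty(cap)
    states = np.empty((cap, 4))
    x = x0.copy()
    t = 0.0
    n = 0
    times[n] = 0.0
    states[n] = x
    n += 1
    while True:
        a = propensities_vec(x, p)
        s = a[0] + a[1] + a[2] + a[3] + a[4] + a[5] + a[6] + a[7]
        if s <= 0.0:
            break
        tnew = t - np.log(np.random.random()) / s
        if tnew > t_end:
            # draw the reaction anyway to keep the RNG stream aligned
            # with gillespie_grid, but discard the event
            np.random.random()
            break
        u = np.random.random() * s
        c = 0.0
        j = 7
        for k in range(8):
            c += a[k]
            if u <= c:
                j = k
                break
        if j < 4:
            x[j] += 1.0
        else:
            x[j - 4] -= 1.0
        t = tnew
        if n >= cap:
            cap *= 2
            new_times = np.empty(cap)
            new_states = np.empty((cap, 4))
            new_times[:n] = times[:n]
            new_states[:n] = states[:n]
            times = new_times
            states = new_states
        times[n] = t
        states[n] = x
        n += 1
    if n >= cap:
        cap += 1
        new_times = np.empty(cap)
        new_states = np.empty((cap, 4))
        new_times[:n] = times[:n]
        new_states[:n] = states[:n]
        times = new_times
        states = new_states
    times[n] = t_end
    states[n] = x
    n += 1
    return times[:n].copy(), states[:n].copy()


@njit(cache=True, fastmath=True)
def _lse_rows(M):
    """Row-wise log-sum-exp of a 2-D array."""
    n = M.shape[0]
    out = np.empty(n)
    for i in range(n):
        mx = M[i, 0]
        for j in range(1, M.shape[1]):
            if M[i, j] > mx:
                mx = M[i, j]
        s = 0.0
        for j in range(M.shape[1]):
            s += np.exp(M[i, j] - mx)
        out[i] = mx + np.log(s)
    return out


@njit(cache=True, fastmath=True)
def _sinkhorn_sweep(C, f, g, eps, omega):
    """One over-relaxed (f, g) Sinkhorn sweep at regularization ``eps``;
    returns the sup-norm of the raw f update step."""
    m, n = C.shape
    logm = np.log(m)
    logn = np.log(n)
    inv_eps = 1.0 / eps
    err = 0.0
    for i in range(m):
        # fused log-sum-exp over row i of (g_j - C_ij)/eps
        mx = -np.inf
        for j in range(n):
            v = (g[j] - C[i, j]) * inv_eps
            if v > mx:
                mx = v
        s = 0.0
        for j in range(n):
            s += np.exp((g[j] - C[i, j]) * inv_eps - mx)
        f_new = -eps * (mx + np.log(s) - logn)
        d = abs(f_new - f[i])
        if d > err:
            err = d
        f[i] = f[i] + omega * (f_new - f[i])
    for j in range(n):
        mx = -np.inf
        for i in range(m):
            v = (f[i] - C[i, j]) * inv_eps
            if v > mx:
                mx = v
        s = 0.0
        for i in range(m):
            s += np.exp((f[i] - C[i, j]) * inv_eps - mx)
        g_new = -eps * (mx + np.log(s) - logm)
        g[j] = g[j] + omega * (g_new - g[j])
    return err


@njit(cache=True)
def sinkhorn_potentials(C, eps, max_iter, tol):
    """Optimal dual potentials for entropic OT between uniform measures.

    Log-domain Sinkhorn with two standard accelerations: epsilon
    annealing (the regularization is cooled geometrically from the cost
    scale down to ``eps``, warm-starting each level) and over-relaxed
    updates (omega = 1.8) at the final level.  Stops when the sup-norm
    update of f drops below ``tol``; the dual objective is stationary
    at the optimum, so the value error is quadratically smaller than
    the potential error.  Returns (f, g, err, it).
    """
    m, n = C.shape
    f = np.zeros(m)
    g = np.zeros(n)
    cmax = 0.0
    for i in range(m):
        for j in range(n):
            if C[i, j] > cmax:
                cmax = C[i, j]
    # annealing schedule: one plain sweep per level
    level = cmax * 0.5
    while level > eps:
        _sinkhorn_sweep(C, f, g, level, 1.0)
        level *= 0.5
    omega = 1.8
    err = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        err = _sinkhorn_sweep(C, f, g, eps, omega)
        if err * omega < tol:
            break
    return f, g, err, it


@njit(cache=True, fastmath=True)
def _symmetric_half_step(C, f, eps):
    """Averaged symmetric Sinkhorn update; returns (f_next, sup change)."""
    n = C.shape[0]
    logn = np.log(n)
    inv_eps = 1.0 / eps
    f_new = np.empty(n)
    err = 0.0
    for i in range(n):
        mx = -np.inf
        for j in range(n):
            v = (f[j] - C[i, j]) * inv_eps
            if v > mx:
                mx = v
        s = 0.0
        for j in range(n):
            s += np.exp((f[j] - C[i, j]) * inv_eps - mx)
        t = 0.5 * (f[i] - eps * (mx + np.log(s) - logn))
        d = abs(t - f[i])
        if d > err:
            err = d
        f_new[i] = t
    return f_new, err


@njit(cache=True, fastmath=True)
def sinkhorn_symmetric(C, eps, max_iter, tol):
    """Symmetric-problem potential OT_eps(X, X), averaged updates with
    the same epsilon annealing as :func:`sinkhorn_potentials`."""
    n = C.shape[0]
    f = np.zeros(n)
    cmax = 0.0
    for i in range(n):
        for j in range(n):
            if C[i, j] > cmax:
                cmax = C[i, j]
    err = np.inf
    level = cmax * 0.5
    while level > eps:
        f, err = _symmetric_half_step(C, f, level)
        level *= 0.5
    for _ in range(max_iter):
        f, err = _symmetric_half_step(C, f, eps)
        if err < tol:
            break
    return f, err
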