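"""Gillespie and chemical-Langevin simulators, snapshot sampling."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import fatescape as fs
from fatescape.simulate import DEFAULT_X0, Trajectory


def pure_death_params(gamma=0.01):
    """All production channels zeroed: a linear death process."""
    zero = {k: 0.0 for k in ("a0", "a1", "b0", "b1", "b3", "c0", "c1", "c2",
                             "c3", "c4", "e0", "e1", "k0", "alpha")}
    return fs.ModelParameters(gamma=gamma, **zero)


class TestGillespie:
    def test_pure_death_is_nonincreasing_and_absorbs(self):
        tr = fs.gillespie_trajectory(
            pure_death_params(gamma=0.5), x0=(10, 10, 10, 10), t_end=100, seed=3
        )
        diffs = np.diff(tr.states, axis=0)
        assert np.all(diffs[:-1] <= 0)  # last row is the t_end pad
        assert np.array_equal(tr.states[-1], [0, 0, 0, 0])

    def test_event_structure(self, true_params):
        tr = fs.gillespie_trajectory(true_params, t_end=20, seed=7)
        assert np.all(np.diff(tr.times) >= 0)
        assert np.all(tr.states >= 0)
        # consecutive states differ by exactly one stoichiometry column
        jumps = np.diff(tr.states[:-1], axis=0)  # exclude the t_end pad
        assert np.all(np.abs(jumps).sum(axis=1) == 1)

    def test_same_seed_bitwise_identical(self, true_params):
        a = fs.gillespie_trajectory(true_params, t_end=30, seed=11)
        b = fs.gillespie_trajectory(true_params, t_end=30, seed=11)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.states, b.states)
        c = fs.gillespie_trajectory(true_params, t_end=30, seed=12)
        assert not np.array_equal(a.times, c.times)

    def test_non_integer_x0_rejected(self, true_params):
        with pytest.raises(ValueError, match="integer"):
            fs.gillespie_trajectory(true_params, x0=(0.5, 1, 0, 0))

    def test_pure_death_moments_match_exact_solution(self):
        # linear death: X(t) ~ Binomial(x0, exp(-gamma t))
        gamma, x0, t = 0.05, 40, 10.0
        n = 600
        params = pure_death_params(gamma=gamma)
        vals = np.array(
            [
                fs.gillespie_trajectory(params, x0=(x0, 0, 0, 0), t_end=t,
                                        seed=1000 + i).state_at(t)[0]
                for i in range(n)
            ]
        )
        p = np.exp(-gamma * t)
        mean, var = x0 * p, x0 * p * (1 - p)
        assert abs(vals.mean() - mean) < 3 * np.sqrt(var / n)
        # variance within a generous MC band (chi^2 fluctuation)
        assert var / 2 < vals.var(ddof=1) < var * 2

    def test_ensemble_mean_matches_ode_at_large_counts(self, true_params):
        # from a large Oct4-Sox2 seed the fate is deterministic and the
        # jump-process mean tracks the rate equations
        x0 = (0.0, 100.0, 0.0, 0.0)
        t_end, n = 30.0, 400
        ds = fs.simulate_dataset(
            true_params, n_cells=n, time_grid=np.array([t_end]), x0=x0, seed=5
        )
        ens = ds.values[:, 0, :]
        sol = solve_ivp(
            lambda t, x: fs.ode_rhs(np.maximum(x, 0), true_params),
            (0, t_end), list(x0), rtol=1e-10, atol=1e-10, method="LSODA",
        )
        ode = sol.y[:, -1]
        se = ens.std(axis=1, ddof=1) / np.sqrt(n)
        assert np.all(np.abs(ens.mean(axis=1) - ode) < 3 * se + 0.5)


class TestCLE:
    def test_zero_noise_equals_explicit_euler(self, true_params):
        dt = 0.05
        tr = fs.cle_trajectory(true_params, t_end=5, dt=dt, seed=0, noise_scale=0.0)
        x = np.array(DEFAULT_X0)
        for k in range(len(tr.times) - 1):
            h = tr.times[k + 1] - tr.times[k]
            x = np.maximum(x + h * fs.ode_rhs(x, true_params), 0)
        assert np.allclose(tr.states[-1], x, atol=1e-12)

    def test_determinism(self, true_params):
        a = fs.cle_trajectory(true_params, t_end=5, dt=0.05, seed=9)
        b = fs.cle_trajectory(true_params, t_end=5, dt=0.05, seed=9)
        assert np.array_equal(a.states, b.states)

    def test_invalid_dt(self, true_params):
        with pytest.raises(ValueError):
            fs.cle_trajectory(true_params, dt=0.0)

    def test_pure_death_mean_matches_closed_form(self):
        gamma, x0, t = 0.1, 50.0, 5.0
        params = pure_death_params(gamma=gamma)
        n = 2000
        finals = np.array(
            [
                fs.cle_trajectory(params, x0=(x0, 0, 0, 0), t_end=t, dt=0.02,
                                  seed=i).states[-1, 0]
                for i in range(n)
            ]
        )
        target = x0 * np.exp(-gamma * t)
        se = finals.std(ddof=1) / np.sqrt(n)
        assert abs(finals.mean() - target) < 3 * se + 1e-3


class TestSnapshots:
    def test_grid_zero_returns_initial_state(self, true_params):
        trs = [fs.gillespie_trajectory(true_params, t_end=5, seed=s) for s in range(3)]
        ds = fs.sample_snapshots(trs, [0.0])
        assert np.array_equal(ds.values[:, 0, :].T, np.tile(DEFAULT_X0, (3, 1)))

    def test_reference_tensor_shape(self, reference300):
        assert reference300.values.shape == (4, 10, 300)
        assert np.allclose(reference300.time_grid, np.arange(1, 11) * 10.0)

    def test_single_cell_shape(self, true_params):
        ds = fs.generate_reference(true_params, n_cells=1, T=7, t_end=10, seed=0)
        assert ds.values.shape == (4, 7, 1)

    def test_left_continuous_hold_convention(self):
        tr = Trajectory(times=[0.0, 5.0, 10.0],
                        states=[[1, 0, 0, 0], [2, 0, 0, 0], [2, 0, 0, 0]])
        ds = fs.sample_snapshots([tr], [4.9, 5.1])
        assert ds.values[0, 0, 0] == 1  # pre-event
        assert ds.values[0, 1, 0] == 2  # post-event

    def test_short_trajectory_errors_with_index(self, true_params):
        trs = [fs.gillespie_trajectory(true_params, t_end=10, seed=1),
               fs.gillespie_trajectory(true_params, t_end=5, seed=2)]
        with pytest.raises(ValueError, match="trajectory 1"):
            fs.sample_snapshots(trs, [8.0])

    def test_snapshot_idempotence(self, true_params):
        tr = fs.gillespie_trajectory(true_params, t_end=20, seed=4)
        grid = np.linspace(2, 20, 5)
        ds = fs.sample_snapshots([tr], grid)
        again = fs.sample_snapshots(
            [Trajectory(times=grid, states=ds.values[:, :, 0].T)], grid
        )
        assert np.array_equal(ds.values, again.values)

    def test_reference_reproducible(self, true_params):
        a = fs.generate_reference(true_params, n_cells=20, seed=77)
        b = fs.generate_reference(true_params, n_cells=20, seed=77)
        assert np.array_equal(a.values, b.values)

    def test_grid_and_event_paths_agree(self, true_params):
        # the fast grid sampler and the full event record use the same
        # RNG stream, so both views of one seed must coincide
        from fatescape._kernels import gillespie_grid

        grid = np.linspace(5, 50, 6)
        tr = fs.gillespie_trajectory(true_params, t_end=50, seed=31)
        via_events = fs.sample_snapshots([tr], grid).values[:, :, 0]
        via_grid = gillespie_grid(
            true_params.to_vector(), np.array(DEFAULT_X0), grid, 31
        )
        assert np.array_equal(via_events, via_grid)


class TestFateStatistics:
    def test_final_time_bimodality_at_lif_50(self, reference300):
        # both fates must be represented in the terminal (N, G) scatter
        N, G = reference300.values[0, -1, :], reference300.values[3, -1, :]
        frac_pluri = np.mean(N > G)
        assert 0.5 < frac_pluri < 0.99
        # the two modes are separated along the Nanog axis: committed
        # pluripotent cells hold tens of Nanog molecules, differentiating
        # cells almost none (Gata6 still climbing toward its attractor)
        assert N[N > G].mean() > 20
        assert N[N <= G].mean() < 5
        assert G[N <= G].mean() > 5

    def test_pluripotent_fraction_increases_with_lif(self, true_params):
        fracs = []
        for L in (5.0, 50.0, 200.0):
            ds = fs.simulate_dataset(
                true_params.replace(LIF=L), n_cells=150,
                time_grid=np.array([100.0]), seed=21,
            )
            N, G = ds.values[0, 0, :], ds.values[3, 0, :]
            fracs.append(np.mean(N > G))
        assert fracs[0] < fracs[1] < fracs[2]
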