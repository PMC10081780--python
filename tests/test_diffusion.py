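import numpy as np
import pytest
from scipy import stats

from beadlysis.diffusion import (
    SimConfig,
    export_trace,
    msd_diagnostic,
    run_ensemble,
    run_simulation,
    step,
    step_variance_per_axis,
    timestep_from_D,
)


def discrete_mfpt_seconds(config: SimConfig) -> float:
    """Exact mean first-passage time to j=0 from a uniform top-half start.

    Independent oracle: solves the linear MFPT system of the y-marginal
    chain (lazy5 + reject_stay: down/up each w.p. 1/5, top wall rejects).
    """
    ny = config.ny
    # unknowns T_1..T_ny ; T_0 = 0
    A = np.zeros((ny, ny))
    b = np.full(ny, 1.0)
    p = 0.2
    for row, j in enumerate(range(1, ny + 1)):
        if j < ny:
            A[row, row] = 2 * p          # leaves j at rate 2p
            if j + 1 <= ny:
                A[row, j + 1 - 1] -= p   # up
            if j - 1 >= 1:
                A[row, j - 1 - 1] -= p   # down (j=1 goes to absorbing 0)
        else:  # top wall: only down leaves
            A[row, row] = p
            A[row, j - 1 - 1] -= p
    T = np.linalg.solve(A, b)
    start = np.arange(ny // 2, ny + 1)
    return float(T[start - 1].mean()) * config.time_step


class TestTimestep:
    @pytest.mark.parametrize(
        "dx, D, expected",
        [(0.02, 10.0, 1e-5), (0.02, 1e-4, 1.0), (0.04, 10.0, 4e-5)],
    )
    def test_closed_form(self, dx, D, expected):
        assert timestep_from_D(dx, D) == pytest.approx(expected)

    def test_invalid(self):
        with pytest.raises(ValueError):
            timestep_from_D(0.0, 10.0)


class TestSingleStep:
    def test_interior_outcomes_equiprobable(self, rng):
        """Each of the 5 lazy5 outcomes occurs with p=0.2 (chi-square, 1e5 draws)."""
        config = SimConfig()
        counts = {}
        for _ in range(100_000):
            ni, nj, bound = step(50, 50, config, rng)
            assert not bound
            counts[(ni, nj)] = counts.get((ni, nj), 0) + 1
        assert set(counts) == {(50, 50), (51, 50), (49, 50), (50, 51), (50, 49)}
        chi = stats.chisquare(list(counts.values()))
        assert chi.pvalue > 0.001

    def test_left_wall_reject_stay_probabilities(self, rng):
        """At i=0 the rejected -x move becomes a stay: P(stay)=2/5."""
        config = SimConfig()
        n = 100_000
        counts = {}
        for _ in range(n):
            ni, nj, _ = step(0, 50, config, rng)
            counts[(ni, nj)] = counts.get((ni, nj), 0) + 1
        assert (-1, 50) not in counts
        expected = {(0, 50): 0.4, (1, 50): 0.2, (0, 51): 0.2, (0, 49): 0.2}
        chi = stats.chisquare(
            [counts[k] for k in expected], [v * n for v in expected.values()]
        )
        assert chi.pvalue > 0.001

    def test_mirror_wall_reflects(self, rng):
        config = SimConfig(reflection_rule="mirror")
        seen = set()
        for _ in range(200):
            seen.add(step(0, 50, config, rng)[:2])
        assert seen <= {(1, 50), (0, 51), (0, 49), (0, 50)}

    def test_landing_on_bottom_row_binds(self, rng):
        config = SimConfig()
        for _ in range(200):
            ni, nj, bound = step(50, 1, config, rng)
            assert bound == (nj == 0)

    def test_stepping_bound_bead_is_an_error(self, rng):
        with pytest.raises(ValueError):
            step(5, 0, SimConfig(), rng)


class TestRunSimulation:
    def test_zero_max_time_leaves_all_unbound(self):
        res = run_simulation(SimConfig(max_time=0.0, master_seed=1))
        assert not res.bound.any()
        assert np.isnan(res.bind_time).all()

    def test_lattice_discreteness_and_conservation(self):
        config = SimConfig(n_beads=50, max_time=2.0, master_seed=7)
        res = run_simulation(config)
        n_bound = int(res.bound.sum())
        assert n_bound + int((~res.bound).sum()) == config.n_beads
        steps = res.bind_step[res.bound]
        assert np.all(steps >= 1)
        # bind times are exact multiples of dt, locations exact nodes
        assert np.allclose(res.bind_time[res.bound] / config.time_step, steps)
        assert np.all(res.y_node[res.bound] == 0)
        assert np.all((res.x_node >= 0) & (res.x_node <= config.nx))

    def test_nearly_all_beads_bind_within_60s(self):
        res = run_simulation(SimConfig(master_seed=3))
        assert res.bound.mean() >= 0.99

    def test_cumulative_bound_fraction_monotone(self):
        res = run_simulation(SimConfig(n_beads=30, max_time=1.0, master_seed=5),
                             trace_every=200)
        bound_per_frame = (res.trace[:, :, 1] == 0).sum(axis=1)
        assert np.all(np.diff(bound_per_frame) >= 0)


class TestEnsemble:
    def test_mean_bind_time_matches_discrete_mfpt_oracle(self):
        config = SimConfig(master_seed=11)
        summary = run_ensemble(config, 20)
        times = []
        from beadlysis.diffusion import _spawn_seeds

        for s in _spawn_seeds(11, 20):
            r = run_simulation(config, seed=int(s))
            times.append(r.bind_time[r.bound])
        times = np.concatenate(times)
        sem = times.std(ddof=1) / np.sqrt(times.size)
        expected = discrete_mfpt_seconds(config)
        assert expected == pytest.approx(0.23083, rel=1e-3)  # closed form check
        assert abs(summary.mean_bind_time_overall_s - expected) <= 3 * sem

    def test_fractions_sum_to_overall_bound_fraction(self):
        summary = run_ensemble(SimConfig(n_beads=50, max_time=5.0, master_seed=2), 5)
        assert summary.bind_fraction_pct.sum() == pytest.approx(
            100 * summary.overall_bound_fraction
        )
        assert np.all(summary.bind_fraction_pct >= 0)
        assert np.nanmin(summary.mean_bind_time_s) >= 0

    def test_single_simulation_equals_ensemble_of_one(self):
        config = SimConfig(n_beads=40, max_time=2.0, master_seed=9)
        summary = run_ensemble(config, 1)
        from beadlysis.diffusion import _spawn_seeds

        res = run_simulation(config, seed=int(_spawn_seeds(9, 1)[0]))
        assert summary.n_bound.sum() == res.bound.sum()
        b = res.bound
        assert summary.mean_bind_time_overall_s == pytest.approx(
            res.bind_time[b].mean()
        )

    def test_bit_identical_reruns_with_same_master_seed(self):
        config = SimConfig(n_beads=30, max_time=1.0, master_seed=77)
        a = run_ensemble(config, 4)
        b = run_ensemble(config, 4)
        assert np.array_equal(a.n_bound, b.n_bound)
        assert np.array_equal(a.bind_fraction_pct, b.bind_fraction_pct)
        c = run_ensemble(SimConfig(n_beads=30, max_time=1.0, master_seed=78), 4)
        assert not np.array_equal(a.n_bound, c.n_bound)

    def test_kernel_agrees_with_pure_python_stepper(self, rng):
        """Dual route: compiled kernel vs the step() reference on a small box."""
        config = SimConfig(domain_width=0.4, domain_height=0.4, n_beads=100,
                           max_time=0.5, master_seed=13)
        summary = run_ensemble(config, 5)
        # reference: python loop over step() with the same init law
        times = []
        for _ in range(500):
            i = int(rng.integers(0, config.nx + 1))
            j = int(rng.integers(config.ny // 2, config.ny + 1))
            for t in range(1, config.max_steps + 1):
                i, j, bound = step(i, j, config, rng)
                if bound:
                    times.append(t * config.time_step)
                    break
        times = np.asarray(times)
        sem = times.std(ddof=1) / np.sqrt(times.size)
        assert len(times) == 500  # all bind easily in 0.5 s on a small box
        assert abs(summary.mean_bind_time_overall_s - times.mean()) <= 4 * sem


class TestMsdDiagnostic:
    def test_zero_steps_has_zero_variance(self):
        df = msd_diagnostic(SimConfig(), 0, 10, seed=1)
        assert df["var_x"].iloc[0] == 0.0

    @pytest.mark.parametrize("rule", ["lazy5", "move4"])
    def test_variance_growth_matches_rule(self, rule):
        config = SimConfig(step_rule=rule)
        n_steps, n_walkers = 4000, 4000
        df = msd_diagnostic(config, n_steps, n_walkers, seed=42)
        per_step = step_variance_per_axis(rule, config.space_step)
        expected = per_step * n_steps
        rel_se = np.sqrt(2.0 / (n_walkers - 1))  # SE of a sample variance
        for col in ("var_x", "var_y"):
            assert abs(df[col].iloc[-1] - expected) <= 3 * rel_se * expected

    def test_move4_recovers_nominal_diffusivity(self):
        """move4 variance growth corresponds to D = dx^2/(4 dt)."""
        config = SimConfig(step_rule="move4")
        per_step = step_variance_per_axis("move4", config.space_step)
        D_axis = per_step / (2 * config.time_step)
        assert D_axis == pytest.approx(
            config.space_step**2 / (4 * config.time_step)
        )
        assert D_axis == pytest.approx(10.0)


class TestTraceExport:
    def test_frame_count_and_grid_positions(self, tmp_path):
        config = SimConfig(n_beads=1, max_time=100 * 1e-5, master_seed=21)
        res = run_simulation(config, trace_every=100)
        df = export_trace(res, tmp_path / "trace.csv")
        assert res.trace.shape[0] == 2  # initial frame + one
        assert (tmp_path / "trace.csv").exists()
        assert df["time_s"].max() == pytest.approx(100 * config.time_step)
        x = df["x_um"].to_numpy()
        assert np.allclose(np.round(x / config.space_step), x / config.space_step)
        assert (x >= 0).all() and (x <= config.domain_width).all()

    def test_untraced_simulation_cannot_export(self, tmp_path):
        res = run_simulation(SimConfig(n_beads=2, max_time=1e-4, master_seed=1))
        with pytest.raises(ValueError):
            export_trace(res, tmp_path / "x.csv")
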