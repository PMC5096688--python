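"""Stochastic simulation: event kernels, lineages, assay statistics."""

import numpy as np
import pytest

from propagon import (
    CellLineageRecord,
    CellState,
    ModelParams,
    MomentState,
    Protocol,
    amplification_rate,
    integrate_moments,
    propagon_assay,
    simulate_lineage,
    simulate_well_mixed,
)

# inert parameter set: rates vanishingly small so only the requested
# process (dilution or division) acts on the aggregates
INERT = ModelParams(alpha=1e-12, beta=1e-18, gamma=1e-12, mu=7e-3, n0=4)


class TestProtocol:
    def test_validation(self):
        with pytest.raises(ValueError):
            Protocol(phases=(), sample_times=())
        with pytest.raises(ValueError):
            Protocol(phases=((-5.0, 0.0, "x"),), sample_times=())
        with pytest.raises(ValueError):
            Protocol(phases=((10.0, 1.5, "x"),), sample_times=())
        with pytest.raises(ValueError):
            Protocol(phases=((10.0, 1.0, "x"),), sample_times=(20.0,))
        p = Protocol(phases=((10.0, 0.0, "a"), (5.0, 1.0, "b")), sample_times=(0.0, 15.0))
        assert p.total_duration == 15.0
        assert list(p.phase_ends) == [10.0, 15.0]


class TestWellMixed:
    def test_deterministic_given_seed(self, example_params):
        init = CellState(s=500, aggregates=(10,) * 5)
        a = simulate_well_mixed(example_params, init, 50.0, seed=7)
        b = simulate_well_mixed(example_params, init, 50.0, seed=7)
        assert np.array_equal(a.U, b.U) and np.array_equal(a.s, b.s)
        c = simulate_well_mixed(example_params, init, 50.0, seed=8)
        assert not (np.array_equal(a.U, c.U) and np.array_equal(a.s, c.s))

    def test_pure_death_mean(self):
        """With all reactions off, each aggregate survives dilution with
        probability exp(-mu t)."""
        init = CellState(s=0, aggregates=(10,) * 50)
        finals = np.array([
            simulate_well_mixed(
                INERT, init, 200.0, seed=k, sample_times=np.array([0.0, 200.0])
            ).U[-1]
            for k in range(400)
        ])
        expected = 50 * np.exp(-INERT.mu * 200.0)
        se = finals.std(ddof=1) / np.sqrt(finals.size)
        assert abs(finals.mean() - expected) <= 3 * se

    def test_minimum_size_aggregate_dies_on_first_break(self):
        """A size-n0 aggregate cannot fragment into two stable pieces, so U
        never exceeds 1 when starting from a single nucleus with conversion
        off."""
        p = ModelParams(alpha=1e-12, beta=1e-18, gamma=0.05, mu=1e-9, n0=4)
        for seed in range(30):
            tr = simulate_well_mixed(
                p, CellState(s=0, aggregates=(4,)), 400.0, seed=seed,
                sample_times=np.linspace(0, 400, 81),
            )
            assert np.max(tr.U) <= 1
            assert tr.U[-1] == 0.0  # some break happened by t >> 1/(3 gamma)
            # dissolved mass returned to monomer
            assert tr.s[-1] == 4.0

    def test_ensemble_mean_tracks_moment_odes(self):
        """Stochastic ensemble means of (s, U, M) follow the deterministic
        moment system within 3 standard errors at matched times."""
        p = ModelParams(alpha=30.0, beta=2.1e-4, gamma=8e-4, mu=7e-3, n0=4)
        init = CellState(s=2000, aggregates=(10,) * 40)
        ts = np.array([0.0, 150.0, 400.0])
        n_runs = 400
        S = np.empty((n_runs, ts.size))
        U = np.empty((n_runs, ts.size))
        M = np.empty((n_runs, ts.size))
        for k in range(n_runs):
            tr = simulate_well_mixed(p, init, 400.0, seed=50_000 + k, sample_times=ts)
            S[k], U[k], M[k] = tr.s, tr.U, tr.M
        mom = integrate_moments(p, MomentState(0.0, 2000.0, 40.0, 400.0), ts)
        for i in range(1, ts.size):
            for sim, ode in ((S, mom[i].s), (U, mom[i].U), (M, mom[i].M)):
                se = sim[:, i].std(ddof=1) / np.sqrt(n_runs)
                assert abs(sim[:, i].mean() - ode) <= 3.5 * se

    def test_overflow_guard(self):
        p = ModelParams(alpha=1e13, beta=1e-3, gamma=1e-3, mu=1e-9, n0=4)
        from propagon.simulate import SimulationError

        with pytest.raises(SimulationError):
            simulate_well_mixed(p, CellState(s=10**9, aggregates=(100,) * 10), 1e5, seed=0)


class TestLineage:
    def test_binomial_partition_one_division(self):
        """One division with fragmentation off: retained counts are
        Binomial(N, p_keep) in both mean and variance."""
        N, p_keep = 200, 0.5
        prot = Protocol(phases=((100.0, 0.0, "g"),), sample_times=(100.0,))
        init = CellState(s=0, aggregates=(4,) * N)
        finals = np.array([
            simulate_lineage(
                INERT, prot, init, t_d=90.0, p_keep=p_keep, seed=k,
                division_phase=1.0,
            ).propagon_counts[-1]
            for k in range(400)
        ])
        se_mean = finals.std(ddof=1) / np.sqrt(finals.size)
        assert abs(finals.mean() - N * p_keep) <= 3 * se_mean
        var = finals.var(ddof=1)
        # variance of a binomial sample variance ~ 2 sigma^4/(n-1) for normalish
        se_var = var * np.sqrt(2 / (finals.size - 1))
        assert abs(var - N * p_keep * (1 - p_keep)) <= 4 * se_var

    def test_halving_law_five_generations(self):
        """gamma_scale = 0 throughout: mean propagons after five divisions
        is N / 2^5 (binomial thinning per generation, no birth)."""
        prot = Protocol(phases=((500.0, 0.0, "GdnHCl"),), sample_times=(0.0, 500.0))
        init = CellState(s=0, aggregates=(4,) * 1000)
        finals = np.array([
            simulate_lineage(INERT, prot, init, t_d=100.0, seed=k).propagon_counts[-1]
            for k in range(250)
        ])
        se = finals.std(ddof=1) / np.sqrt(finals.size)
        assert abs(finals.mean() - 31.25) <= 3 * se

    def test_division_times_and_determinism(self):
        prot = Protocol(phases=((300.0, 0.0, "g"),), sample_times=(0.0, 300.0))
        init = CellState(s=100, aggregates=(8,) * 10)
        rec = simulate_lineage(INERT, prot, init, t_d=100.0, seed=5, division_phase=1.0)
        assert rec.division_times == (100.0, 200.0, 300.0)
        rec2 = simulate_lineage(INERT, prot, init, t_d=100.0, seed=5, division_phase=1.0)
        assert rec == rec2

    def test_asynchronous_phase_drawn_from_seed(self):
        prot = Protocol(phases=((150.0, 0.0, "g"),), sample_times=(150.0,))
        init = CellState(s=0, aggregates=(8,) * 10)
        t1 = simulate_lineage(INERT, prot, init, t_d=100.0, seed=1).division_times
        t2 = simulate_lineage(INERT, prot, init, t_d=100.0, seed=2).division_times
        assert t1 != t2  # different cycle offsets
        assert all(0 < t <= 150.0 for t in t1 + t2)

    def test_recovery_approaches_steady_state(self, panel_by_label):
        """Curing then release: median propagon count non-decreasing through
        recovery, climbing toward the strain's steady-state level."""
        from propagon.synth import steady_state_cell
        from propagon import curing_recovery_protocol

        spec = panel_by_label["R2E1"]
        prot = curing_recovery_protocol()
        init = steady_state_cell(spec)
        counts = np.array([
            simulate_lineage(
                spec.params, prot, init, t_d=spec.t_d, seed=k, mode="hybrid"
            ).propagon_counts
            for k in range(150)
        ])
        med = np.median(counts, axis=0)
        # smoothed monotonicity: allow +-1 count of sampling jitter
        assert np.all(np.diff(med) >= -1.0)
        assert med[-1] > med[0]
        assert med[-1] > 0.5 * len(init.aggregates)

    def test_hybrid_matches_exact_ensemble(self, panel_by_label):
        """The accelerated hybrid engine reproduces the exact kernel's
        per-cell propagon count distribution (means within 3 SE)."""
        from propagon.synth import steady_state_cell

        spec = panel_by_label["RWT"]
        prot = Protocol(
            phases=((300.0, 0.0, "GdnHCl"), (240.0, 1.0, "recovery")),
            sample_times=(300.0, 420.0, 540.0),
        )
        init = steady_state_cell(spec)
        n = 200
        ex = np.array([
            simulate_lineage(spec.params, prot, init, t_d=spec.t_d, seed=k).propagon_counts
            for k in range(n)
        ], dtype=float)
        hy = np.array([
            simulate_lineage(
                spec.params, prot, init, t_d=spec.t_d, seed=k, mode="hybrid"
            ).propagon_counts
            for k in range(n)
        ], dtype=float)
        se = np.sqrt(ex.var(axis=0, ddof=1) / n + hy.var(axis=0, ddof=1) / n)
        assert np.all(np.abs(ex.mean(axis=0) - hy.mean(axis=0)) <= 3 * se)

    def test_bad_arguments(self, example_params):
        prot = Protocol(phases=((100.0, 0.0, "g"),), sample_times=(0.0,))
        init = CellState(s=0, aggregates=(8,))
        with pytest.raises(ValueError):
            simulate_lineage(example_params, prot, init, t_d=0.0)
        with pytest.raises(ValueError):
            simulate_lineage(example_params, prot, init, t_d=50.0, p_keep=1.0)
        with pytest.raises(ValueError):
            simulate_lineage(example_params, prot, init, t_d=50.0, mode="magic")
        with pytest.raises(ValueError):
            simulate_lineage(
                example_params, prot, CellState(s=0, aggregates=(2,)), t_d=50.0
            )


class TestAmplificationRate:
    @staticmethod
    def _records(times, counts_matrix):
        return [
            CellLineageRecord(tuple(times), tuple(int(c) for c in row), (), 0)
            for row in counts_matrix
        ]

    def test_exact_exponential_input(self):
        """Noise-free exponential ensemble mean recovers the rate exactly."""
        r = 0.01
        times = np.array([0.0, 60.0, 120.0, 180.0])
        counts = np.round(1000 * np.exp(r * times)).astype(int)
        recs = self._records(times, [counts] * 4)
        slope, se = amplification_rate(recs)
        assert slope == pytest.approx(r, rel=1e-4)  # integer rounding only
        assert se < 1e-4

    def test_doubled_fragmentation_amplifies_faster(self, panel_by_label):
        """Paired simulation: doubling gamma increases the fitted rate."""
        from propagon.synth import steady_state_cell
        from propagon import curing_recovery_protocol

        spec = panel_by_label["RWT"]
        p2 = ModelParams(
            alpha=spec.params.alpha, beta=spec.params.beta,
            gamma=2 * spec.params.gamma, mu=spec.params.mu, n0=spec.params.n0,
        )
        prot = curing_recovery_protocol()
        rates = []
        for params in (spec.params, p2):
            init = steady_state_cell(spec)
            recs = [
                simulate_lineage(params, prot, init, t_d=spec.t_d, seed=k, mode="hybrid")
                for k in range(250)
            ]
            rates.append(amplification_rate(recs, slice(0, 7))[0])
        assert rates[1] > rates[0]

    def test_window_errors(self):
        times = np.array([0.0, 30.0, 60.0, 90.0])
        recs = self._records(times, [[1, 2, 3, 4]] * 3)
        with pytest.raises(ValueError):
            amplification_rate(recs, window=[0, 1])
        recs0 = self._records(times, [[0, 0, 1, 2]] * 3)
        with pytest.raises(ValueError, match="zero"):
            amplification_rate(recs0, window=slice(0, 3))
        with pytest.raises(ValueError):
            amplification_rate([])


class TestPropagonAssay:
    def test_full_efficiency_is_identity(self):
        assert propagon_assay(137, 1.0, seed=1) == 137
        assert propagon_assay(0, 0.5, seed=1) == 0

    def test_binomial_mean(self):
        vals = np.array([propagon_assay(1000, 0.5, seed=k) for k in range(400)])
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean() - 500.0) <= 3 * se

    def test_domain(self):
        with pytest.raises(ValueError):
            propagon_assay(-1, 0.5)
        with pytest.raises(ValueError):
            propagon_assay(10, 0.0)
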