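"""Engine correctness: conversions, propensities, SSA oracles, division."""

import numpy as np
import pytest
from scipy import stats as sps

from conftest import NO_DIVISION, make_network
from tetopsim.engine import (CellCycleParams, CellState, DoseSchedule,
                             divide, draw_elongation_delay, propensity,
                             simulate_cell, simulate_ensemble,
                             stochastic_rate_constant)
from tetopsim.model import AVOGADRO
from tetopsim.stats import conservation_residuals, summarize

V0 = 1e-15


class TestConversions:
    def test_molar_heterodimer(self):
        c = stochastic_rate_constant(1e9, "per_molar_second", 2, V0)
        assert c == pytest.approx(1.66053906, rel=1e-8)
        c = stochastic_rate_constant(30.0, "per_molar_second", 2, V0)
        assert c == pytest.approx(4.98160e-8, rel=1e-4)

    def test_unimolecular_passthrough(self):
        assert stochastic_rate_constant(0.1, "per_second", 1, V0) == 0.1
        assert stochastic_rate_constant(0.1, "per_second", 1, 3e-15) == 0.1

    def test_homodimer_doubling(self):
        c = stochastic_rate_constant(1e9, "per_molar_second", 2, V0,
                                     homodimer=True)
        assert c == pytest.approx(2e9 / (AVOGADRO * V0))

    def test_errors(self):
        with pytest.raises(ValueError):
            stochastic_rate_constant(1.0, "per_molar_second", 3, V0)
        with pytest.raises(ValueError):
            stochastic_rate_constant(1.0, "per_second", 1, 0.0)
        with pytest.raises(ValueError):
            stochastic_rate_constant(30.0, "per_step", 1, V0)


class TestPropensity:
    def test_nsdna_binding_example(self, wt_network):
        counts = {"TetR2": 1, "nsDNA": 4_000_000}
        a = propensity(wt_network, "4f", counts, V0)
        assert a == pytest.approx(0.1992639, rel=1e-4)

    def test_homodimer_combinations(self, wt_network):
        a = propensity(wt_network, "1f", {"TetR": 2}, V0)
        assert a == pytest.approx(3.32107, rel=1e-4)
        assert propensity(wt_network, "1f", {"TetR": 1}, V0) == 0.0

    def test_zero_count_reactant(self, wt_network):
        assert propensity(wt_network, "6f", {"TetR2": 0, "Tc": 50}, V0) == 0.0

    def test_gamma_reactions_do_not_race(self, wt_network):
        assert propensity(wt_network, "17", {"RNAp*:DNA(PR1)": 3}, V0) == 0.0

    def test_volume_dependence_bimolecular_only(self, wt_network):
        a1 = propensity(wt_network, "6f", {"TetR2": 2, "Tc": 5}, V0)
        a2 = propensity(wt_network, "6f", {"TetR2": 2, "Tc": 5}, 2 * V0)
        assert a1 == pytest.approx(2 * a2)
        b1 = propensity(wt_network, "35", {"TetR2": 4}, V0)
        b2 = propensity(wt_network, "35", {"TetR2": 4}, 2 * V0)
        assert b1 == b2 == pytest.approx(4 * 3.85e-5)


class TestGammaDelay:
    def test_moments_and_goodness_of_fit(self):
        rng = np.random.default_rng(7)
        draws = np.array([draw_elongation_delay(621, 30.0, rng)
                          for _ in range(10_000)])
        assert draws.mean() == pytest.approx(20.7, rel=0.01)
        assert draws.var() == pytest.approx(621 / 900, rel=0.1)
        ks = sps.kstest(draws, sps.gamma(a=621, scale=1 / 30).cdf)
        assert ks.pvalue > 0.01

    def test_shape_one_is_exponential(self):
        rng = np.random.default_rng(8)
        draws = np.array([draw_elongation_delay(1, 0.5, rng)
                          for _ in range(10_000)])
        ks = sps.kstest(draws, sps.expon(scale=2.0).cdf)
        assert ks.pvalue > 0.01

    def test_translation_delay_mean(self):
        rng = np.random.default_rng(9)
        draws = [draw_elongation_delay(207, 100.0, rng) for _ in range(2000)]
        assert np.mean(draws) == pytest.approx(2.07, rel=0.02)

    def test_invalid_parameters(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            draw_elongation_delay(0, 30.0, rng)
        with pytest.raises(ValueError):
            draw_elongation_delay(10, 0.0, rng)


class TestSSAOracles:
    def test_empty_network_counts_constant(self):
        net = make_network([("A", True, 5)], [("noop", {"A": 1}, {"A": 1}, "k0")],
                           {"k0": (0.0, "per_second")})
        tr = simulate_cell(net, 600.0, grid_dt=60.0, cycle=NO_DIVISION, seed=1)
        assert np.all(tr.series("A") == 5)
        assert np.array_equal(tr.grid, np.arange(0.0, 601.0, 60.0))

    def test_linear_decay_matches_analytic_mean(self):
        # A -> 0 at 0.002/s from A0=1000: E[A](500 s) = 1000 e^-1 = 367.88
        net = make_network([("A", True, 1000)],
                           [("d", {"A": 1}, {}, "kd")],
                           {"kd": (0.002, "per_second")})
        finals = [simulate_cell(net, 500.0, grid_dt=500.0, cycle=NO_DIVISION,
                                seed=s).series("A")[-1] for s in range(200)]
        se = np.std(finals, ddof=1) / np.sqrt(len(finals))
        assert abs(np.mean(finals) - 1000 * np.exp(-1)) < 3 * se + 1e-9

    def test_birth_death_stationary_poisson(self, birth_death):
        # sample every 60 s (>> relaxation time 10 s): ~independent draws
        tr = simulate_cell(birth_death, 600_600.0, grid_dt=60.0,
                           cycle=NO_DIVISION, seed=42)
        samples = tr.series("A")[10:]  # discard burn-in
        n = samples.size
        assert n >= 10_000
        mean_se = samples.std(ddof=1) / np.sqrt(n)
        assert abs(samples.mean() - 100.0) < 3 * mean_se
        var = samples.var(ddof=1)
        var_se = var * np.sqrt(2.0 / (n - 1))
        assert abs(var - 100.0) < 3 * var_se

    def test_reversible_dimerization_matches_cme(self):
        # 2A <-> A2 with per-molecule constants kf=1, kr=2, 20 monomers total:
        # stationary chain on d dimers solved by detailed balance.
        n0 = 20
        net = make_network(
            [("A", True, n0), ("A2", True, 0)],
            [("f", {"A": 2}, {"A2": 1}, "kf"), ("r", {"A2": 1}, {"A": 2}, "kr")],
            {"kf": (1.0, "per_second"), "kr": (2.0, "per_second")},
        )
        kf, kr = 1.0, 2.0
        pi = [1.0]
        for d in range(n0 // 2):
            nA = n0 - 2 * d
            pi.append(pi[-1] * (kf * nA * (nA - 1) / 2) / (kr * (d + 1)))
        pi = np.array(pi) / np.sum(pi)

        tr = simulate_cell(net, 10_000.0, grid_dt=0.1, cycle=NO_DIVISION,
                           seed=5)
        dimers = tr.series("A2")[100:]
        emp = np.bincount(dimers, minlength=n0 // 2 + 1) / dimers.size
        tv = 0.5 * np.abs(emp - pi).sum()
        assert tv < 0.02

    def test_birth_death_ensemble_summary(self, birth_death):
        trs = simulate_ensemble(birth_death, 50, 600.0, grid_dt=60.0,
                                cycle=NO_DIVISION, master_seed=3)
        s = summarize(trs)
        final = s.mean_series("A")[-1]
        assert abs(final - 100.0) < 3 * 10.0 / np.sqrt(50) + 1.0


class TestDeterminism:
    def test_identical_seed_bitwise(self, wt_network):
        kw = dict(grid_dt=300.0, seed=123,
                  dose=DoseSchedule.pulse(1800.0, 50))
        a = simulate_cell(wt_network, 7200.0, **kw)
        b = simulate_cell(wt_network, 7200.0, **kw)
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(a.fire_counts, b.fire_counts)
        assert np.array_equal(a.pending, b.pending)

    def test_different_seeds_differ(self, wt_network):
        a = simulate_cell(wt_network, 7200.0, grid_dt=300.0, seed=1)
        b = simulate_cell(wt_network, 7200.0, grid_dt=300.0, seed=2)
        assert not np.array_equal(a.counts, b.counts)

    def test_ensemble_seeding_order_independent(self, birth_death):
        from tetopsim.engine import cell_seed
        seeds = [cell_seed(99, i) for i in range(8)]
        assert len(set(seeds)) == 8
        assert seeds == [cell_seed(99, i) for i in range(8)]


class TestDivision:
    def _state(self, counts):
        return CellState(t=1800.0, volume=2e-15,
                         counts=np.array(counts, dtype=np.int64),
                         pending=[], next_division=1800.0)

    def test_binomial_halving_moments(self):
        rng = np.random.default_rng(11)
        cycle = CellCycleParams()
        mask = np.array([1, 0], dtype=np.uint8)
        finals = []
        for _ in range(400):
            st = self._state([1000, 7])
            divide(st, cycle, rng, mask)
            finals.append(st.counts.copy())
        finals = np.array(finals)
        assert np.all(finals[:, 1] == 7)  # unpartitioned species untouched
        m, sd = finals[:, 0].mean(), finals[:, 0].std(ddof=1)
        assert abs(m - 500.0) < 3 * 15.8 / np.sqrt(400)
        assert sd == pytest.approx(np.sqrt(1000 * 0.25), rel=0.2)

    def test_floor_mode_and_zero(self):
        rng = np.random.default_rng(12)
        cycle = CellCycleParams(halving="floor")
        st = self._state([7, 0])
        divide(st, cycle, rng, np.array([1, 1], dtype=np.uint8))
        assert list(st.counts) == [3, 0]
        assert st.volume == cycle.v0
        assert st.next_division > st.t

    def test_division_times_truncated_normal(self):
        rng = np.random.default_rng(13)
        cycle = CellCycleParams()
        intervals = []
        for _ in range(2000):
            st = self._state([0, 0])
            divide(st, cycle, rng, np.zeros(2, dtype=np.uint8))
            intervals.append(st.next_division - st.t)
        intervals = np.array(intervals)
        assert np.all(intervals > 0)
        assert intervals.mean() == pytest.approx(1800.0, rel=0.02)
        assert intervals.std() == pytest.approx(240.0, rel=0.1)

    def test_dna_and_machinery_not_partitioned_in_simulation(self, wt_network):
        tr = simulate_cell(wt_network, 4 * 3600.0, grid_dt=120.0, seed=21)
        res = conservation_residuals(tr, wt_network)
        assert set(res) == {"tetO1", "tetO2", "tetP_R1", "tetP_R2", "tetP_A",
                            "nsDNA", "RNAp", "Rib"}
        assert all(v == 0 for v in res.values())


class TestDosing:
    def test_pulse_adds_external_tc(self, wt_network):
        tr = simulate_cell(wt_network, 3600.0, grid_dt=60.0, seed=31,
                           dose=DoseSchedule.pulse(1800.0, 400))
        tcex = tr.series("TcEx")
        assert np.all(tcex[tr.grid < 1800.0] == 0)
        assert tcex[tr.grid >= 1800.0][0] == 400
        # influx consumes the pulse over time
        assert tcex[-1] < 400

    def test_clamp_holds_level(self, wt_network):
        tr = simulate_cell(wt_network, 3600.0, grid_dt=60.0, seed=32,
                           dose=DoseSchedule.clamp(600.0, 500))
        tcex = tr.series("TcEx")
        assert np.all(tcex[tr.grid >= 600.0] == 500)
        assert tr.series("Tc")[-1] > 0  # constant influx accumulated

    def test_zero_influx_override_blocks_entry(self):
        # k62 (TetA-mediated re-entry) also zeroed: as printed it recreates
        # intracellular Tc whenever TetA exists, independent of TcEx
        from tetopsim.model import build_tet_network
        net = build_tet_network({"k9": 0.0, "k62": 0.0})
        tr = simulate_cell(net, 3600.0, grid_dt=600.0, seed=33,
                           dose=DoseSchedule.clamp(0.0, 1000))
        assert np.all(tr.series("Tc") == 0)

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            DoseSchedule(((10.0, "pulse_add", 5), (5.0, "clamp", 1)))
        with pytest.raises(ValueError):
            DoseSchedule(((0.0, "bolus", 5),))
        with pytest.raises(ValueError):
            DoseSchedule(((0.0, "pulse_add", -5),))


class TestGuards:
    def test_bad_grid_rejected(self, wt_network):
        with pytest.raises(ValueError):
            simulate_cell(wt_network, -1.0)
        with pytest.raises(ValueError):
            simulate_cell(wt_network, 100.0, grid=np.array([0.0, 200.0]))
        with pytest.raises(ValueError):
            simulate_cell(wt_network, 100.0, grid=np.array([50.0, 50.0]))

    def test_counts_never_negative_on_tet_network(self, wt_network):
        tr = simulate_cell(wt_network, 2 * 3600.0, grid_dt=60.0, seed=41,
                           dose=DoseSchedule.pulse(600.0, 1000))
        assert tr.counts.min() >= 0
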