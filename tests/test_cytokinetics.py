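import math

import numpy as np
import pytest

from radiosim import ModelParameters, presets
from radiosim.cytokinetics import (HIT1, HIT2, UNHIT, CompartmentState,
                                   mitosis_outcome, step_compartments,
                                   summarize_state)


def make_state(params, n=1):
    return CompartmentState(n, params)


class TestStep:
    def test_empty_state_is_fixed_point(self, case0):
        s = make_state(case0)
        d = step_compartments(s)
        assert s.total().sum() == 0
        assert d.births.sum() == 0
        assert d.apoptotic_deaths.sum() == 0

    def test_diff_death_rates_are_linear_fractions(self):
        p = ModelParameters(R_ADiff=0.01, R_NDiff=0.0, R_A=0.0)
        s = make_state(p)
        s.diff[0] = 1000.0
        step_compartments(s)
        assert s.diff[0] == pytest.approx(990.0)
        assert s.apo.sum() == pytest.approx(10.0)

    def test_m_cohort_branching_expectation(self):
        """100 stem finishing M with P_sym=1, P_sleep=0.2: 200 newborns,
        160 to G1 and 40 to G0."""
        p = ModelParameters(P_sym=1.0, P_sleep=0.2, R_A=0.0, R_ADiff=0.0)
        s = make_state(p)
        s.cycle[3][0, 0, UNHIT, -1] = 100.0   # M, about to expire
        d = step_compartments(s)
        assert d.births[0] == pytest.approx(100.0)
        assert s.dormant()[0] == pytest.approx(40.0)
        assert s.cycle[0][0].sum() == pytest.approx(160.0)

    def test_monte_carlo_branching_mean_converges(self):
        """Stochastic-mode division outcomes average to the deterministic
        expectation at the ~1/sqrt(n) rate over seeds."""
        p = ModelParameters(P_sym=1.0, P_sleep=0.2, R_A=0.0, stochastic=True)
        g0_counts = []
        n_seeds = 40
        for seed in range(n_seeds):
            s = make_state(p)
            s.cycle[3][0, 0, UNHIT, -1] = 100.0
            step_compartments(s, rng=np.random.default_rng(seed))
            g0_counts.append(s.dormant()[0])
        mean = np.mean(g0_counts)
        # sd of one draw ~ 2*sqrt(100*0.2*0.8) = 8 -> se ~ 8/sqrt(40)
        assert mean == pytest.approx(40.0, abs=4 * 8 / math.sqrt(n_seeds))

    def test_conservation_identity_over_long_run(self, fast_grower, rng):
        s = make_state(fast_grower, n=3)
        s.seed_stem(100.0, rng)
        for _ in range(500):
            before = s.total()
            d = step_compartments(s)
            after = s.total()
            np.testing.assert_allclose(
                after, before + d.births - d.cleared_apoptotic - d.cleared_necrotic,
                rtol=1e-9, atol=1e-6)

    def test_total_non_decreasing_without_death(self, rng):
        p = ModelParameters(R_A=0.0, R_ADiff=0.0, R_NDiff=0.0,
                            T_G0=1e9, P_G0toG1=1.0)
        s = make_state(p)
        s.seed_stem(100.0, rng)
        prev = s.total()[0]
        for _ in range(300):
            step_compartments(s)
            cur = s.total()[0]
            assert cur >= prev - 1e-9
            prev = cur

    def test_population_doubles_every_cycle(self, rng):
        """Pure symmetric stem growth with no death doubles every T_c."""
        p = ModelParameters(T_c=25.0, P_sym=1.0, P_sleep=0.0, R_A=0.0,
                            R_ADiff=0.0, R_NDiff=0.0)
        s = make_state(p)
        s.cycle[0][0, 0, UNHIT, s.cycle[0].shape[-1] - 1] = 1.0  # entering G1
        n_cycles = 4
        for _ in range(int(25 * n_cycles)):
            step_compartments(s)
        assert s.total()[0] == pytest.approx(2 ** n_cycles, rel=0.1)

    def test_hit_cells_necrose_after_two_mitoses(self):
        """A hit cohort completes two rudimentary cycles, then its entire
        progeny is necrotic; hit offspring never enter G0."""
        p = ModelParameters(T_c=11.0, P_sleep=0.5, P_sym=0.5, R_A=0.0,
                            R_ADiff=0.0, T_N=500.0, T_G0=1e9)
        s = make_state(p)
        s.cycle[0][0, 0, HIT2, -1] = 64.0   # hit(2) stem entering S next
        for _ in range(3 * 11):
            step_compartments(s)
        assert s.cycling()[0] == pytest.approx(0.0, abs=1e-9)
        assert s.dormant()[0] == pytest.approx(0.0, abs=1e-9)
        # 64 -> 128 hit(1) -> 256 necrotic
        assert s.nec.sum() == pytest.approx(256.0)


class TestMitosisOutcome:
    def test_fully_asymmetric_stem_division(self, case0):
        out = mitosis_outcome("STEM", 100, UNHIT, case0.replace(P_sym=0.0))
        assert out["stem"] == 100.0
        assert out["limp"] == {case0.N_LIMP: 100.0}

    def test_fully_symmetric_stem_division(self, case0):
        out = mitosis_outcome("STEM", 100, UNHIT, case0.replace(P_sym=1.0))
        assert out["stem"] == 200.0
        assert out["limp"] == {}

    def test_terminal_limp_division_yields_diff(self, case0):
        out = mitosis_outcome("LIMP", 50, UNHIT, case0, limp_k=1)
        assert out["diff"] == 100.0

    def test_hit1_division_is_necrotic(self, case0):
        out = mitosis_outcome("STEM", 10, HIT1, case0)
        assert out["necrotic"] == 20.0
        assert out["to_g1"] == 0.0 and out["to_g0"] == 0.0

    def test_hit_offspring_skip_dormancy(self, case0):
        out = mitosis_outcome("LIMP", 10, HIT2, case0.replace(P_sleep=0.9),
                              limp_k=3)
        assert out["to_g0"] == 0.0
        assert out["to_g1"] == 20.0

    def test_unknown_category_rejected(self, case0):
        with pytest.raises(ValueError):
            mitosis_outcome("GHOST", 1, UNHIT, case0)


class TestSummary:
    def test_all_diff_composition(self, case0):
        s = make_state(case0)
        s.diff[0] = 500.0
        c = summarize_state(s)
        assert c["diff_frac"] == 100.0
        assert c["gf"] == 0.0

    def test_living_fractions_sum_to_100(self, fast_grower, rng):
        s = make_state(fast_grower, n=2)
        s.seed_stem(100.0, rng)
        for _ in range(200):
            step_compartments(s)
        c = summarize_state(s)
        assert c["gf"] + c["diff_frac"] + c["g0_frac"] == pytest.approx(100.0)

    def test_only_dead_cells_is_error(self, case0):
        s = make_state(case0)
        s.nec[0, 0] = 10.0
        with pytest.raises(ValueError):
            summarize_state(s)

    def test_empty_state_is_error(self, case0):
        with pytest.raises(ValueError):
            summarize_state(make_state(case0))


class TestHourlyG0Variant:
    def test_literal_hourly_exit_empties_dormant_pool_fast(self):
        """Under the per-hour-fraction reading, P_G0toG1 = 0.5 drains G0
        within a few hours (geometric residence ~2 h)."""
        p = ModelParameters(g0_exit="hourly", P_G0toG1=0.5, R_A=0.0)
        s = make_state(p)
        s.g0_age[0, 0, UNHIT, 0] = 1000.0
        step_compartments(s)
        assert s.dormant()[0] == pytest.approx(500.0)
        for _ in range(9):
            step_compartments(s)
        assert s.dormant()[0] < 1.5
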