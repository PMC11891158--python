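import numpy as np
import pytest

from radiosim import (Radiosensitivity, RTSchedule, TumorMesh,
                      bootstrap_equilibrium, init_mesh, make_schedule,
                      run_simulation, volume_reduction)
from radiosim.analysis import make_well_mixed_mesh


@pytest.fixture(scope="module")
def fast_eq():
    from radiosim import ModelParameters
    p = ModelParameters(T_c=31, T_G0=50, T_N=10, T_A=5, N_LIMP=2,
                        R_A=1e-4, R_NDiff=0, R_ADiff=1e-4,
                        P_G0toG1=0.9, P_sleep=0.05, P_sym=0.9)
    eq = bootstrap_equilibrium(p, n_gcs=3, rng=np.random.default_rng(0),
                               max_days=400)
    return p, eq


def well_mixed(p, eq, seed=0, **over):
    return make_well_mixed_mesh(p.replace(**over), eq,
                                rng=np.random.default_rng(seed))


class TestRunContracts:
    def test_free_growth_mode_rejects_schedule(self, fast_eq):
        p, eq = fast_eq
        mesh = well_mixed(p, eq, mode=1)
        with pytest.raises(ValueError):
            run_simulation(mesh, rs=Radiosensitivity.from_alpha(0.1),
                           schedule=make_schedule(0, 5, 2.0))

    def test_schedule_requires_radiosensitivity(self, fast_eq):
        p, eq = fast_eq
        mesh = well_mixed(p, eq, mode=2)
        with pytest.raises(ValueError):
            run_simulation(mesh, schedule=make_schedule(0, 5, 2.0))

    def test_zero_effect_radiation_equals_free_growth(self, fast_eq):
        """A schedule with alpha = beta = 0 leaves the trajectory identical
        to the untreated run under the same seed."""
        p, eq = fast_eq
        free = run_simulation(well_mixed(p, eq, mode=1), t_end_hours=240)
        rs = Radiosensitivity(0, 0, 0, 0, 0, 0)
        treated = run_simulation(well_mixed(p, eq, mode=2), rs=rs,
                                 schedule=make_schedule(0, 5, 2.0),
                                 t_end_hours=240)
        np.testing.assert_allclose(free.frame["total"], treated.frame["total"])

    def test_byte_identical_repetition(self, fast_eq):
        p, eq = fast_eq
        a = run_simulation(well_mixed(p, eq, seed=4, mode=1), t_end_hours=120)
        b = run_simulation(well_mixed(p, eq, seed=4, mode=1), t_end_hours=120)
        assert a.frame.equals(b.frame)


class TestTreatmentDirection:
    def test_higher_alpha_shrinks_more(self, fast_eq):
        p, eq = fast_eq
        sched = make_schedule(0, 10, 2.0)
        finals = {}
        for alpha in (0.009254, 0.15):
            rs = Radiosensitivity.from_alpha(alpha, 3.0, OER=2.388)
            out = run_simulation(well_mixed(p, eq, mode=2), rs=rs,
                                 schedule=sched, t_end_hours=24 * 21)
            finals[alpha] = out.frame["volume_mm3"].iloc[-1]
        assert finals[0.15] < finals[0.009254]

    def test_lower_oer_shrinks_more(self, fast_eq):
        """OER = 1 makes dormant/S-phase cells as sensitive as cycling ones,
        so the kill is larger than with a hypoxic-protection OER."""
        p, eq = fast_eq
        sched = make_schedule(0, 10, 2.0)
        finals = {}
        for oer in (2.388, 1.0):
            rs = Radiosensitivity.from_alpha(0.05, 3.0, OER=oer)
            out = run_simulation(well_mixed(p, eq, mode=2), rs=rs,
                                 schedule=sched, t_end_hours=24 * 21)
            finals[oer] = out.frame["volume_mm3"].iloc[-1]
        assert finals[1.0] < finals[2.388]

    def test_dead_fraction_rises_then_clears(self, fast_eq):
        p, eq = fast_eq
        rs = Radiosensitivity.from_alpha(0.3, 3.0)
        out = run_simulation(well_mixed(p, eq, mode=2), rs=rs,
                             schedule=make_schedule(0, 5, 2.0),
                             t_end_hours=24 * 15, record_stride=24)
        dead = out.frame["dead_frac"].to_numpy()
        peak = dead.argmax()
        assert dead[peak] > dead[0]          # transient rise
        assert dead[-1] < dead[peak]         # pools clear after T_A / T_N

    def test_irradiation_events_logged(self, fast_eq):
        p, eq = fast_eq
        rs = Radiosensitivity.from_alpha(0.1, 3.0)
        out = run_simulation(well_mixed(p, eq, mode=2), rs=rs,
                             schedule=make_schedule(0, 3, 2.0),
                             t_end_hours=24 * 5)
        irr = [e for e in out.events if e["event"] == "irradiation"]
        assert len(irr) == 3
        assert all(e["hit_cells"] > 0 for e in irr)


class TestVolumeReduction:
    def _const_output(self, v0, v1):
        import pandas as pd
        from radiosim.engine import SimulationOutput, _COLUMNS
        rows = [[0.0, v0] + [0.0] * 13, [24.0, v1] + [0.0] * 13]
        return SimulationOutput(frame=pd.DataFrame(rows, columns=_COLUMNS))

    def test_half_volume_is_fifty_percent(self):
        assert volume_reduction(self._const_output(100, 50), 0, 24) == 50.0

    def test_no_change_is_zero(self):
        assert volume_reduction(self._const_output(80, 80), 0, 24) == 0.0

    def test_regrowth_is_negative(self):
        assert volume_reduction(self._const_output(50, 100), 0, 24) == -100.0

    def test_zero_initial_volume_rejected(self):
        with pytest.raises(ValueError):
            volume_reduction(self._const_output(0, 10), 0, 24)

    def test_reversed_times_rejected(self):
        with pytest.raises(ValueError):
            volume_reduction(self._const_output(10, 5), 24, 0)


class TestSelfConsistency:
    def test_composition_stays_near_bootstrap_equilibrium(self, fast_eq):
        """Free growth from an initialised tumor keeps the composition the
        bootstrap found (engine/initialisation consistency)."""
        p, eq = fast_eq
        out = run_simulation(well_mixed(p, eq, mode=1), t_end_hours=24 * 20)
        last = out.frame.iloc[-1]
        assert last["gf"] == pytest.approx(eq.gf, rel=0.05)
        assert last["diff_frac"] == pytest.approx(eq.diff_frac, rel=0.05)
        assert last["g0_frac"] == pytest.approx(eq.g0_frac, rel=0.05)
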