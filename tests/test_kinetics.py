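"""Kinetics engine: rate laws, integration accuracy, conservation, metrics."""

import dataclasses

import numpy as np
import pytest

from ibusynth.kinetics import (
    INPUT_NAMES,
    DESIGN_BOUNDS,
    IntegrationError,
    KineticsConfig,
    SimulationInput,
    Trajectory,
    compile_mechanism,
    extract_metrics,
    rate_vector,
    reference_inputs,
    simulate,
)
from ibusynth.mechanism import MechanismSpec, Reaction, canonical_mechanism

from conftest import random_bounded_inputs


def perturbed_input(**overrides) -> SimulationInput:
    """Reference point with arbitrary coordinate overrides (bounds not checked)."""
    vals = dict(zip(INPUT_NAMES, reference_inputs().to_array()))
    vals.update(overrides)
    return SimulationInput.from_array([vals[n] for n in INPUT_NAMES], perturbed=True)


@pytest.fixture(scope="module")
def mech():
    return canonical_mechanism()


@pytest.fixture(scope="module")
def compiled(mech):
    return compile_mechanism(mech)


class TestSimulationInput:
    def test_requires_14_positive_values(self):
        with pytest.raises(ValueError):
            SimulationInput.from_array([1.0] * 13)
        with pytest.raises(ValueError):
            perturbed_input(x1=-1.0)

    def test_out_of_bounds_rejected_unless_perturbed(self):
        vals = reference_inputs().to_array()
        vals[4] = 10.0  # far above the catalyst bound
        with pytest.raises(ValueError, match="x5"):
            SimulationInput.from_array(vals)
        SimulationInput.from_array(vals, perturbed=True)  # allowed when flagged

    def test_rate_constant_lookup(self):
        inp = reference_inputs()
        assert inp.rate_constant("k1") == inp["x6"]
        assert inp.rate_constant("k8r") == inp["x14"]
        with pytest.raises(KeyError):
            inp.rate_constant("k99")


class TestRateVector:
    def test_all_zero_concentrations_give_zero_rates(self, mech):
        rates = rate_vector(np.zeros(12), mech, reference_inputs())
        assert np.all(rates == 0)

    def test_r1_hand_value(self, mech):
        # r1 rate = k1 * c_roh * c_H+ = 0.5 * 2 * 3 = 3.0
        conc = np.zeros(12)
        conc[mech.species.index("roh")] = 2.0
        conc[mech.species.index("hp")] = 3.0
        rates = rate_vector(conc, mech, perturbed_input(x6=0.5))
        assert rates[0] == pytest.approx(3.0)

    def test_r2_hand_value(self, mech):
        # r2 rate = k2 * c_ren * c_H+ * c_Cl- = 0.1 * 1 * 2 * 0.5 = 0.1
        conc = np.zeros(12)
        conc[mech.species.index("ren")] = 1.0
        conc[mech.species.index("hp")] = 2.0
        conc[mech.species.index("cl")] = 0.5
        rates = rate_vector(conc, mech, perturbed_input(x7=0.1))
        assert rates[1] == pytest.approx(0.1)

    def test_negative_concentration_rejected(self, mech):
        conc = np.zeros(12)
        conc[0] = -1e-3
        with pytest.raises(ValueError, match="negative"):
            rate_vector(conc, mech, reference_inputs())


class TestSimulate:
    def test_first_order_decay_closed_form(self):
        # single reaction roh -> ren at unit rate constant: roh(t) = e^{-t}
        toy = MechanismSpec(
            species=("roh", "ren"),
            constant_species={},
            reactions=(Reaction("decay", {"roh": 1}, {"roh": -1.0, "ren": 1.0}, "k1"),),
        )
        inp = perturbed_input(x1=1.0, x6=1.0)
        cfg = KineticsConfig(t_end=10.0, t_first=0.01, rtol=1e-10, atol=1e-14)
        traj = simulate(inp, toy, cfg)
        assert traj.concentration("roh")[-1] == pytest.approx(np.exp(-10.0), abs=1e-8)

    def test_no_catalyst_means_no_product(self, mech):
        traj = simulate(perturbed_input(x5=0.0), mech, KineticsConfig())
        assert np.all(traj.concentration("ibu") == 0)
        assert np.all(traj.concentration("pd2") == 0)

    def test_matches_rk4_oracle_at_reference(self, compiled):
        _assert_rk4_agreement(compiled, reference_inputs(), t_end=60.0, dt=1e-3)

    def test_matches_rk4_oracle_random_inputs(self, compiled):
        X = random_bounded_inputs(20, seed=5).to_numpy()
        for row in X:
            _assert_rk4_agreement(
                compiled, SimulationInput.from_array(row), t_end=10.0, dt=1e-3
            )

    def test_failure_carries_input_for_triage(self):
        inp = reference_inputs()
        err = IntegrationError("boom", inp)
        assert err.input is inp
        assert "inputs:" in str(err)  # design vector visible in the message


def _assert_rk4_agreement(compiled, inp, t_end, dt):
    """Adaptive solution endpoint vs a brute-force fixed-step RK4 oracle."""
    cfg = KineticsConfig(t_end=t_end, t_first=min(1.0, t_end / 10))
    traj = simulate(inp, compiled, cfg)
    from ibusynth.kinetics import _initial_state, _rate_constants

    k = _rate_constants(compiled, inp) * compiled.const_factor
    O, ST = compiled.orders, compiled.stoich.T

    def f(c):
        return ST @ (k * np.prod(c[None, :] ** O, axis=1))

    c = _initial_state(compiled, inp)
    n_steps = int(round(t_end / dt))
    for _ in range(n_steps):
        k1 = f(c)
        k2 = f(c + 0.5 * dt * k1)
        k3 = f(c + 0.5 * dt * k2)
        k4 = f(c + dt * k3)
        c = c + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    scale = max(c.max(), 1e-12)
    np.testing.assert_allclose(
        traj.concentrations[-1], c, rtol=1e-6, atol=1e-6 * scale
    )


@pytest.fixture(scope="module")
def trajectories(compiled):
    X = random_bounded_inputs(100, seed=77).to_numpy()
    cfg = KineticsConfig()
    out = []
    for row in X:
        inp = SimulationInput.from_array(row)
        out.append((inp, simulate(inp, compiled, cfg)))
    return out


class TestConservation:
    """Stoichiometric conservation laws of the carbonylation network."""

    def test_pd_conserved(self, trajectories):
        for inp, traj in trajectories:
            pd_total = sum(traj.concentration(s) for s in ("pd1", "pd2", "pd3", "pd4"))
            np.testing.assert_allclose(pd_total, inp["x5"], rtol=1e-6)

    def test_aryl_backbone_conserved(self, trajectories):
        for inp, traj in trajectories:
            aryl = (
                traj.concentration("roh") + traj.concentration("ren")
                + traj.concentration("rcl") + traj.concentration("pd3")
                + traj.concentration("pd4") + traj.concentration("ibu")
                + 2.0 * traj.concentration("ester")
            )
            np.testing.assert_allclose(aryl, inp["x1"], rtol=1e-6)

    def test_chlorine_conserved(self, trajectories):
        for inp, traj in trajectories:
            cl = (
                traj.concentration("cl") + traj.concentration("rcl")
                + 2.0 * traj.concentration("pd1") + traj.concentration("pd3")
                + traj.concentration("pd4")
            )
            np.testing.assert_allclose(cl, inp["x2"] + 2.0 * inp["x5"], rtol=1e-6)

    def test_conversion_in_unit_interval(self, trajectories):
        cfg = KineticsConfig()
        for inp, traj in trajectories:
            _, cr, _ = extract_metrics(traj, inp, cfg)
            assert 0.0 <= cr <= 1.0


class TestToleranceRobustness:
    def test_halving_tolerances_barely_moves_metrics(self, compiled):
        X = random_bounded_inputs(100, seed=123).to_numpy()
        cfg = KineticsConfig()
        tight = dataclasses.replace(cfg, rtol=cfg.rtol / 2, atol=cfg.atol / 2)
        for row in X:
            inp = SimulationInput.from_array(row)
            rt1, cr1, _ = extract_metrics(simulate(inp, compiled, cfg), inp, cfg)
            rt2, cr2, _ = extract_metrics(simulate(inp, compiled, tight), inp, tight)
            assert abs(rt1 - rt2) / max(rt2, 1e-12) < 0.005
            assert abs(cr1 - cr2) < 0.001


class TestExtractMetrics:
    def _traj(self, t, c):
        conc = np.zeros((len(t), 12))
        species = canonical_mechanism().species
        conc[:, species.index("ibu")] = c
        return Trajectory(time_grid=t, concentrations=conc, species=species)

    def test_exponential_rise_crossing(self):
        # c(t) = c_inf (1 - e^{-t/tau}): the 99% crossing sits at tau*ln(100)
        tau, c_inf = 3600.0, 0.05
        cfg = KineticsConfig()
        t = cfg.time_grid()
        traj = self._traj(t, c_inf * (1.0 - np.exp(-t / tau)))
        rt, cr, censored = extract_metrics(traj, perturbed_input(x1=0.1), cfg)
        expected_h = tau * np.log(100.0) / 3600.0
        # within one (geometric) grid step of the analytic crossing
        assert rt == pytest.approx(expected_h, rel=0.05)
        assert not censored
        assert cr == pytest.approx(0.99 * c_inf / 0.1, rel=1e-3)

    def test_zero_trajectory_is_censored(self):
        cfg = KineticsConfig()
        t = cfg.time_grid()
        rt, cr, censored = extract_metrics(
            self._traj(t, np.zeros_like(t)), perturbed_input(x1=0.1), cfg
        )
        assert censored
        assert rt == cfg.t_end / 3600.0
        assert cr == 0.0

    def test_plateau_from_start_gives_first_grid_time(self):
        cfg = KineticsConfig()
        t = cfg.time_grid()
        rt, cr, censored = extract_metrics(
            self._traj(t, np.full_like(t, 0.08)), perturbed_input(x1=0.1), cfg
        )
        assert rt == t[0] / 3600.0 == 0.0
        assert not censored

    def test_nonpositive_substrate_rejected(self):
        cfg = KineticsConfig()
        t = cfg.time_grid()
        with pytest.raises(ValueError, match="x1"):
            extract_metrics(
                self._traj(t, np.zeros_like(t)), perturbed_input(x1=0.0), cfg
            )
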