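"""Network solver tests: closed forms, conservation, oracle equivalence,
pulsatile consistency, Reynolds numbers and backflow detection."""

import math
from dataclasses import replace

import numpy as np
import pytest

from emboflow import (
    BoundaryConditions,
    ConfigurationError,
    LaminarFlowWarning,
    PulsatileWaveform,
    TreeGenConfig,
    detect_backflow,
    distribute_outlet_pressure,
    generate_tree,
    reynolds,
    segment_resistance,
    solve_pulsatile,
    solve_steady,
)
from emboflow.stall import analytic_stall_pressure

from conftest import make_two_outlet, two_outlet_resistances


def conservation_residuals(tree, sol):
    """Relative junction mass residual at every internal junction."""
    res = []
    for sid in tree.segments:
        kids = tree.children_of(sid)
        if kids:
            q_in = sol.segment_flows[sid]
            q_out = sum(sol.segment_flows[k] for k in kids)
            scale = max(abs(q_in), abs(q_out), 1e-30)
            res.append(abs(q_in - q_out) / scale)
    return res


class TestSegmentResistance:
    def test_hand_evaluated_value(self):
        assert segment_resistance(0.01, 0.001, 0.0035) == pytest.approx(
            8.9127e7, rel=1e-4
        )

    def test_quartic_and_linear_scaling(self):
        base = segment_resistance(0.01, 0.001, 0.0035)
        assert segment_resistance(0.01, 0.002, 0.0035) == pytest.approx(base / 16)
        assert segment_resistance(0.02, 0.001, 0.0035) == pytest.approx(2 * base)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            segment_resistance(0.0, 0.001, 0.0035)


class TestDistributeOutletPressure:
    def test_equal_areas_split_evenly(self):
        p = distribute_outlet_pressure(5000.0, {f"o{i}": 2e-6 for i in range(10)})
        assert all(v == pytest.approx(500.0) for v in p.values())

    def test_proportional_split(self):
        p = distribute_outlet_pressure(1000.0, {"a": 3e-6, "b": 1e-6})
        assert p["a"] == pytest.approx(750.0)
        assert p["b"] == pytest.approx(250.0)

    def test_parts_sum_to_total(self):
        rng = np.random.default_rng(0)
        areas = {f"o{i}": float(a) for i, a in enumerate(rng.uniform(1e-7, 1e-5, 17))}
        p = distribute_outlet_pressure(4321.0, areas)
        assert math.fsum(p.values()) == pytest.approx(4321.0, abs=1e-9)

    def test_zero_total_gives_zeros(self):
        p = distribute_outlet_pressure(0.0, {"a": 1e-6, "b": 2e-6})
        assert set(p.values()) == {0.0}

    def test_bad_input_rejected(self):
        with pytest.raises(ValueError):
            distribute_outlet_pressure(100.0, {})
        with pytest.raises(ValueError):
            distribute_outlet_pressure(100.0, {"a": -1e-6})


class TestSolveSteady:
    def test_symmetric_y_splits_evenly(self, y_tree):
        sol = solve_steady(y_tree, BoundaryConditions(inlet_flow=4e-6))
        assert sol.segment_flows["L"] == pytest.approx(2e-6, rel=1e-12)
        assert sol.segment_flows["R"] == pytest.approx(2e-6, rel=1e-12)

    def test_two_outlet_closed_form(self, two_outlet):
        r1, r2 = two_outlet_resistances(two_outlet)
        q, p1, p2 = 5e-6, 800.0, 300.0
        bc = BoundaryConditions(
            inlet_flow=q, outlet_pressures={"tgt": p1, "oth": p2}
        )
        sol = solve_steady(two_outlet, bc)
        expected = (q * r2 + (p2 - p1)) / (r1 + r2)
        assert sol.segment_flows["tgt"] == pytest.approx(expected, rel=1e-12)
        assert sol.segment_flows["oth"] == pytest.approx(q - expected, rel=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_dense_oracle_on_small_trees(self, dense_oracle, seed):
        """Sparse reduced solve == brute-force dense solve on <=8-segment
        trees, to 1e-9 relative."""
        tree = generate_tree(
            TreeGenConfig(
                total_outlet_count=4,
                target_outlet_count=1,
                target_depth=2,
                random_seed=seed,
            )
        )
        assert len(tree) <= 8
        bc = BoundaryConditions(
            inlet_flow=5e-6, target_total_pressure=700.0, non_target_pressure=300.0
        )
        sol = solve_steady(tree, bc)
        ref = dense_oracle(tree, bc)
        for sid in tree.segments:
            assert sol.segment_flows[sid] == pytest.approx(ref[sid], rel=1e-9)

    @pytest.mark.parametrize("pressure", [0.0, 2000.0, 5000.0])
    def test_mass_conserved_everywhere(self, fixture_tree, baseline_bc, pressure):
        bc = replace(baseline_bc, target_total_pressure=pressure)
        sol = solve_steady(fixture_tree, bc)
        assert max(conservation_residuals(fixture_tree, sol)) < 1e-10
        leaf_sum = math.fsum(sol.segment_flows[l] for l in fixture_tree.leaf_ids)
        assert leaf_sum == pytest.approx(5e-6, rel=1e-10)

    def test_flows_affine_in_inputs(self, fixture_tree):
        """Superposition: segment flows are affine in inlet flow and in any
        outlet pressure (second difference over three operating points = 0)."""
        sid = fixture_tree.target_branch_id
        flows_q = []
        for q in (2e-6, 5e-6, 8e-6):
            sol = solve_steady(fixture_tree, BoundaryConditions(inlet_flow=q))
            flows_q.append(sol.segment_flows[sid])
        assert flows_q[0] - 2 * flows_q[1] + flows_q[2] == pytest.approx(
            0.0, abs=1e-15
        )
        flows_p = []
        for p in (0.0, 1500.0, 3000.0):
            sol = solve_steady(
                fixture_tree,
                BoundaryConditions(inlet_flow=5e-6, target_total_pressure=p),
            )
            flows_p.append(sol.segment_flows[sid])
        assert flows_p[0] - 2 * flows_p[1] + flows_p[2] == pytest.approx(
            0.0, abs=1e-15
        )

    def test_laminar_warning_above_limit(self, fixture_tree):
        with pytest.warns(LaminarFlowWarning):
            solve_steady(fixture_tree, BoundaryConditions(inlet_flow=50e-6))

    def test_unknown_outlet_pressure_key_rejected(self, y_tree):
        bc = BoundaryConditions(inlet_flow=1e-6, outlet_pressures={"root": 0.0})
        with pytest.raises(ConfigurationError, match="non-leaf"):
            solve_steady(y_tree, bc)


class TestReynolds:
    def test_reproduces_baseline_inlet_value(self, fixture_tree, baseline_bc):
        """Re = 4*rho*Q/(pi*mu*D) at 5 cm^3/s through a 4.62 mm vessel
        is ~417."""
        sol = solve_steady(fixture_tree, baseline_bc)
        re = reynolds(sol, fixture_tree)
        assert re[fixture_tree.inlet_id] == pytest.approx(417.0, rel=0.01)

    def test_zero_flow_zero_re_and_linearity(self, y_tree):
        sol1 = solve_steady(y_tree, BoundaryConditions(inlet_flow=1e-6))
        sol2 = solve_steady(y_tree, BoundaryConditions(inlet_flow=2e-6))
        re1, re2 = reynolds(sol1, y_tree), reynolds(sol2, y_tree)
        for sid in y_tree.segments:
            assert re2[sid] == pytest.approx(2 * re1[sid], rel=1e-12)
        sol0 = solve_steady(y_tree, BoundaryConditions(inlet_flow=0.0))
        assert max(reynolds(sol0, y_tree).values()) < 1e-10

    def test_velocity_consistent_with_flow(self, fixture_tree, baseline_bc):
        sol = solve_steady(fixture_tree, baseline_bc)
        for s in fixture_tree:
            assert sol.segment_velocities[s.segment_id] == pytest.approx(
                sol.segment_flows[s.segment_id] / (math.pi * s.radius**2), rel=1e-12
            )


class TestWaveform:
    def test_default_has_unit_pulsatility_and_exact_mean(self):
        wf = PulsatileWaveform.default()
        assert wf.pulsatility_index == pytest.approx(1.0, rel=1e-9)
        t = wf.sample(n_steps=512)
        assert np.mean(wf.flow_at(t)) == pytest.approx(wf.mean_flow, rel=1e-9)

    def test_nonpositive_waveform_rejected(self):
        with pytest.raises(ConfigurationError, match="positive"):
            PulsatileWaveform(mean_flow=5e-6, harmonic_amplitudes=(1.5,),
                              harmonic_phases=(0.0,))


class TestSolvePulsatile:
    def test_constant_waveform_reduces_to_steady(self, y_tree):
        wf = PulsatileWaveform(
            mean_flow=4e-6, harmonic_amplitudes=(), harmonic_phases=()
        )
        sols = solve_pulsatile(
            y_tree, BoundaryConditions(inlet_flow=wf), n_steps=16
        )
        steady = solve_steady(y_tree, BoundaryConditions(inlet_flow=4e-6))
        for sol in sols:
            for sid in y_tree.segments:
                assert sol.segment_flows[sid] == pytest.approx(
                    steady.segment_flows[sid], rel=1e-12
                )

    def test_symmetric_split_at_every_step(self, y_tree):
        wf = PulsatileWaveform.default(mean_flow=4e-6)
        sols = solve_pulsatile(y_tree, BoundaryConditions(inlet_flow=wf), n_steps=32)
        for sol in sols:
            q_in = sol.segment_flows["root"]
            assert sol.segment_flows["L"] == pytest.approx(q_in / 2, rel=1e-12)

    def test_uniform_pressure_outlet_curve_mirrors_inlet(self, fixture_tree):
        """With uniform outlet pressures the summed target-outlet flow is
        the inlet waveform scaled by a constant split fraction: correlation
        exactly 1."""
        wf = PulsatileWaveform.default()
        sols = solve_pulsatile(
            fixture_tree, BoundaryConditions(inlet_flow=wf), n_steps=64
        )
        inlet = [s.segment_flows[fixture_tree.inlet_id] for s in sols]
        target = [
            sum(s.segment_flows[l] for l in fixture_tree.target_leaf_ids)
            for s in sols
        ]
        r = np.corrcoef(inlet, target)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_time_average_matches_steady_at_mean(self, fixture_tree):
        wf = PulsatileWaveform.default()
        sols = solve_pulsatile(
            fixture_tree, BoundaryConditions(inlet_flow=wf), n_steps=64, n_periods=2
        )
        steady = solve_steady(fixture_tree, BoundaryConditions(inlet_flow=wf.mean_flow))
        for sid in fixture_tree.segments:
            avg = math.fsum(s.segment_flows[sid] for s in sols) / len(sols)
            assert avg == pytest.approx(steady.segment_flows[sid], rel=1e-9)

    def test_requires_waveform_and_enough_steps(self, y_tree):
        with pytest.raises(ConfigurationError):
            solve_pulsatile(y_tree, BoundaryConditions(inlet_flow=1e-6))
        wf = PulsatileWaveform.default()
        with pytest.raises(ConfigurationError):
            solve_pulsatile(y_tree, BoundaryConditions(inlet_flow=wf), n_steps=8)


class TestDetectBackflow:
    def test_uniform_pressures_no_backflow(self, fixture_tree, baseline_bc):
        assert detect_backflow(solve_steady(fixture_tree, baseline_bc)) == set()

    def test_above_stall_target_branch_retrograde(self, two_outlet):
        r1, r2 = two_outlet_resistances(two_outlet)
        q = 5e-6
        bc = BoundaryConditions(inlet_flow=q, non_target_pressure=300.0)
        p_star = 300.0 + q * r2  # closed-form zero-flow stall
        sol = solve_steady(
            two_outlet, replace(bc, target_total_pressure=1.2 * p_star)
        )
        assert ("tgt", 0.0) in detect_backflow(sol)

    def test_pulsatile_episodes_in_diastole_only(self, fixture_tree):
        """With the target pressure between the diastolic and systolic
        instantaneous stalls, retrograde episodes occupy part of the cycle."""
        wf = PulsatileWaveform.default()
        t = wf.sample(64)
        q = wf.flow_at(t)
        stall_min = analytic_stall_pressure(
            fixture_tree, BoundaryConditions(inlet_flow=float(q.min()))
        )
        stall_max = analytic_stall_pressure(
            fixture_tree, BoundaryConditions(inlet_flow=float(q.max()))
        )
        p_mid = 0.5 * (stall_min + stall_max)
        bc = BoundaryConditions(inlet_flow=wf, target_total_pressure=p_mid)
        episodes = detect_backflow(solve_pulsatile(fixture_tree, bc, n_steps=64))
        assert episodes
        times_retro = {
            t for sid, t in episodes if sid == fixture_tree.target_branch_id
        }
        assert 0 < len(times_retro) < 64
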