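"""Logic-circuit scoring tests: truth tables, theta, net fold-change."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from switchscreen.errors import (
    DegenerateMeasurementError,
    InvalidParameterError,
)
from switchscreen.gates import (
    GateMeasurement,
    enumerate_and_gate_assignments,
    evaluate_gate_panel,
    evaluate_half_subtractor,
    net_fold_change,
    truth_table,
    vector_proximity_angle,
)


class TestTruthTables:
    @pytest.mark.parametrize(
        "name,outputs",
        [
            ("AND", (0, 0, 0, 1)),
            ("NOR", (1, 0, 0, 0)),
            ("XOR", (0, 1, 1, 0)),
            ("NIMPLY", (0, 1, 0, 0)),
            ("NAND", (1, 1, 1, 0)),
            ("OR", (0, 1, 1, 1)),
        ],
    )
    def test_canonical_outputs(self, name, outputs):
        assert truth_table(name).outputs == outputs

    def test_unknown_gate_raises(self):
        with pytest.raises(InvalidParameterError):
            truth_table("XNORISH")


class TestNetFoldChange:
    def test_flat_output_scores_one(self):
        assert net_fold_change([3.0, 3, 3, 3], truth_table("AND")) == 1.0

    def test_and_examples(self):
        assert net_fold_change([1.0, 1, 1, 10], truth_table("AND")) == pytest.approx(10.0)
        assert net_fold_change([2.0, 1, 3, 12], truth_table("AND")) == pytest.approx(6.0)

    def test_multi_on_states_use_mean(self):
        # XOR: ON mean (8+4)/2 = 6, OFF mean (1+2)/2 = 1.5
        assert net_fold_change([1.0, 8, 4, 2], truth_table("XOR")) == pytest.approx(4.0)

    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_global_rescaling_invariance(self, c):
        vec = [1.0, 2.0, 0.5, 9.0]
        table = truth_table("AND")
        assert net_fold_change([v * c for v in vec], table) == pytest.approx(
            net_fold_change(vec, table)
        )


class TestVectorProximityAngle:
    def test_proportional_output_is_zero_degrees(self):
        assert vector_proximity_angle([0, 0, 0, 7.5], truth_table("AND")) == pytest.approx(0.0)

    def test_complement_output_is_ninety_degrees(self):
        assert vector_proximity_angle([1.0, 1, 1, 0], truth_table("AND")) == pytest.approx(90.0)

    def test_uniform_output_is_sixty_degrees_for_and(self):
        assert vector_proximity_angle([4.0, 4, 4, 4], truth_table("AND")) == pytest.approx(60.0)

    @given(st.floats(min_value=0.01, max_value=1000.0))
    def test_scale_invariance(self, c):
        vec = np.array([0.5, 1.0, 0.2, 8.0])
        table = truth_table("AND")
        assert vector_proximity_angle(vec * c, table) == pytest.approx(
            vector_proximity_angle(vec, table)
        )

    @pytest.mark.parametrize("name", ["AND", "NOR", "XOR", "NIMPLY"])
    def test_complement_is_worst_case_for_any_table(self, name):
        table = truth_table(name)
        complement = [1.0 - o for o in table.outputs]
        assert vector_proximity_angle(complement, table) == pytest.approx(90.0)

    def test_zero_observed_vector_raises(self):
        with pytest.raises(DegenerateMeasurementError):
            vector_proximity_angle([0.0, 0, 0, 0], truth_table("AND"))


class TestPanelEvaluation:
    def test_ideal_panel_all_pass(self):
        table = truth_table("AND")
        ms = [
            GateMeasurement(circuit_id=f"g{i}", ni=(1e-9, 1e-9, 1e-9, float(i + 1)))
            for i in range(5)
        ]
        scores, n_pass = evaluate_gate_panel(ms, table)
        assert n_pass == 5 and all(s.passed for s in scores)

    def test_cutoff_boundary_is_inclusive(self):
        table = truth_table("AND")
        vec = (0.3, 0.3, 0.3, 5.0)
        theta = vector_proximity_angle(vec, table)
        _, n_pass = evaluate_gate_panel(
            [GateMeasurement(circuit_id="g", ni=vec)], table, angle_cutoff=theta
        )
        assert n_pass == 1

    def test_leaky_gates_fail(self):
        table = truth_table("AND")
        ms = [
            GateMeasurement(circuit_id="good", ni=(0.2, 0.2, 0.2, 10.0)),
            GateMeasurement(circuit_id="leaky", ni=(5.0, 5.0, 5.0, 10.0)),
        ]
        scores, n_pass = evaluate_gate_panel(ms, table, angle_cutoff=20.0)
        assert n_pass == 1 and scores[0].passed and not scores[1].passed


class TestEnumeration:
    @pytest.mark.parametrize("k,count", [(3, 3), (4, 12), (6, 60)])
    def test_counts(self, k, count):
        ids = [f"S{i}" for i in range(k)]
        circuits = enumerate_and_gate_assignments(ids)
        assert len(circuits) == count
        assert len(set(circuits)) == count

    def test_deterministic_lexicographic_order(self):
        circuits = enumerate_and_gate_assignments(["S3", "S1", "S2"])
        assert circuits == [
            (("S1", "S2"), "S3"),
            (("S1", "S3"), "S2"),
            (("S2", "S3"), "S1"),
        ]

    def test_fewer_than_three_raises(self):
        with pytest.raises(InvalidParameterError):
            enumerate_and_gate_assignments(["S1", "S2"])


class TestCascade:
    def test_levels_alternate_with_each_added_stage(self):
        from switchscreen.gates import cascade_expected_levels

        levels = cascade_expected_levels(4, repression=0.1, on_level=10.0)
        assert levels == [10.0, 1.0, 10.0, 1.0, 10.0]

    def test_simulated_cascade_panel_reproduces_alternation(self):
        """Adding a repression stage flips the measured reporter NI: the
        sign of successive differences alternates through the pipeline."""
        from switchscreen import CellPopulationModel
        from switchscreen.gates import cascade_expected_levels
        from switchscreen.pipeline import summarize_gate_panel
        from switchscreen.simulate import GateSpec, simulate_gate_panel

        levels = cascade_expected_levels(4, repression=0.1, on_level=10.0)
        spec = GateSpec(
            circuit_id="cascade",
            outputs=tuple(1 if lv == 10.0 else 0 for lv in levels),
            on_level=10.0,
            leak_levels=(1.0, 1.0),
        )
        labels = tuple(str(k) for k in range(5))
        ds = simulate_gate_panel(
            [spec], CellPopulationModel(), n_events=1500, seed=8,
            state_labels=labels,
        )
        ni = [m for m in summarize_gate_panel(ds) if m.circuit_id == "cascade"][0].ni
        diffs = np.diff(ni)
        signs = np.sign(diffs)
        assert all(s1 * s2 < 0 for s1, s2 in zip(signs, signs[1:]))
        assert signs[0] < 0  # the first added repressor turns the reporter off


class TestHalfSubtractor:
    def test_ideal_outputs_score_zero_degrees(self):
        # D = XOR, Bo ON only when the second input (subtrahend first
        # operand absent) is present: state [0,1]
        d = (1e-9, 1.0, 1.0, 1e-9)
        bo = (1e-9, 1e-9, 1.0, 1e-9)
        sd, sbo = evaluate_half_subtractor(d, bo, subtrahend="second")
        assert sd.theta_deg == pytest.approx(0.0, abs=1e-3)
        assert sbo.theta_deg == pytest.approx(0.0, abs=1e-3)

    def test_flat_outputs_hit_closed_form_angles(self):
        flat = (1.0, 1.0, 1.0, 1.0)
        sd, sbo = evaluate_half_subtractor(flat, flat)
        assert sd.theta_deg == pytest.approx(45.0)   # arccos(2 / (sqrt(2)*2))
        assert sbo.theta_deg == pytest.approx(60.0)  # arccos(1 / 2)

    def test_subtrahend_orientation_flips_borrow(self):
        bo_first = (0.01, 1.0, 0.01, 0.01)   # ON in [1,0]
        d = (0.01, 1.0, 1.0, 0.01)
        _, s1 = evaluate_half_subtractor(d, bo_first, subtrahend="first")
        _, s2 = evaluate_half_subtractor(d, bo_first, subtrahend="second")
        assert s1.theta_deg < 5.0 < s2.theta_deg

    def test_leaky_measurement_matches_expected_vector_oracle(self):
        leak, on = 0.2, 5.0
        d = (leak, on, on, leak)
        bo = (leak, leak, on, leak)
        sd, sbo = evaluate_half_subtractor(d, bo, subtrahend="second")
        # closed-form angle of the expected (leak-contaminated) vectors
        def angle(vec, truth):
            v, t = np.asarray(vec), np.asarray(truth)
            return math.degrees(
                math.acos(np.dot(v, t) / (np.linalg.norm(v) * np.linalg.norm(t)))
            )
        assert sd.theta_deg == pytest.approx(angle(d, (0, 1, 1, 0)), abs=1e-9)
        assert sbo.theta_deg == pytest.approx(angle(bo, (0, 0, 1, 0)), abs=1e-9)
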