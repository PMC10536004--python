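"""Structure builders, rate matrix, and forward simulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from teacat.model import (
    FECAL_EDGE,
    ABSORPTION_EDGE,
    ModelStructure,
    ParameterSet,
    build_final_structure,
    build_variant_structure,
    observe,
    rate_matrix,
    simulate,
)

from conftest import random_params


class TestStructures:
    def test_final_structure_has_seven_compartments_and_three_sinks(self):
        s = build_final_structure()
        assert len(s.compartments) == 7
        assert set(s.sinks) == {"feces", "urine", "extravascular_loss"}
        assert s.dose_compartment == "upper_GI"

    def test_sinks_have_no_outgoing_edges(self):
        s = build_final_structure()
        assert all(o not in s.sinks for o, _ in s.edges)

    @pytest.mark.parametrize(
        "variant,n_compartments,extra_edges",
        [
            ("no_extravascular", 6, -3),
            ("portal_vein", 8, 1),
            ("biliary_excretion", 7, 1),
            ("enterohepatic", 7, 1),
        ],
    )
    def test_variant_compartment_and_edge_counts(self, variant, n_compartments, extra_edges):
        base = build_final_structure()
        v = build_variant_structure(variant)
        assert len(v.compartments) == n_compartments
        assert len(v.edges) == len(base.edges) + extra_edges

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="unknown variant"):
            build_variant_structure("hepatic_portal_shunt")

    def test_invalid_structures_rejected(self):
        with pytest.raises(ValueError, match="no outgoing edge"):
            ModelStructure(
                ("upper_GI", "plasma"),
                ("urine",),
                (("upper_GI", "plasma"),),
                plasma_compartment="plasma",
            )
        with pytest.raises(ValueError, match="unreachable"):
            ModelStructure(
                ("upper_GI", "plasma"),
                ("urine",),
                (("upper_GI", "urine"), ("plasma", "urine")),
            )


class TestRateMatrix:
    def test_single_compartment_with_loss(self):
        s = ModelStructure(("plasma",), ("urine",), (("plasma", "urine"),),
                           dose_compartment="plasma")
        p = ParameterSet({("plasma", "urine"): 0.7})
        M = rate_matrix(s, p)
        assert M.loc["plasma", "plasma"] == pytest.approx(-0.7)
        assert M.loc["urine", "plasma"] == pytest.approx(0.7)

    def test_zero_coefficients_give_zero_matrix(self, structure):
        p = ParameterSet({e: 0.0 for e in structure.edges})
        assert np.allclose(rate_matrix(structure, p).to_numpy(), 0.0)

    def test_column_sums_vanish_on_final_structure(self, structure, truth):
        M = rate_matrix(structure, truth.parameter_sets["EGCG"])
        assert np.allclose(M.sum(axis=0), 0.0, atol=1e-12)

    def test_missing_coefficient_raises(self, structure):
        p = ParameterSet({ABSORPTION_EDGE: 0.3})
        with pytest.raises(KeyError, match="missing coefficient"):
            rate_matrix(structure, p)


class TestSimulate:
    def test_exponential_decay_closed_form(self):
        s = ModelStructure(("plasma",), ("urine",), (("plasma", "urine"),),
                           dose_compartment="plasma")
        p = ParameterSet({("plasma", "urine"): 1.0})
        traj = simulate(s, p, [0.0, 1.0, 2.0])
        assert traj["plasma"] == pytest.approx([1.0, np.exp(-1), np.exp(-2)], rel=1e-10)
        assert traj["urine"] == pytest.approx([0.0, 1 - np.exp(-1), 1 - np.exp(-2)], rel=1e-10)

    @pytest.mark.parametrize("k1,k2", [(0.7, 2.3), (2.0, 0.31)])
    def test_two_compartment_bateman_solution(self, k1, k2):
        s = ModelStructure(
            ("a", "b"), ("sink",), (("a", "b"), ("b", "sink")), dose_compartment="a",
            plasma_compartment="b", urine_sink="sink",
        )
        p = ParameterSet({("a", "b"): k1, ("b", "sink"): k2})
        t = np.linspace(0.1, 8.0, 25)
        traj = simulate(s, p, t)
        expected = k1 * (np.exp(-k1 * t) - np.exp(-k2 * t)) / (k2 - k1)
        assert np.max(np.abs(traj["b"] - expected)) < 1e-8

    def test_initial_condition_is_unit_bolus(self, structure, truth):
        traj = simulate(structure, truth.parameter_sets["EC"], [0.0, 1.0])
        assert traj["upper_GI"][0] == pytest.approx(1.0)
        for lab in structure.nodes[1:]:
            assert traj[lab][0] == pytest.approx(0.0, abs=1e-12)

    def test_input_validation(self, structure, truth):
        p = truth.parameter_sets["EC"]
        with pytest.raises(ValueError, match="non-decreasing"):
            simulate(structure, p, [1.0, 0.5])
        with pytest.raises(ValueError, match="non-negative"):
            simulate(structure, p, [-1.0, 0.5])
        bad = ParameterSet({e: 1.0 for e in structure.edges})
        bad.values[("plasma", "kidneys")] = -0.1
        with pytest.raises(ValueError, match="negative coefficient"):
            simulate(structure, bad, [0.0, 1.0])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_mass_conservation_and_sink_monotonicity(self, seed):
        structure = build_final_structure()
        rng = np.random.default_rng(seed)
        p = random_params(structure, rng)
        t = np.linspace(0.0, 24.0, 30)
        traj = simulate(structure, p, t)
        assert np.allclose(traj.states.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(traj.states >= -1e-9)
        for sink in structure.sinks:
            assert np.all(np.diff(traj[sink]) >= -1e-9)

    def test_expm_and_ode_backends_agree(self, structure):
        # relative error with a 1e-6 fraction-of-dose floor (a millionth of
        # the dose is far below any observable resolution)
        rng = np.random.default_rng(42)
        t = np.linspace(0.0, 24.0, 20)
        for _ in range(10):
            p = random_params(structure, rng)
            a = simulate(structure, p, t, backend="expm").states
            b = simulate(structure, p, t, backend="ode").states
            assert np.max(np.abs(a - b) / np.maximum(np.abs(a), 1e-6)) < 1e-6


class TestObserve:
    def test_study_schedule_shapes(self, structure, truth):
        plasma_times = (0, 0.25, 0.5, 1, 2, 3, 5, 8, 10, 12)
        urine_ends = (4, 8, 12, 24)
        grid = np.unique(np.concatenate([plasma_times, urine_ends]))
        traj = simulate(structure, truth.parameter_sets["EGC"], grid)
        plasma, urine = observe(traj, structure, plasma_times, urine_ends)
        assert len(plasma) == 10
        assert len(urine) == 4
        assert np.all(np.diff(urine) >= 0)

    def test_zero_transfer_keeps_dose_in_place(self, structure):
        p = ParameterSet({e: 0.0 for e in structure.edges})
        traj = simulate(structure, p, [0.0, 1.0, 12.0])
        plasma, urine = observe(traj, structure, [0.0, 12.0], [1.0])
        assert np.all(plasma == 0.0)
        assert np.all(urine == 0.0)
        assert traj["upper_GI"] == pytest.approx([1.0, 1.0, 1.0])

    def test_off_grid_time_rejected(self, structure, truth):
        traj = simulate(structure, truth.parameter_sets["EGC"], [0.0, 1.0, 2.0])
        with pytest.raises(ValueError, match="not on the simulation grid"):
            observe(traj, structure, [0.5], [2.0])


def test_trajectory_tidy_export(structure, truth):
    traj = simulate(structure, truth.parameter_sets["ECG"], [0.0, 6.0])
    df = traj.to_frame()
    assert list(df.columns) == ["time_h", "compartment", "fraction_of_dose"]
    assert len(df) == 2 * len(structure.nodes)


def test_fecal_edge_linked_at_exactly_twice_absorption(truth):
    for ps in truth.parameter_sets.values():
        assert ps.values[FECAL_EDGE] == pytest.approx(2 * ps.values[ABSORPTION_EDGE], rel=0, abs=0)
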