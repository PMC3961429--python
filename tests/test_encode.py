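"""IP encodings: gate linearizations, variable counts, encoding behaviour."""

import itertools

import pytest

from boolgap import (build_ip_mri_a, build_ip_mri_b, build_ip_mri_c,
                     find_greedy_fvs, linearize_and, linearize_or, to_lp)
from boolgap.fvs import FVSResult
from boolgap.solve import solve_instance


def feasible_outputs(cons, inputs_point, output_var):
    """Enumerate output values satisfying the constraints at a 0/1 point."""
    out = []
    for y in (0, 1):
        point = dict(inputs_point, **{output_var: y})
        ok = True
        for coeffs, rel, rhs in cons:
            val = sum(c * point[v] for v, c in coeffs.items())
            ok &= (val <= rhs if rel == "<=" else
                   val >= rhs if rel == ">=" else val == rhs)
        if ok:
            out.append(y)
    return out


@pytest.mark.parametrize("k", [1, 2, 3, 4])
@pytest.mark.parametrize("gate, expect", [
    (linearize_and, all), (linearize_or, any)])
def test_gate_linearizations_exact_by_truth_table(k, gate, expect):
    xs = [f"x{i}" for i in range(k)]
    cons = gate("y", xs)
    for bits in itertools.product((0, 1), repeat=k):
        point = dict(zip(xs, bits))
        assert feasible_outputs(cons, point, "y") == [int(expect(bits))]


def test_k2_and_matches_standard_form():
    cons = linearize_and("y", ["x1", "x2"])
    assert ({"y": 1, "x1": -1}, "<=", 0) in cons
    assert ({"y": 1, "x2": -1}, "<=", 0) in cons
    assert ({"y": 1, "x1": -1, "x2": -1}, ">=", -1) in cons


def test_empty_gates_rejected():
    with pytest.raises(ValueError):
        linearize_and("y", [])
    with pytest.raises(ValueError):
        linearize_or("y", [])


def test_a_variable_count_formula(cyctrap):
    inst = build_ip_mri_a(cyctrap)
    n_nodes = len(cyctrap.nodes)
    horizon = inst.meta["horizon"]
    assert horizon == n_nodes
    n_decisions = len(inst.meta["decision_units"])
    assert len(inst.variables) == n_nodes * (horizon + 1) + n_decisions
    assert sorted(inst.time_indices) == list(range(horizon + 1))
    # objective touches exactly the insertion decisions, coefficient 1
    assert set(inst.objective.values()) == {1}
    assert all(v.startswith("TER") for v in inst.objective)


def test_c_variable_count_and_two_steps(cyctrap):
    fvs = find_greedy_fvs(cyctrap)
    inst = build_ip_mri_c(cyctrap, fvs)
    assert fvs.size == 1
    assert sorted(inst.time_indices) == [0, 1]  # |FVS|+1 time indices
    n_split_nodes = len(cyctrap.nodes) + len(inst.meta["split"])
    n_decisions = len(inst.meta["decision_units"])
    assert len(inst.variables) == n_split_nodes * (fvs.size + 1) + n_decisions
    assert len(inst.variables) < len(build_ip_mri_a(cyctrap).variables)


def test_c_rejects_non_fvs(cyctrap):
    with pytest.raises(ValueError, match="feedback vertex set"):
        build_ip_mri_c(cyctrap, FVSResult(()))


def test_a_solves_cyctrap(cyctrap):
    status, values, objective = solve_instance(build_ip_mri_a(cyctrap))
    assert status == "optimal" and objective == 3


def test_b_timeless_undercuts_on_the_cycle_trap(cyctrap):
    inst = build_ip_mri_b(cyctrap)
    assert inst.meta["sound_on_cycles"] is False
    status, values, objective = solve_instance(inst)
    assert status == "optimal" and objective == 2
    assert values["TERrb"] == 1 and values["TERrc"] == 1
    # the witness keeps the whole cycle lit without source support
    assert values["TCt(0)"] == 1 and values["TCc2(0)"] == 1


def test_b_equals_a_on_acyclic_instance(chain):
    _, _, obj_b = solve_instance(build_ip_mri_b(chain))
    _, _, obj_a = solve_instance(build_ip_mri_a(chain))
    assert obj_a == obj_b == 1


def test_trivial_when_target_in_host_scope():
    from boolgap import build_network
    net = build_network(["s", "t"], ["rh"], [("s", "rh"), ("rh", "t")],
                        ["s"], "t", ["s", "rh", "t"])
    for builder in (build_ip_mri_a, build_ip_mri_b):
        status, _, objective = solve_instance(builder(net))
        assert status == "optimal" and objective == 0


def test_forced_trajectory_equals_fixpoint(cyctrap):
    """With the insertions pinned, A's state is unique and is the lfp."""
    from boolgap import minimal_valid_assignment
    inst = build_ip_mri_a(cyctrap)
    for r in ("ra1", "ra2", "ra3"):
        inst.fix(f"TER{r}", 1)
    for r in ("rb", "rc"):
        inst.fix(f"TER{r}", 0)
    status, values, _ = solve_instance(inst)
    assert status == "optimal"
    horizon = inst.meta["horizon"]
    lfp = minimal_valid_assignment(cyctrap, {"ra1", "ra2", "ra3"})
    for node in cyctrap.nodes:
        prefix = "TC" if node in cyctrap.compound_ids else "TR"
        assert values[f"{prefix}{node}({horizon})"] == lfp[node], node


def test_border_fixture_split_and_solved(border_net):
    fvs = find_greedy_fvs(border_net)
    assert fvs.size == 0
    inst = build_ip_mri_c(border_net, fvs)
    assert any(v.startswith("TSRrb5") for v in inst.variables)
    status, _, objective = solve_instance(inst)
    assert status == "optimal" and objective == 1


def test_lp_export_round_trips_structure(cyctrap):
    text = to_lp(build_ip_mri_b(cyctrap))
    assert text.startswith("Minimize")
    assert "Binary" in text and text.rstrip().endswith("End")
    assert "(" not in text and "~" not in text  # LP-safe names
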