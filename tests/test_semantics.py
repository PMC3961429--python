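"""Least-fixpoint semantics against the exhaustive-enumeration oracle."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from boolgap import (additional_reactions, build_network, is_producible,
                     is_valid_assignment, minimal_valid_assignment,
                     source_connected_nodes)
from boolgap.semantics import Assignment, evaluation_domain
from conftest import oracle_minimal_assignments, tiny_net


def test_forced_propagation_chain():
    net = build_network(["s", "c"], ["r"], [("s", "r"), ("r", "c")],
                        ["s"], "c", ["s", "r", "c"])
    lfp = minimal_valid_assignment(net, ())
    assert lfp == {"s": 1, "r": 1, "c": 1}


def test_cycle_without_entry_stays_dark(cyctrap):
    lfp = minimal_valid_assignment(cyctrap, {"rb", "rc"})
    assert lfp["t"] == 0 and lfp["rb"] == 0 and lfp["rc"] == 0 and lfp["c2"] == 0
    assert not is_producible(cyctrap, {"rb", "rc"}, "t")


def test_insertable_path_lights_target(cyctrap):
    assert is_producible(cyctrap, {"ra1", "ra2", "ra3"}, "t")
    lfp = minimal_valid_assignment(cyctrap, {"ra1", "ra2", "ra3"})
    assert lfp.ones() >= {"s1", "rh", "c1", "ra1", "c4", "ra2", "c5", "ra3", "t"}


def test_source_always_producible(cyctrap):
    assert is_producible(cyctrap, (), "s1")
    with pytest.raises(KeyError):
        is_producible(cyctrap, (), "nope")


def test_validity_conditions(cyctrap):
    va = {"rb", "rc"}
    lfp = minimal_valid_assignment(cyctrap, va)
    assert is_valid_assignment(cyctrap, va, lfp)
    # the self-sustaining cycle is valid but not minimal
    pumped = Assignment(lfp)
    pumped.update({"t": 1, "rb": 1, "c2": 1, "rc": 1})
    assert is_valid_assignment(cyctrap, va, pumped)
    assert pumped != lfp
    # a dark source violates condition (i)
    dark = Assignment(lfp)
    dark["s1"] = 0
    assert not is_valid_assignment(cyctrap, va, dark)
    # domain mismatch is an error, not False
    with pytest.raises(ValueError, match="domain"):
        is_valid_assignment(cyctrap, va, Assignment({"s1": 1}))


def test_invalid_insertion_set_rejected(cyctrap):
    with pytest.raises(ValueError, match="non-insertable"):
        minimal_valid_assignment(cyctrap, {"rh"})


@pytest.mark.parametrize("seed", range(30))
def test_least_fixpoint_matches_enumeration_oracle(seed):
    """The fixpoint equals the unique inclusion-minimal valid assignment."""
    net = tiny_net(seed)
    rng = random.Random(seed + 99)
    extra = sorted(additional_reactions(net))
    choices = [frozenset()] + [frozenset(rng.sample(extra, rng.randint(1, len(extra))))
                               for _ in range(2) if extra]
    for va in choices:
        lfp = minimal_valid_assignment(net, va)
        valid, minimal = oracle_minimal_assignments(net, va)
        assert len(minimal) == 1  # uniqueness
        assert minimal[0] == lfp
        assert lfp in valid


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.integers(0, 10_000))
def test_monotone_in_insertion_set(seed):
    net = tiny_net(seed)
    rng = random.Random(seed)
    extra = sorted(additional_reactions(net))
    small = frozenset(r for r in extra if rng.random() < 0.5)
    big = small | frozenset(r for r in extra if rng.random() < 0.5)
    assert (minimal_valid_assignment(net, small).ones()
            <= minimal_valid_assignment(net, big).ones())


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.integers(0, 10_000))
def test_worklist_equals_synchronous(seed):
    net = tiny_net(seed)
    extra = sorted(additional_reactions(net))
    for va in (frozenset(), frozenset(extra)):
        assert (minimal_valid_assignment(net, va, order="worklist")
                == minimal_valid_assignment(net, va, order="synchronous"))


def test_source_connected_equals_ones_of_lfp(cyctrap):
    for va in (frozenset(), {"ra1", "ra2", "ra3"}, {"rb", "rc"}):
        lfp = minimal_valid_assignment(cyctrap, va)
        assert source_connected_nodes(cyctrap, lfp) == lfp.ones()


def test_source_connected_excludes_pumped_cycle(cyctrap):
    va = {"rb", "rc"}
    lfp = minimal_valid_assignment(cyctrap, va)
    pumped = Assignment(lfp)
    pumped.update({"t": 1, "rb": 1, "c2": 1, "rc": 1})
    conn = source_connected_nodes(cyctrap, pumped)
    assert {"t", "rb", "c2", "rc"}.isdisjoint(conn)
    # Theorem-2 mechanism: zeroing the unconnected part recovers the lfp
    rezeroed = Assignment({n: (v if n in conn else 0) for n, v in pumped.items()})
    assert rezeroed == lfp


def test_all_zero_except_sources_connects_only_sources(cyctrap):
    _, domain = evaluation_domain(cyctrap, ())
    a = Assignment({n: int(n in cyctrap.sources) for n in domain})
    assert source_connected_nodes(cyctrap, a) == cyctrap.sources


def test_convergence_within_node_count_sweeps():
    # a long chain is the worst case for synchronous sweeps
    n = 12
    comps = [f"c{i}" for i in range(n + 1)]
    reacts = [f"r{i}" for i in range(n)]
    edges = []
    for i in range(n):
        edges += [(f"c{i}", f"r{i}"), (f"r{i}", f"c{i+1}")]
    net = build_network(comps, reacts, edges, ["c0"], f"c{n}",
                        comps + reacts)
    lfp = minimal_valid_assignment(net, ())
    assert lfp[f"c{n}"] == 1
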