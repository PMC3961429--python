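"""Shared fixtures and independent oracles.

The oracles here re-derive expected answers from first principles
(exhaustive enumeration over assignments, subsets, or vertex covers) so
the package's algorithms are checked against something that shares no
code path with them.
"""

from __future__ import annotations

import itertools
import random

import networkx as nx
import pytest

from boolgap import build_network, fixture
from boolgap.semantics import Assignment, evaluation_domain


@pytest.fixture
def chain():
    return fixture("CHAIN")


@pytest.fixture
def cyctrap():
    return fixture("CYCTRAP")


@pytest.fixture
def border_net():
    return fixture("BORDER")


@pytest.fixture
def infeasible_net():
    return fixture("INFEASIBLE")


def tiny_net(seed: int, max_compounds: int = 5, max_reactions: int = 5):
    """Small random bipartite network (total nodes <= 10 by default)."""
    rng = random.Random(seed)
    nc = rng.randint(2, max_compounds)
    nr = rng.randint(1, max_reactions)
    compounds = [f"c{i}" for i in range(nc)]
    reactions = [f"r{i}" for i in range(nr)]
    edges = set()
    host = set()
    for r in reactions:
        subs = rng.sample(compounds, rng.randint(1, min(2, nc)))
        prods = rng.sample(compounds, rng.randint(1, min(2, nc)))
        edges |= {(c, r) for c in subs} | {(r, c) for c in prods}
        if rng.random() < 0.5:
            host |= {r, *subs, *prods}
    source, target = compounds[0], compounds[-1]
    host.add(source)
    host.discard(target)  # keep the target interesting when possible
    return build_network(compounds, reactions, sorted(edges), [source],
                         target, sorted(host), source_policy="strip")


# -- independent validity / minimality oracle -----------------------------

def oracle_is_valid(net, va, assignment) -> bool:
    """Validity re-checked straight from the definition."""
    active, domain = evaluation_domain(net, va)
    for s in net.sources:
        if assignment[s] != 1:
            return False
    for n in domain:
        if n in active:
            expect = int(all(assignment[c] for c in net.substrates(n)))
        elif n in net.sources:
            continue
        else:
            expect = int(any(assignment[r] for r in net.producers(n)
                             if r in active))
        if assignment[n] != expect:
            return False
    return True


def oracle_minimal_assignments(net, va):
    """All valid assignments and the inclusion-minimal ones, by brute force."""
    _, domain = evaluation_domain(net, va)
    nodes = sorted(domain)
    valid = []
    for bits in itertools.product((0, 1), repeat=len(nodes)):
        a = Assignment(zip(nodes, bits))
        if oracle_is_valid(net, va, a):
            valid.append(a)
    minimal = [a for a in valid
               if not any(b.ones() < a.ones() for b in valid)]
    return valid, minimal


def oracle_min_fvs(net, limit_k: int = 6):
    """Smallest reaction set whose removal leaves the digraph acyclic."""
    g = net.to_digraph()
    if nx.is_directed_acyclic_graph(g):
        return ()
    reactions = sorted(net.reaction_ids)
    for k in range(1, limit_k + 1):
        for combo in itertools.combinations(reactions, k):
            h = g.copy()
            h.remove_nodes_from(combo)
            if nx.is_directed_acyclic_graph(h):
                return combo
    raise AssertionError("no small FVS found; raise limit_k")
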