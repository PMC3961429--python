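"""Validity and least-fixpoint (minimal valid assignment) semantics.

An assignment maps every node of the evaluated subnetwork to 0/1.  It is
*valid* when (i) sources are 1, (ii) a non-source compound is 1 iff some
producing reaction among the active ones is 1, and (iii) an active
reaction (host or inserted) is 1 iff all of its substrates are 1.
Reactions outside host ∪ V_a are inactive and read as 0.

Cycles admit several valid assignments; the *minimal* one -- unique, by
the source-connectedness argument -- is the least fixpoint of the
monotone update operator started from the sources.  It is what decides
producibility.
"""

from __future__ import annotations

from typing import Iterable

from .network import MetabolicNetwork, additional_reactions

__all__ = [
    "Assignment",
    "evaluation_domain",
    "minimal_valid_assignment",
    "is_valid_assignment",
    "is_producible",
    "source_connected_nodes",
]


class Assignment(dict):
    """0/1 valuation of the evaluated subnetwork; absent nodes read as 0."""

    def __missing__(self, key):  # compounds outside the induced subgraph
        return 0

    def ones(self) -> frozenset:
        return frozenset(k for k, v in self.items() if v)


def _check_va(net: MetabolicNetwork, va: Iterable[str]) -> frozenset:
    va = frozenset(va)
    extra = additional_reactions(net)
    if not va <= extra:
        raise ValueError(f"insertion set contains non-insertable ids: {sorted(va - extra)}")
    return va


def evaluation_domain(net: MetabolicNetwork, va: Iterable[str]) -> tuple:
    """(active reactions, all nodes) of the subnetwork induced by host ∪ V_a.

    The compounds of the induced subnetwork are the sources, the host
    compounds, and every compound adjacent to an active reaction.
    """
    va = _check_va(net, va)
    active = net.host_reactions | va
    comps = set(net.sources) | set(net.host_compounds)
    for r in active:
        comps.update(net.substrates(r))
        comps.update(net.products(r))
    return frozenset(active), frozenset(comps) | frozenset(active)


def minimal_valid_assignment(net: MetabolicNetwork, va: Iterable[str] = (),
                             order: str = "synchronous") -> Assignment:
    """Least fixpoint: the unique minimal valid assignment for host ∪ V_a.

    ``order`` selects synchronous Kleene sweeps (canonical) or a chaotic
    worklist; the operator is monotone, so both give the same fixpoint.
    Convergence takes at most |nodes| sweeps.
    """
    active, domain = evaluation_domain(net, va)
    compounds = domain - active
    val = Assignment({n: 0 for n in domain})
    for s in net.sources:
        val[s] = 1

    def reaction_value(r):
        return int(all(val[c] for c in net.substrates(r)))

    def compound_value(c):
        if c in net.sources:
            return 1
        return int(any(val[r] for r in net.producers(c) if r in active))

    if order == "synchronous":
        for _ in range(len(domain) + 1):
            new = {r: reaction_value(r) for r in active}
            new.update((c, compound_value(c)) for c in compounds)
            if new == val:
                break
            val = Assignment(new)
        return val
    if order == "worklist":
        pending = sorted(domain)
        while pending:
            work, pending = pending, []
            changed = set()
            for n in work:
                v = reaction_value(n) if n in active else compound_value(n)
                if v != val[n]:
                    val[n] = v
                    changed.add(n)
            for n in changed:  # schedule successors of changed nodes
                pending.extend(m for m in (net.products(n) if n in active
                                           else net.consumers(n)) if m in domain)
            pending = sorted(set(pending))
        return val
    raise ValueError(f"unknown order {order!r}")


def is_valid_assignment(net: MetabolicNetwork, va: Iterable[str],
                        assignment: Assignment) -> bool:
    """Check conditions (i)-(iii) of validity; raises on a domain mismatch."""
    active, domain = evaluation_domain(net, va)
    if set(assignment) != set(domain):
        raise ValueError("assignment domain does not match the induced subnetwork")
    for s in net.sources:
        if not assignment[s]:
            return False
    for c in domain - active:
        if c in net.sources:
            continue
        produced = any(assignment[r] for r in net.producers(c) if r in active)
        if bool(assignment[c]) != produced:
            return False
    for r in active:
        fires = all(assignment[c] for c in net.substrates(r))
        if bool(assignment[r]) != fires:
            return False
    return True


def is_producible(net: MetabolicNetwork, va: Iterable[str], compound: str) -> bool:
    """Value of *compound* in the minimal valid assignment under V_a."""
    if compound not in net.compound_ids:
        raise KeyError(f"unknown compound {compound!r}")
    return bool(minimal_valid_assignment(net, va)[compound])


def source_connected_nodes(net: MetabolicNetwork, assignment: Assignment) -> frozenset:
    """Nodes reachable from a source along a directed all-ones path."""
    ones = assignment.ones()
    seen = set(net.sources & ones)
    stack = sorted(seen)
    while stack:
        n = stack.pop()
        succ = net.consumers(n) if n in net.compound_ids else net.products(n)
        for m in succ:
            if m in ones and m in assignment and m not in seen:
                seen.add(m)
                stack.append(m)
    return frozenset(seen)
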