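"""Feedback vertex set and node splitting for the time-folded encoding.

Every directed cycle of a bipartite compound/reaction graph alternates
between the two node kinds, so a reaction-only FVS always exists.  A
minimum FVS is not required -- the insertion optimum is independent of
the FVS choice -- so a deterministic greedy procedure is used: trim
nodes that cannot lie on a cycle (in- or out-degree 0), then repeatedly
delete the highest-degree remaining reaction node (ties to the
lexicographically smallest id) until the graph is cycle-free.

Splitting replaces a reaction r by r_in (keeping the in-edges) and
r_out (keeping the out-edges); splitting a set that contains an FVS
leaves an acyclic graph.  *Border* reactions -- insertable reactions
with at least one host substrate -- are split alongside the FVS when
encoding, so host-side and inserted-side values live on separate halves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

from .network import MetabolicNetwork, additional_reactions

__all__ = ["FVSResult", "SplitNetwork", "find_greedy_fvs", "border_reactions",
           "split_nodes", "merge_split"]

IN_SUFFIX = "_in"
OUT_SUFFIX = "_out"


@dataclass(frozen=True)
class FVSResult:
    """Ordered reaction-node feedback vertex set."""

    members: tuple

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class SplitNetwork:
    base: MetabolicNetwork
    split_pairs: dict  # reaction id -> (in-half id, out-half id)
    graph: nx.DiGraph = field(repr=False)


def _trim(g: nx.DiGraph) -> None:
    """Iteratively delete nodes of in-degree or out-degree 0 (off-cycle)."""
    queue = [n for n in g if g.in_degree(n) == 0 or g.out_degree(n) == 0]
    while queue:
        batch, queue = queue, []
        g.remove_nodes_from(batch)
        queue = [n for n in g if g.in_degree(n) == 0 or g.out_degree(n) == 0]


def find_greedy_fvs(net: MetabolicNetwork) -> FVSResult:
    g = net.to_digraph()
    members = []
    while True:
        _trim(g)
        if g.number_of_nodes() == 0:
            break
        # nonempty after trimming => every node is on a cycle or between
        # cycles; pick the busiest reaction node, smallest id on ties
        pick = min((r for r in g if r in net.reaction_ids),
                   key=lambda r: (-(g.in_degree(r) + g.out_degree(r)), r))
        members.append(pick)
        g.remove_node(pick)
    return FVSResult(tuple(members))


def border_reactions(net: MetabolicNetwork) -> frozenset:
    """Insertable reactions with at least one substrate in the host network."""
    host_comps = net.host_nodes & net.compound_ids
    return frozenset(r for r in additional_reactions(net)
                     if any(c in host_comps for c in net.substrates(r)))


def split_nodes(net: MetabolicNetwork, to_split: Iterable[str],
                require_acyclic: bool = False) -> SplitNetwork:
    to_split = frozenset(to_split)
    if not to_split <= net.reaction_ids:
        raise ValueError(f"cannot split non-reaction ids: {sorted(to_split - net.reaction_ids)}")
    g = net.to_digraph()
    pairs = {}
    for r in sorted(to_split):
        r_in, r_out = r + IN_SUFFIX, r + OUT_SUFFIX
        if r_in in g or r_out in g:
            raise ValueError(f"split ids for {r!r} collide with existing nodes")
        attrs = g.nodes[r]
        g.add_node(r_in, **attrs)
        g.add_node(r_out, **attrs)
        for c in net.substrates(r):
            g.add_edge(c, r_in)
        for c in net.products(r):
            g.add_edge(r_out, c)
        g.remove_node(r)
        pairs[r] = (r_in, r_out)
    if require_acyclic and not nx.is_directed_acyclic_graph(g):
        cyc = nx.find_cycle(g)
        raise ValueError(f"split graph still contains a cycle: {cyc}")
    return SplitNetwork(net, pairs, g)


def merge_split(split: SplitNetwork) -> nx.DiGraph:
    """Contract each in/out pair back; recovers the original digraph."""
    g = split.graph.copy()
    for r, (r_in, r_out) in split.split_pairs.items():
        g.add_node(r, **g.nodes[r_in])
        for c, _ in list(g.in_edges(r_in)):
            g.add_edge(c, r)
        for _, c in list(g.out_edges(r_out)):
            g.add_edge(r, c)
        g.remove_nodes_from([r_in, r_out])
    return g
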