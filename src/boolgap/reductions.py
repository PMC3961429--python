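"""Vertex-cover reduction: the NP-hardness machinery, made executable.

Minimum vertex cover (MVC) maps to minimum reaction insertion: each
graph vertex becomes an insertable reaction consuming one shared source
compound and producing a compound per incident edge; a single host
reaction consumes every edge compound and produces the target.  Picking
k vertex reactions makes the target producible iff the k vertices cover
every edge, so the two optima coincide.  A degree-bounding gadget then
rewrites any node of in- or out-degree above 2 into a binary tree of
pass-through host nodes, preserving the optimum.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from .network import MetabolicNetwork, build_network

__all__ = ["MVCGraph", "mvc_to_mri", "bound_degrees", "brute_force_mvc",
           "read_edge_list"]


@dataclass(frozen=True)
class MVCGraph:
    """Simple undirected graph for vertex-cover instances."""

    vertices: frozenset
    edges: frozenset  # of frozenset pairs

    def __post_init__(self):
        for e in self.edges:
            if len(e) != 2:
                raise ValueError(f"self-loop or malformed edge {sorted(e)}")
            if not e <= self.vertices:
                raise ValueError(f"edge {sorted(e)} leaves the vertex set")


def read_edge_list(text: str) -> MVCGraph:
    """One "u v" pair per line; '#' starts a comment."""
    vertices, edges = set(), set()
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        u, v = line.split()
        vertices |= {u, v}
        edges.add(frozenset((u, v)))
    return MVCGraph(frozenset(vertices), frozenset(edges))


def _edge_id(e: frozenset) -> str:
    return "c_" + "_".join(sorted(e))


def mvc_to_mri(g: MVCGraph) -> MetabolicNetwork:
    """MRI instance whose insertion optimum equals the MVC optimum of *g*.

    Host: the source, every edge compound, the collector reaction and the
    target.  Insertable: one reaction per vertex.
    """
    if not g.edges:
        raise ValueError("the reduction needs at least one edge")
    source, target, collector = "src", "tgt", "r_t"
    compounds = [source, target] + [_edge_id(e) for e in sorted(g.edges, key=sorted)]
    reactions = ["r_" + v for v in sorted(g.vertices)] + [collector]
    edges = []
    for v in sorted(g.vertices):
        rv = "r_" + v
        edges.append((source, rv))
        for e in sorted(g.edges, key=sorted):
            if v in e:
                edges.append((rv, _edge_id(e)))
    for e in sorted(g.edges, key=sorted):
        edges.append((_edge_id(e), collector))
    edges.append((collector, target))
    host = [source, target, collector] + [_edge_id(e) for e in g.edges]
    return build_network(compounds, reactions, edges, [source], target, host)


def bound_degrees(net: MetabolicNetwork) -> MetabolicNetwork:
    """Rewrite so every node has indegree <= 2 and outdegree <= 2.

    Two excess predecessors (or successors) at a time are merged behind
    a pass-through compound/reaction pair -- a single-input AND or OR is
    a copy, so the Boolean value of every original node is unchanged.
    Intermediates are host nodes, so insertion decisions stay on the
    original insertable reactions and the MRI optimum is preserved.
    """
    compounds = set(net.compound_ids)
    reactions = set(net.reaction_ids)
    edges = set(net.edges)
    host = set(net.host_nodes)
    counter = itertools.count()

    def preds(n):
        return sorted(u for (u, v) in edges if v == n)

    def succs(n):
        return sorted(v for (u, v) in edges if u == n)

    def new_pair(kind_first):
        """Fresh (compound, reaction) or (reaction, compound) pass pair."""
        k = next(counter)
        c, r = f"g{k}__c", f"g{k}__r"
        compounds.add(c)
        reactions.add(r)
        host.update((c, r))
        return (c, r) if kind_first == "compound" else (r, c)

    queue = sorted(net.nodes)
    while queue:
        node = queue.pop()
        p = preds(node)
        while len(p) > 2:
            a, b = p[0], p[1]
            edges -= {(a, node), (b, node)}
            if node in compounds:
                buf, passer = new_pair("compound")  # a,b -> buf -> passer -> node
                edges |= {(a, buf), (b, buf), (buf, passer), (passer, node)}
            else:
                passer, buf = new_pair("reaction")  # a,b -> passer -> buf -> node
                edges |= {(a, passer), (b, passer), (passer, buf), (buf, node)}
            p = preds(node)
        s = succs(node)
        while len(s) > 2:
            a, b = s[0], s[1]
            edges -= {(node, a), (node, b)}
            if node in compounds:
                passer, buf = new_pair("reaction")  # node -> passer -> buf -> a,b
                edges |= {(node, passer), (passer, buf), (buf, a), (buf, b)}
            else:
                buf, passer = new_pair("compound")  # node -> buf -> passer -> a,b
                edges |= {(node, buf), (buf, passer), (passer, a), (passer, b)}
            s = succs(node)

    pairs = [pr for pr in net.reversible_pairs
             if all(set(preds(x)) == set(net.substrates(x))
                    and set(succs(x)) == set(net.products(x)) for x in pr)]
    return build_network(sorted(compounds), sorted(reactions), sorted(edges),
                         sorted(net.sources), net.target, sorted(host), pairs)


def brute_force_mvc(g: MVCGraph) -> int:
    """Exact minimum vertex-cover size by subset enumeration (<=16 vertices)."""
    if len(g.vertices) > 16:
        raise ValueError("exhaustive MVC limited to 16 vertices")
    verts = sorted(g.vertices)
    for k in range(len(verts) + 1):
        for combo in itertools.combinations(verts, k):
            chosen = set(combo)
            if all(e & chosen for e in g.edges):
                return k
    return len(verts)
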