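"""Bipartite compound/reaction network model.

A metabolic network is a directed bipartite graph: compound nodes (OR
semantics: producible if any producing reaction is active) and reaction
nodes (AND semantics: active if every substrate is producible).  A *host*
network -- the organism's existing metabolism -- is an induced subgraph of
the *reference* network; reactions outside the host are candidates for
insertion.  Source compounds are seeds supplied by the environment and
have no incoming edges; one compound is the production target.

Reversible reactions are represented by two opposed irreversible halves
(P = forward, Q = backward) linked through ``reversible_pairs``.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from functools import cached_property
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkError",
    "MetabolicNetwork",
    "build_network",
    "decompose_reversible",
    "additional_reactions",
    "decision_units",
    "network_from_dict",
    "network_to_dict",
    "load_network",
    "save_network",
]


class NetworkError(ValueError):
    """Structural violation of the bipartite network invariants."""


@dataclass(frozen=True)
class MetabolicNetwork:
    """Validated bipartite host/reference network.

    Construct through :func:`build_network`, which checks all invariants;
    direct instantiation skips validation.
    """

    compound_ids: frozenset
    reaction_ids: frozenset
    edges: frozenset  # of (u, v) pairs, always compound<->reaction
    sources: frozenset
    target: str
    host_nodes: frozenset
    reversible_pairs: frozenset = field(default_factory=frozenset)

    # -- adjacency helpers ------------------------------------------------

    @cached_property
    def _in(self) -> dict:
        inc: dict = {n: [] for n in self.compound_ids | self.reaction_ids}
        for u, v in sorted(self.edges):
            inc[v].append(u)
        return {k: tuple(v) for k, v in inc.items()}

    @cached_property
    def _out(self) -> dict:
        out: dict = {n: [] for n in self.compound_ids | self.reaction_ids}
        for u, v in sorted(self.edges):
            out[u].append(v)
        return {k: tuple(v) for k, v in out.items()}

    def substrates(self, reaction: str) -> tuple:
        return self._in[reaction]

    def products(self, reaction: str) -> tuple:
        return self._out[reaction]

    def producers(self, compound: str) -> tuple:
        """Reactions with an edge into *compound*."""
        return self._in[compound]

    def consumers(self, compound: str) -> tuple:
        return self._out[compound]

    @property
    def nodes(self) -> frozenset:
        return self.compound_ids | self.reaction_ids

    @cached_property
    def host_reactions(self) -> frozenset:
        return self.reaction_ids & self.host_nodes

    @cached_property
    def host_compounds(self) -> frozenset:
        return self.compound_ids & self.host_nodes

    def is_compound(self, node: str) -> bool:
        return node in self.compound_ids

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for c in self.compound_ids:
            g.add_node(c, kind="compound", host=c in self.host_nodes)
        for r in self.reaction_ids:
            g.add_node(r, kind="reaction", host=r in self.host_nodes)
        g.add_edges_from(self.edges)
        return g

    def host_subnetwork(self) -> "MetabolicNetwork":
        """Induced subgraph on the host nodes (sources/target retained)."""
        comps = self.compound_ids & (self.host_nodes | self.sources | {self.target})
        reacts = self.reaction_ids & self.host_nodes
        keep = comps | reacts
        edges = frozenset((u, v) for u, v in self.edges if u in keep and v in keep)
        pairs = frozenset(p for p in self.reversible_pairs if p <= reacts)
        return replace(self, compound_ids=frozenset(comps),
                       reaction_ids=frozenset(reacts), edges=edges,
                       host_nodes=self.host_nodes & (comps | reacts),
                       reversible_pairs=pairs)


def build_network(compounds: Iterable[str], reactions: Iterable[str],
                  edges: Iterable[tuple], sources: Iterable[str], target: str,
                  host_nodes: Iterable[str],
                  reversible_pairs: Iterable[frozenset] = (),
                  source_policy: str = "strip") -> MetabolicNetwork:
    """Validate and construct a :class:`MetabolicNetwork`.

    ``source_policy`` controls seeds that (against the model's assumption)
    have incoming edges: ``"strip"`` removes those edges with a warning,
    ``"strict"`` raises.
    """
    compounds = list(compounds)
    reactions = list(reactions)
    if len(set(compounds)) != len(compounds):
        raise NetworkError("duplicate compound ids")
    if len(set(reactions)) != len(reactions):
        raise NetworkError("duplicate reaction ids")
    cset, rset = frozenset(compounds), frozenset(reactions)
    if cset & rset:
        raise NetworkError(f"ids used as both compound and reaction: {sorted(cset & rset)}")
    nodes = cset | rset

    edge_set = set()
    for u, v in edges:
        if u not in nodes or v not in nodes:
            raise NetworkError(f"edge ({u}, {v}) references undeclared node")
        if (u in cset) == (v in cset):
            raise NetworkError(
                f"edge ({u}, {v}) violates bipartiteness: both endpoints are "
                + ("compounds" if u in cset else "reactions"))
        edge_set.add((u, v))

    src = frozenset(sources)
    if not src <= cset:
        raise NetworkError(f"sources not declared as compounds: {sorted(src - cset)}")
    if target not in cset:
        raise NetworkError(f"target {target!r} is not a declared compound")
    if target in src:
        raise NetworkError(f"target {target!r} is listed as a source")

    offending = [(u, v) for (u, v) in edge_set if v in src]
    if offending:
        if source_policy == "strict":
            raise NetworkError(f"source nodes with incoming edges: {sorted(offending)}")
        if source_policy != "strip":
            raise ValueError(f"unknown source_policy {source_policy!r}")
        for e in offending:
            edge_set.discard(e)
        logger.warning("stripped %d edge(s) into source compounds: %s",
                       len(offending), sorted(offending))

    host = frozenset(host_nodes)
    if not host <= nodes:
        raise NetworkError(f"host nodes not declared: {sorted(host - nodes)}")

    net = MetabolicNetwork(cset, rset, frozenset(edge_set), src, target, host,
                           frozenset(frozenset(p) for p in reversible_pairs))
    # only product->source edges are ever stripped, so a half may lack a
    # product that appears among the other half's substrates iff it is a
    # source compound
    def mirrored(s, p):
        return p <= s and (s - p) <= src

    for pair in net.reversible_pairs:
        a, b = sorted(pair)
        if len(pair) != 2 or not {a, b} <= rset:
            raise NetworkError(f"reversible pair {sorted(pair)} must name two reactions")
        if not (mirrored(set(net.substrates(a)), set(net.products(b)))
                and mirrored(set(net.substrates(b)), set(net.products(a)))):
            raise NetworkError(
                f"reversible pair ({a}, {b}) halves are not mirror images")
    return net


def additional_reactions(net: MetabolicNetwork) -> frozenset:
    """Reaction nodes of the reference network absent from the host."""
    return net.reaction_ids - net.host_nodes


_KEGG_R = re.compile(r"^R(\d{5})$")


def _half_ids(rid: str) -> tuple:
    m = _KEGG_R.match(rid)
    if m:  # KEGG convention: R00001 -> P00001 / Q00001
        return "P" + m.group(1), "Q" + m.group(1)
    return "P_" + rid, "Q_" + rid


def decompose_reversible(spec: Mapping, source_policy: str = "strip") -> MetabolicNetwork:
    """Build a network from a reaction-level description with reversibility flags.

    ``spec`` follows the JSON network schema: keys ``compounds``,
    ``reactions`` (each ``{"id", "substrates", "products", "reversible",
    "host"}``), ``sources``, ``target`` and optionally ``host_compounds``.
    Each reversible reaction becomes a forward (P) and backward (Q) half
    with swapped substrates/products, recorded in ``reversible_pairs``.
    Irreversible reactions pass through unchanged, so the operation is
    idempotent on already-decomposed descriptions.
    """
    compounds = list(spec["compounds"])
    # explicit host_compounds pin the host compound set; otherwise a host
    # reaction's substrates and products are taken to be host compounds
    explicit_host = "host_compounds" in spec
    reactions, edges, pairs, host = [], [], [], set(spec.get("host_compounds", ()))

    def add(rid, subs, prods, is_host):
        if rid in seen:
            raise NetworkError(f"duplicate derived reaction id {rid!r}")
        seen.add(rid)
        reactions.append(rid)
        edges.extend((c, rid) for c in subs)
        edges.extend((rid, c) for c in prods)
        if is_host:
            host.add(rid)
            if not explicit_host:
                host.update(subs)
                host.update(prods)

    seen: set = set()
    for rx in spec["reactions"]:
        rid, subs, prods = rx["id"], list(rx["substrates"]), list(rx["products"])
        is_host = bool(rx.get("host", False))
        if rx.get("reversible", False):
            fwd, bwd = _half_ids(rid)
            add(fwd, subs, prods, is_host)
            add(bwd, prods, subs, is_host)
            pairs.append(frozenset((fwd, bwd)))
        else:
            add(rid, subs, prods, is_host)

    for pair in spec.get("reversible_pairs", ()):
        pairs.append(frozenset(pair))
    return build_network(compounds, reactions, edges, spec["sources"],
                         spec["target"], host, pairs, source_policy=source_policy)


def decision_units(net: MetabolicNetwork, reversible_cost: str = "pair") -> tuple:
    """Insertion decision units, sorted: frozensets of additional reaction ids.

    Under ``"pair"`` costing one unit covers both halves of a reversible
    pair whose halves are both insertable; ``"direction"`` charges each
    half separately.
    """
    if reversible_cost not in ("pair", "direction"):
        raise ValueError(f"unknown reversible_cost {reversible_cost!r}")
    extra = additional_reactions(net)
    units = []
    if reversible_cost == "pair":
        paired: set = set()
        for pair in net.reversible_pairs:
            if pair <= extra:
                units.append(pair)
                paired |= pair
        units.extend(frozenset((r,)) for r in extra - paired)
    else:
        units.extend(frozenset((r,)) for r in extra)
    return tuple(sorted(units, key=lambda u: sorted(u)))


# -- serialization ---------------------------------------------------------

def network_to_dict(net: MetabolicNetwork) -> dict:
    """Deterministic (sorted) JSON-ready description of a network."""
    reactions = []
    for rid in sorted(net.reaction_ids):
        reactions.append({
            "id": rid,
            "substrates": sorted(net.substrates(rid)),
            "products": sorted(net.products(rid)),
            "reversible": False,  # pairs carry reversibility post-decomposition
            "host": rid in net.host_nodes,
        })
    return {
        "compounds": sorted(net.compound_ids),
        "reactions": reactions,
        "sources": sorted(net.sources),
        "target": net.target,
        "host_compounds": sorted(net.host_nodes & net.compound_ids),
        "reversible_pairs": sorted(sorted(p) for p in net.reversible_pairs),
    }


def network_from_dict(data: Mapping, source_policy: str = "strip") -> MetabolicNetwork:
    return decompose_reversible(data, source_policy=source_policy)


def save_network(net: MetabolicNetwork, path) -> None:
    with open(path, "w") as fh:
        json.dump(network_to_dict(net), fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_network(path, source_policy: str = "strip") -> MetabolicNetwork:
    with open(path) as fh:
        return network_from_dict(json.load(fh), source_policy=source_policy)
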