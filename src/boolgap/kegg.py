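"""KGML (KEGG Markup Language) parsing and host/reference assembly.

A pathway map contributes compound entries and reaction elements; the
bipartite network is built from the ``<reaction>`` elements (substrate
and product children), not from the enzyme relation graph.  Several
maps are merged by R/C identifier into one reference network; the maps
of the host organism mark the host nodes.  Reversible reactions are
decomposed into P/Q halves at merge time.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from lxml import etree

from .network import MetabolicNetwork, NetworkError, decompose_reversible

logger = logging.getLogger(__name__)

__all__ = ["PathwayFragment", "parse_kgml", "merge_maps"]

_C_ID = re.compile(r"^C\d{5}$")
_R_ID = re.compile(r"^R\d{5}$")


@dataclass(frozen=True)
class PathwayFragment:
    """Reactions and compounds contributed by one pathway map."""

    map_id: str
    compounds: frozenset
    # (R-number, substrates tuple, products tuple, reversible flag)
    reactions: tuple


def _strip_prefix(name: str) -> str:
    return name.split(":", 1)[-1]


def parse_kgml(path) -> PathwayFragment:
    """Extract the reaction graph of one KGML file."""
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise NetworkError(f"malformed KGML {path}: {exc}") from exc
    root = tree.getroot()
    map_id = root.get("name", str(path))

    compounds: set = set()
    for entry in root.iter("entry"):
        if entry.get("type") == "compound":
            for token in entry.get("name", "").split():
                cid = _strip_prefix(token)
                if _C_ID.match(cid):
                    compounds.add(cid)

    reactions = {}
    for rx in root.iter("reaction"):
        reversible = rx.get("type") == "reversible"
        subs = tuple(sorted({_strip_prefix(s.get("name", ""))
                             for s in rx.iter("substrate")}))
        prods = tuple(sorted({_strip_prefix(p.get("name", ""))
                              for p in rx.iter("product")}))
        for token in rx.get("name", "").split():
            rid = _strip_prefix(token)
            if not _R_ID.match(rid):
                continue
            if not subs or not prods:
                raise NetworkError(f"reaction {rid} in {path} lacks substrates "
                                   "or products")
            for cid in subs + prods:
                if not _C_ID.match(cid):
                    raise NetworkError(f"reaction {rid} references malformed "
                                       f"compound id {cid!r}")
            if rid in reactions:  # duplicate within the map: union directions
                old_subs, old_prods, old_rev = reactions[rid]
                rev = old_rev or reversible or (
                    set(subs) == set(old_prods) and set(prods) == set(old_subs))
                reactions[rid] = (old_subs, old_prods, rev)
            else:
                reactions[rid] = (subs, prods, reversible)
            compounds.update(subs)
            compounds.update(prods)

    if not reactions:
        logger.warning("KGML map %s contains no reaction elements", map_id)
    return PathwayFragment(map_id, frozenset(compounds),
                           tuple((rid, *info) for rid, info
                                 in sorted(reactions.items())))


def _union(fragments: Iterable[PathwayFragment]) -> tuple:
    """Merge fragments by id; opposite directions of one R-number union
    into a reversible reaction."""
    compounds: set = set()
    reactions: dict = {}
    provenance: dict = {}
    for frag in fragments:
        compounds |= frag.compounds
        for rid, subs, prods, rev in frag.reactions:
            provenance.setdefault(rid, []).append(frag.map_id)
            if rid not in reactions:
                reactions[rid] = [set(subs), set(prods), rev]
                continue
            cur = reactions[rid]
            if set(subs) == cur[1] and set(prods) == cur[0]:
                cur[2] = True  # same reaction annotated in the other direction
            else:
                cur[0] |= set(subs)
                cur[1] |= set(prods)
                cur[2] = cur[2] or rev
    return compounds, reactions, provenance


def merge_maps(reference: Sequence[PathwayFragment],
               host: Sequence[PathwayFragment],
               sources: Iterable[str], target: str,
               source_policy: str = "strip") -> MetabolicNetwork:
    """Assemble host and reference fragments into one network.

    Host fragments must be a subset selection of the reference (their
    reactions are added to the reference union if missing); a reaction
    present in any host fragment is a host reaction.
    """
    ref_comps, ref_reactions, provenance = _union(list(reference) + list(host))
    host_comps, host_reactions, _ = _union(host)

    sources = sorted(set(sources))
    missing = [s for s in sources if s not in ref_comps]
    if missing:
        raise NetworkError(f"sources absent from the merged maps: {missing}")
    if target not in ref_comps:
        raise NetworkError(f"target {target!r} absent from the merged maps")

    spec = {
        "compounds": sorted(ref_comps),
        "reactions": [
            {"id": rid, "substrates": sorted(subs), "products": sorted(prods),
             "reversible": rev, "host": rid in host_reactions}
            for rid, (subs, prods, rev) in sorted(ref_reactions.items())
        ],
        "sources": sources,
        "target": target,
        "host_compounds": sorted(host_comps),
    }
    net = decompose_reversible(spec, source_policy=source_policy)
    # frozen dataclass: provenance rides alongside via the instance dict
    net.__dict__["provenance"] = {k: tuple(v) for k, v in sorted(provenance.items())}
    return net
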