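"""Deterministic fixtures and a seeded random-instance generator.

The fixtures are the small hand-built networks the method's behaviour
pivots on, in particular CYCTRAP: a three-reaction insertable path to
the target next to a two-reaction insertable cycle through it.  The
cycle *looks* like the cheaper insertion but cannot start without an
external entry, which is exactly what the minimal-valid-assignment
semantics (and the time-aware encodings) must detect, and what the
timeless encoding gets wrong.

The random generator emulates the same anatomy at configurable size: a
host backbone fed by one source, insertable reactions wiring random
compound pairs, optional injected two-reaction cycles, and (optionally)
a guaranteed insertable path to the target so the instance is solvable.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .network import MetabolicNetwork, build_network

__all__ = ["GeneratorConfig", "fixture", "random_network", "FIXTURES"]


def _cyctrap() -> MetabolicNetwork:
    return build_network(
        compounds=["s1", "c1", "c2", "c4", "c5", "t"],
        reactions=["rh", "ra1", "ra2", "ra3", "rb", "rc"],
        edges=[("s1", "rh"), ("rh", "c1"),
               ("c1", "ra1"), ("ra1", "c4"),
               ("c4", "ra2"), ("ra2", "c5"),
               ("c5", "ra3"), ("ra3", "t"),
               ("t", "rb"), ("rb", "c2"),
               ("c2", "rc"), ("rc", "t")],
        sources=["s1"], target="t",
        host_nodes=["s1", "c1", "rh"])


def _chain() -> MetabolicNetwork:
    return build_network(
        compounds=["s", "c1", "t"],
        reactions=["rh1", "rx"],
        edges=[("s", "rh1"), ("rh1", "c1"), ("c1", "rx"), ("rx", "t")],
        sources=["s"], target="t",
        host_nodes=["s", "c1", "rh1"])


def _border() -> MetabolicNetwork:
    # insertable reaction whose substrate sits in the host (Fig-4 shape)
    return build_network(
        compounds=["s", "ch", "t"],
        reactions=["rh", "rb5"],
        edges=[("s", "rh"), ("rh", "ch"), ("ch", "rb5"), ("rb5", "t")],
        sources=["s"], target="t",
        host_nodes=["s", "ch", "rh", "t"])


def _infeasible() -> MetabolicNetwork:
    return build_network(
        compounds=["s", "c1", "t"],
        reactions=["rh"],
        edges=[("s", "rh"), ("rh", "c1")],
        sources=["s"], target="t",
        host_nodes=["s", "c1", "rh"])


FIXTURES = {
    "CHAIN": _chain,
    "CYCTRAP": _cyctrap,
    "BORDER": _border,
    "INFEASIBLE": _infeasible,
}


def fixture(name: str) -> MetabolicNetwork:
    """Named deterministic instance; see ``FIXTURES`` for the catalog."""
    try:
        return FIXTURES[name]()
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; available: "
                       f"{sorted(FIXTURES)}") from None


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the random bipartite instance generator.

    Defaults give a small, cyclic, solvable instance whose candidate set
    stays within the exhaustive-search bound, so IP answers can always
    be cross-checked against the oracle.
    """

    n_compounds: int = 10
    n_reactions: int = 10
    host_fraction: float = 0.4
    cycle_count: int = 1
    seed: int = 0
    ensure_feasible: bool = True

    def __post_init__(self):
        if self.n_compounds < 3 or self.n_reactions < 1:
            raise ValueError("need at least 3 compounds and 1 reaction")
        if not 0.0 <= self.host_fraction <= 1.0:
            raise ValueError("host_fraction must lie in [0, 1]")
        if self.cycle_count < 0:
            raise ValueError("cycle_count must be non-negative")
        if self.cycle_count and self.n_compounds < 4:
            raise ValueError("cycles need at least 4 compounds")


def random_network(cfg: GeneratorConfig) -> MetabolicNetwork:
    """Seeded random instance; identical config gives an identical network."""
    rng = random.Random(cfg.seed)
    source = "c000"
    target = f"c{cfg.n_compounds - 1:03d}"
    compounds = [f"c{i:03d}" for i in range(cfg.n_compounds)]
    inner = [c for c in compounds if c not in (source, target)]

    reactions, edges = [], []
    n_host = max(1, round(cfg.host_fraction * cfg.n_reactions))
    host_nodes = {source}

    # host backbone: a chain from the source through random inner compounds
    chain_len = min(n_host, len(inner))
    chain = rng.sample(inner, chain_len)
    prev = source
    for i, c in enumerate(chain):
        rid = f"rh{i:03d}"
        reactions.append(rid)
        edges += [(prev, rid), (rid, c)]
        host_nodes.update((prev, rid, c))
        prev = c
    for i in range(chain_len, n_host):  # extra host reactions off the chain
        rid = f"rh{i:03d}"
        sub = rng.choice(chain or [source])
        prod = rng.choice(inner)
        reactions.append(rid)
        edges += [(sub, rid), (rid, prod)]
        host_nodes.update((sub, rid, prod))

    # insertable reactions wiring random compounds (never into the source)
    n_extra = cfg.n_reactions - n_host
    for i in range(n_extra):
        rid = f"rx{i:03d}"
        subs = rng.sample(compounds, rng.choice((1, 1, 2)))
        prods = rng.sample([c for c in compounds if c != source and c not in subs],
                           rng.choice((1, 1, 2)))
        reactions.append(rid)
        edges += [(c, rid) for c in subs]
        edges += [(rid, c) for c in prods]

    # injected two-reaction cycles off the backbone (insertable)
    for k in range(cfg.cycle_count):
        a, b = rng.sample(inner, 2)
        r1, r2 = f"rcy{k:03d}a", f"rcy{k:03d}b"
        reactions += [r1, r2]
        edges += [(a, r1), (r1, b), (b, r2), (r2, a)]

    if cfg.ensure_feasible:
        # a guaranteed insertable route host-compound -> ... -> target
        start = rng.choice(sorted(host_nodes & set(compounds)))
        hops = rng.choice((1, 2, 3))
        prev = start
        for j in range(hops):
            rid = f"rfs{j:03d}"
            nxt = target if j == hops - 1 else rng.choice(inner)
            reactions.append(rid)
            edges += [(prev, rid), (rid, nxt)]
            prev = nxt

    return build_network(compounds, reactions, sorted(set(edges)),
                         [source], target, sorted(host_nodes))
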