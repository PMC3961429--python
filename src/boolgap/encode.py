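"""Binary integer-program encodings of minimum reaction insertion.

Three encodings of the same optimisation -- minimise the number of
inserted reactions subject to the target being 1 in the minimal valid
assignment -- trade variables for soundness:

``A``  time-expanded: one copy of every node per time step, exact
       synchronous-update constraints between consecutive steps, all
       non-sources 0 at t=0.  Sound and complete; O(n^2) variables.

``B``  timeless: one variable per node with exact AND/OR equalities.
       Sound only on acyclic networks: a cycle may hold itself at 1
       without source support, undercounting the insertions needed.

``C``  FVS-folded: split the feedback vertex set (plus border
       reactions), encode the acyclic remainder timelessly within each
       of |FVS|+1 steps, and copy each FVS in-half to its out-half on
       the step transition, with the out-halves 0 at t=0 and in = out
       at the last step.  Sound, complete, and O(n·|FVS|) variables.

Boolean gates use the standard exact linearisations, so for a fixed
choice of the insertion variables the state trajectory of A and C is
forced, and equals the least fixpoint.  The insertion decision for an
additional reaction is a time-invariant binary variable TER joined to
the reaction's AND like a virtual substrate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx

from .fvs import FVSResult, border_reactions, split_nodes
from .network import MetabolicNetwork, decision_units

__all__ = ["IPInstance", "linearize_and", "linearize_or",
           "build_ip_mri_a", "build_ip_mri_b", "build_ip_mri_c", "to_lp"]

# constraint: (coefficients, relation, right-hand side)
Constraint = tuple


@dataclass
class IPInstance:
    """Solver-agnostic binary MILP (all variables in {0,1})."""

    variables: list
    constraints: list
    objective: dict  # variable -> coefficient, minimised
    meta: dict = field(default_factory=dict)

    def add_var(self, name: str) -> str:
        self.variables.append(name)
        return name

    def add(self, coeffs: dict, rel: str, rhs: float) -> None:
        assert rel in ("<=", ">=", "=")
        self.constraints.append((coeffs, rel, rhs))

    def fix(self, name: str, value: int) -> None:
        self.add({name: 1}, "=", value)

    @property
    def time_indices(self) -> frozenset:
        """Distinct time-step indices occurring in variable names."""
        hits = (re.search(r"\((\d+)\)$", v) for v in self.variables)
        return frozenset(int(m.group(1)) for m in hits if m)


def linearize_and(output_var: str, input_vars: Sequence[str]) -> list:
    """Exact constraints pinning output = AND(inputs) over binaries."""
    if not input_vars:
        raise ValueError("AND of an empty input list")
    cons = [({output_var: 1, x: -1}, "<=", 0) for x in input_vars]
    lhs = {output_var: 1}
    for x in input_vars:
        lhs[x] = lhs.get(x, 0) - 1
    cons.append((lhs, ">=", -(len(input_vars) - 1)))
    return cons


def linearize_or(output_var: str, input_vars: Sequence[str]) -> list:
    """Exact constraints pinning output = OR(inputs) over binaries."""
    if not input_vars:
        raise ValueError("OR of an empty input list")
    cons = [({output_var: 1, x: -1}, ">=", 0) for x in input_vars]
    lhs = {output_var: 1}
    for x in input_vars:
        lhs[x] = lhs.get(x, 0) - 1
    cons.append((lhs, "<=", 0))
    return cons


def _tc(c: str, t: int) -> str:
    return f"TC{c}({t})"


def _tr(r: str, t: int) -> str:
    return f"TR{r}({t})"


def _ter(unit: frozenset) -> str:
    return "TER" + "~".join(sorted(unit))


def _tsr(r: str, half: str, t: int) -> str:
    return f"TSR{r}{half}({t})"


def _decision_vars(inst: IPInstance, net: MetabolicNetwork,
                   reversible_cost: str) -> dict:
    """Create one TER variable per decision unit; map reaction -> its TER."""
    gate = {}
    units = decision_units(net, reversible_cost)
    for unit in units:
        v = inst.add_var(_ter(unit))
        inst.objective[v] = 1
        for r in unit:
            gate[r] = v
    inst.meta["decision_units"] = units
    return gate


def build_ip_mri_a(net: MetabolicNetwork, reversible_cost: str = "pair") -> IPInstance:
    """Time-expanded encoding over t = 0..|nodes|."""
    horizon = len(net.compound_ids) + len(net.reaction_ids)
    inst = IPInstance([], [], {}, {"encoding": "A", "horizon": horizon})
    gate = _decision_vars(inst, net, reversible_cost)

    for t in range(horizon + 1):
        for c in sorted(net.compound_ids):
            inst.add_var(_tc(c, t))
        for r in sorted(net.reaction_ids):
            inst.add_var(_tr(r, t))

    for s in sorted(net.sources):  # seeds held at 1 throughout
        for t in range(horizon + 1):
            inst.fix(_tc(s, t), 1)
    for c in sorted(net.compound_ids - net.sources):
        inst.fix(_tc(c, 0), 0)
    for r in sorted(net.reaction_ids):
        inst.fix(_tr(r, 0), 0)

    for t in range(horizon):
        for r in sorted(net.reaction_ids):
            inputs = [_tc(c, t) for c in sorted(net.substrates(r))]
            if r in gate:
                inputs.append(gate[r])
            if inputs:
                inst.constraints += linearize_and(_tr(r, t + 1), inputs)
            else:  # substrate-free host reaction fires unconditionally
                inst.fix(_tr(r, t + 1), 1)
        for c in sorted(net.compound_ids - net.sources):
            producers = [_tr(r, t) for r in sorted(net.producers(c))]
            if producers:
                inst.constraints += linearize_or(_tc(c, t + 1), producers)
            else:
                inst.fix(_tc(c, t + 1), 0)

    inst.fix(_tc(net.target, horizon), 1)
    inst.meta["n_state_vars"] = (len(net.nodes)) * (horizon + 1)
    return inst


def build_ip_mri_b(net: MetabolicNetwork, reversible_cost: str = "pair") -> IPInstance:
    """Timeless encoding: exact but unsound on cyclic networks.

    A directed cycle can satisfy the equalities with all its nodes at 1
    without being source-connected, so the optimum can undercut the true
    one; ``meta["sound_on_cycles"]`` is False to flag this.
    """
    inst = IPInstance([], [], {}, {"encoding": "B", "sound_on_cycles": False})
    gate = _decision_vars(inst, net, reversible_cost)
    for c in sorted(net.compound_ids):
        inst.add_var(_tc(c, 0))
    for r in sorted(net.reaction_ids):
        inst.add_var(_tr(r, 0))

    for s in sorted(net.sources):
        inst.fix(_tc(s, 0), 1)
    for r in sorted(net.reaction_ids):
        inputs = [_tc(c, 0) for c in sorted(net.substrates(r))]
        if r in gate:
            inputs.append(gate[r])
        if inputs:
            inst.constraints += linearize_and(_tr(r, 0), inputs)
        else:
            inst.fix(_tr(r, 0), 1)
    for c in sorted(net.compound_ids - net.sources):
        producers = [_tr(r, 0) for r in sorted(net.producers(c))]
        if producers:
            inst.constraints += linearize_or(_tc(c, 0), producers)
        else:
            inst.fix(_tc(c, 0), 0)

    inst.fix(_tc(net.target, 0), 1)
    inst.meta["n_state_vars"] = len(net.nodes)
    return inst


def build_ip_mri_c(net: MetabolicNetwork, fvs: FVSResult,
                   reversible_cost: str = "pair",
                   split_border: bool = True) -> IPInstance:
    """FVS-folded encoding with t = 0..|FVS| (|FVS|+1 time indices).

    FVS splits carry the time mechanism: out-half 0 at t=0, out(t+1) =
    in(t) across steps, and in = out at the final step, which pins the
    trajectory to the least fixpoint.  Border reactions are split into
    the same in/out shape but copied within the step (the per-step
    equalities already evaluate them exactly, and a cross-step copy
    would need a longer horizon than |FVS|+1 on border chains).
    """
    fvs_set = frozenset(fvs.members)
    if not fvs_set <= net.reaction_ids:
        raise ValueError("FVS must consist of reaction nodes")
    to_split = fvs_set | (border_reactions(net) if split_border else frozenset())
    split = split_nodes(net, to_split)
    if not nx.is_directed_acyclic_graph(split.graph):
        raise ValueError("the supplied set is not a feedback vertex set: "
                         "the split graph still has a cycle")
    horizon = len(fvs_set)  # transitions; indices 0..horizon
    inst = IPInstance([], [], {}, {
        "encoding": "C", "horizon": horizon,
        "split": tuple(sorted(to_split)), "fvs": tuple(fvs.members),
    })
    gate = _decision_vars(inst, net, reversible_cost)

    def rvar(r: str, t: int) -> str:
        """Variable feeding r's products at step t (out-half if split)."""
        return _tsr(r, "out", t) if r in to_split else _tr(r, t)

    for t in range(horizon + 1):
        for c in sorted(net.compound_ids):
            inst.add_var(_tc(c, t))
        for r in sorted(net.reaction_ids):
            if r in to_split:
                inst.add_var(_tsr(r, "in", t))
                inst.add_var(_tsr(r, "out", t))
            else:
                inst.add_var(_tr(r, t))

    for t in range(horizon + 1):
        for s in sorted(net.sources):
            inst.fix(_tc(s, t), 1)
        for r in sorted(net.reaction_ids):
            inputs = [_tc(c, t) for c in sorted(net.substrates(r))]
            if r in gate:
                inputs.append(gate[r])
            head = _tsr(r, "in", t) if r in to_split else _tr(r, t)
            if inputs:
                inst.constraints += linearize_and(head, inputs)
            else:
                inst.fix(head, 1)
        for c in sorted(net.compound_ids - net.sources):
            producers = [rvar(r, t) for r in sorted(net.producers(c))]
            if producers:
                inst.constraints += linearize_or(_tc(c, t), producers)
            else:
                inst.fix(_tc(c, t), 0)

    for r in sorted(to_split):
        if r in fvs_set:
            inst.fix(_tsr(r, "out", 0), 0)
            for t in range(horizon):
                inst.add({_tsr(r, "out", t + 1): 1, _tsr(r, "in", t): -1}, "=", 0)
            # final-step stationarity pins the minimal valid assignment
            inst.add({_tsr(r, "in", horizon): 1, _tsr(r, "out", horizon): -1}, "=", 0)
        else:  # border split: same-step pass-through copy
            for t in range(horizon + 1):
                inst.add({_tsr(r, "out", t): 1, _tsr(r, "in", t): -1}, "=", 0)

    inst.fix(_tc(net.target, horizon), 1)
    inst.meta["n_state_vars"] = (len(net.nodes) + len(to_split)) * (horizon + 1)
    return inst


def _lp_name(name: str) -> str:
    return name.replace("(", "_").replace(")", "").replace("~", "_")


def to_lp(inst: IPInstance) -> str:
    """Render as CPLEX-LP text (names sanitised to the LP charset)."""
    lines = ["Minimize", " obj: " + " + ".join(
        f"{v} {_lp_name(n)}" if v != 1 else _lp_name(n)
        for n, v in sorted(inst.objective.items()))]
    lines.append("Subject To")
    rel_map = {"<=": "<=", ">=": ">=", "=": "="}
    for i, (coeffs, rel, rhs) in enumerate(inst.constraints):
        terms = []
        for n, v in sorted(coeffs.items()):
            sign = "+" if v >= 0 else "-"
            mag = abs(v)
            coef = "" if mag == 1 else f"{mag} "
            terms.append(f"{sign} {coef}{_lp_name(n)}")
        body = " ".join(terms).lstrip("+ ")
        lines.append(f" c{i}: {body} {rel_map[rel]} {rhs}")
    lines.append("Binary")
    lines.extend(" " + _lp_name(v) for v in inst.variables)
    lines.append("End")
    return "\n".join(lines) + "\n"
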