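"""MILP solving, verification, enumeration, and the exhaustive oracle.

The HiGHS solver (through :func:`scipy.optimize.milp`) drives the
encodings.  Every optimal answer is re-verified against the fixpoint
semantics before it is returned: the insertion set must actually make
the target producible under the minimal valid assignment, independently
of any IP artifacts.  Infeasibility is decided by a single fixpoint
evaluation with every candidate inserted, never by solver status alone.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .encode import IPInstance, build_ip_mri_a, build_ip_mri_b, build_ip_mri_c
from .fvs import find_greedy_fvs
from .network import MetabolicNetwork, additional_reactions, decision_units
from .semantics import Assignment, is_producible, minimal_valid_assignment

__all__ = ["MRISolution", "SolverError", "solve_mri", "brute_force_mri",
           "enumerate_optima", "verify_solution", "solve_instance"]


class SolverError(RuntimeError):
    """Solver failure, or an IP answer that fails semantic verification."""


@dataclass
class MRISolution:
    status: str  # optimal | infeasible | trivial
    inserted: frozenset
    objective: Optional[int]
    witness: Optional[Assignment]
    encoding: str
    solver_meta: dict = field(default_factory=dict)


def solve_instance(inst: IPInstance, time_limit: Optional[float] = None) -> tuple:
    """Solve one binary IP; returns (status, values dict, objective)."""
    idx = {v: i for i, v in enumerate(inst.variables)}
    n = len(inst.variables)
    c = np.zeros(n)
    for v, coef in inst.objective.items():
        c[idx[v]] = coef

    rows, cols, data, lb, ub = [], [], [], [], []
    for i, (coeffs, rel, rhs) in enumerate(inst.constraints):
        for v, coef in coeffs.items():
            rows.append(i)
            cols.append(idx[v])
            data.append(coef)
        if rel == "<=":
            lb.append(-np.inf), ub.append(rhs)
        elif rel == ">=":
            lb.append(rhs), ub.append(np.inf)
        else:
            lb.append(rhs), ub.append(rhs)
    a = sparse.csr_matrix((data, (rows, cols)), shape=(len(inst.constraints), n))

    options = {}
    if time_limit is not None:
        options["time_limit"] = time_limit
    res = milp(c, constraints=LinearConstraint(a, lb, ub),
               integrality=np.ones(n), bounds=Bounds(0, 1), options=options)
    if res.status == 0:
        values = {v: int(round(res.x[idx[v]])) for v in inst.variables}
        return "optimal", values, int(round(res.fun))
    if res.status == 2:
        return "infeasible", {}, None
    return f"solver_status_{res.status}", {}, None


def verify_solution(net: MetabolicNetwork, va: Iterable[str]) -> bool:
    """Producibility of the target under V_a by the fixpoint semantics."""
    return is_producible(net, va, net.target)


def _selected_units(inst: IPInstance, values: dict) -> tuple:
    units = [u for u in inst.meta["decision_units"]
             if values[_unit_var(inst, u)] == 1]
    return tuple(units)


def _unit_var(inst: IPInstance, unit: frozenset) -> str:
    return "TER" + "~".join(sorted(unit))


def _build(net: MetabolicNetwork, method: str, reversible_cost: str) -> IPInstance:
    if method == "A":
        return build_ip_mri_a(net, reversible_cost)
    if method == "B":
        return build_ip_mri_b(net, reversible_cost)
    if method == "C":
        return build_ip_mri_c(net, find_greedy_fvs(net), reversible_cost)
    raise ValueError(f"unknown method {method!r}")


def solve_mri(net: MetabolicNetwork, method: str = "C",
              reversible_cost: str = "pair",
              time_limit: Optional[float] = None,
              allow_unsound: bool = False) -> MRISolution:
    """Minimum reaction insertion for the network's target.

    ``method`` is ``"C"`` (FVS-folded, default), ``"A"`` (time-expanded
    cross-check), ``"brute"`` (exhaustive oracle), or ``"B"`` -- the
    diagnostic timeless encoding, which is unsound on cycles and
    therefore requires ``allow_unsound=True``; its answer is returned
    unverified with ``solver_meta["verified"]`` reporting the check.
    """
    if method == "B" and not allow_unsound:
        raise ValueError("IP-MRI-B is unsound on cyclic networks; "
                         "pass allow_unsound=True to use it diagnostically")
    extra = additional_reactions(net)

    # monotone pre-checks: one fixpoint call each
    if verify_solution(net, ()):
        return MRISolution("trivial", frozenset(), 0,
                           minimal_valid_assignment(net, ()), method)
    if not verify_solution(net, extra):
        return MRISolution("infeasible", frozenset(), None,
                           minimal_valid_assignment(net, extra), method)

    if method == "brute":
        return brute_force_mri(net, reversible_cost=reversible_cost)

    inst = _build(net, method, reversible_cost)
    status, values, objective = solve_instance(inst, time_limit)
    if status != "optimal":
        return MRISolution(status, frozenset(), None, None, method,
                           {"note": "no verified solution", "ip_status": status})
    units = _selected_units(inst, values)
    va = frozenset(itertools.chain.from_iterable(units))
    ok = verify_solution(net, va)
    if method == "B":
        witness = Assignment({v[2:].rsplit("(", 1)[0]: x
                              for v, x in values.items()
                              if v.startswith(("TC", "TR")) and not v.startswith("TER")})
        return MRISolution("optimal", va, objective, witness, "B",
                           {"verified": ok, "sound": False})
    if not ok:
        raise SolverError(f"encoding {method} returned {sorted(va)}, which does "
                          "not make the target producible under the fixpoint "
                          "semantics")
    return MRISolution("optimal", va, objective,
                       minimal_valid_assignment(net, va), method,
                       {"verified": True, "n_variables": len(inst.variables)})


def brute_force_mri(net: MetabolicNetwork, max_candidates: int = 20,
                    reversible_cost: str = "pair") -> MRISolution:
    """Exact optimum by scanning insertion-unit subsets by cardinality.

    Ties break lexicographically.  Refuses when more than
    ``max_candidates`` decision units would make the scan explode.
    """
    units = decision_units(net, reversible_cost)
    if len(units) > max_candidates:
        raise ValueError(f"{len(units)} candidate units exceed the exhaustive "
                         f"bound of {max_candidates}")
    for k in range(len(units) + 1):
        for combo in itertools.combinations(units, k):
            va = frozenset(itertools.chain.from_iterable(combo))
            if verify_solution(net, va):
                status = "trivial" if k == 0 else "optimal"
                return MRISolution(status, va, k,
                                   minimal_valid_assignment(net, va), "brute")
    return MRISolution("infeasible", frozenset(), None,
                       minimal_valid_assignment(net, frozenset().union(*units) if units else ()),
                       "brute")


def enumerate_optima(net: MetabolicNetwork, limit: int = 10,
                     method: str = "C", reversible_cost: str = "pair") -> list:
    """Distinct optimal insertion sets via no-good (exclusion) cuts.

    After each optimum V the cut sum_{u in V} x_u <= |V|-1 is added and
    the IP re-solved until the objective degrades or *limit* is hit.
    """
    first = solve_mri(net, method=method, reversible_cost=reversible_cost)
    if first.status == "infeasible":
        return []
    if first.status == "trivial":
        return [frozenset()]
    best = first.objective
    inst = _build(net, method, reversible_cost)
    found = []
    while len(found) < limit:
        status, values, objective = solve_instance(inst)
        if status != "optimal" or objective != best:
            break
        units = _selected_units(inst, values)
        va = frozenset(itertools.chain.from_iterable(units))
        if not verify_solution(net, va):
            raise SolverError("enumerated set fails semantic verification")
        found.append(va)
        inst.add({_unit_var(inst, u): 1 for u in units}, "<=", len(units) - 1)
    return found


def solution_report(net: MetabolicNetwork, sol: MRISolution) -> dict:
    """JSON-ready report: status, objective, insertions, producible set."""
    report = {
        "status": sol.status,
        "objective": sol.objective,
        "encoding": sol.encoding,
        "inserted": sorted(sol.inserted),
        "solver_meta": {k: v for k, v in sol.solver_meta.items()
                        if isinstance(v, (int, float, str, bool))},
    }
    if sol.witness is not None:
        report["producible_compounds"] = sorted(
            c for c in sol.witness.ones() if c in net.compound_ids)
    return report
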