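# boolgap — minimum reaction insertion in a Boolean metabolic model

`boolgap` solves the metabolic gap-filling question a strain designer asks
when a host organism cannot make a desired compound: *what is the smallest
set of reactions, taken from a multi-organism reference network, whose
insertion into the host makes the target producible?*  It is aimed at
metabolic engineers and systems biologists who want the Boolean answer —
one that respects substrate availability — rather than a shortest-path or
flux-balance answer.

## The model

A metabolic network is a directed bipartite graph with compound nodes and
reaction nodes.  Each reaction is an AND gate (it fires iff **all** its
substrates are producible); each compound is an OR gate (it is producible
iff **some** producing reaction fires).  Seed compounds *S* (the sources)
are always available; one compound *t* is the target.  The host network
*G_h* is an induced subgraph of the reference network *G_ref*; reactions
of *G_ref* outside the host are the insertion candidates.

For a candidate set *V_a*, producibility is judged by the **minimal valid
assignment**: the unique least fixpoint of the AND/OR update started from
the sources.  This is what makes cycles honest — a cycle can hold itself
at 1 in *some* valid assignment, but not in the minimal one, so a pathway
that "relies on a cycle" without an external entry point is correctly
rejected.  **Minimum Reaction Insertion (MRI)** asks for a minimum-size
*V_a* such that the target is 1 in the minimal valid assignment.  The
problem is NP-complete (it embeds minimum vertex cover, see
`boolgap.reductions`), so it is solved by binary integer programming:

* **IP-MRI-A** — time-expanded exact encoding, `O(n²)` variables;
* **IP-MRI-B** — timeless encoding, small but *unsound on cycles*
  (kept as a diagnostic);
* **IP-MRI-C** — the production encoding: a greedy reaction feedback
  vertex set (FVS) is split into in/out halves, the acyclic remainder is
  encoded timelessly within each of |FVS|+1 time steps, and values cross
  steps only through the FVS copies — `O(n·|FVS|)` variables with the
  exactness of A.

Answers are always re-verified against the fixpoint semantics before
being returned.  The MILP backend is HiGHS via `scipy.optimize.milp`.

## Worked example

The `CYCTRAP` fixture is the canonical cycle trap: the host turns seed
`s1` into `c1`; a three-reaction insertable path `ra1,ra2,ra3` leads from
`c1` to the target `t`, while a two-reaction insertable cycle `rb,rc`
runs through `t` itself.  The cycle looks like the cheaper fix but cannot
start without an external entry.

```sh
boolgap synth --fixture CYCTRAP --out cyctrap.json
boolgap solve --network cyctrap.json --method C
```

prints

```json
{
 "encoding": "C",
 "inserted": ["ra1", "ra2", "ra3"],
 "objective": 3,
 "producible_compounds": ["c1", "c4", "c5", "s1", "t"],
 "solver_meta": {"n_variables": 33, "verified": true},
 "status": "optimal"
}
```

The optimum is 3 — the honest path — not the 2-reaction cycle.  The
unsound timeless encoding falls into the trap
(`--method B` reports objective 2 with `"verified": false`), and

```sh
boolgap check --network cyctrap.json --insert rb,rc
```

confirms `"producible": false` for the cycle-only insertion: in the
minimal valid assignment every cycle node stays 0.

Other subcommands: `fvs` (greedy feedback vertex set), `encode` (export
an encoding as a CPLEX-LP file), `reduce-mvc` (vertex-cover instance →
MRI instance), `oracle` (exhaustive search for small candidate sets),
`synth` (fixtures and seeded random instances).  KGML pathway maps can be
supplied directly: `boolgap solve --ref-maps ko00010.xml --ref-maps
ko00561.xml --host-maps eco00010.xml --sources C00031,C00036 --target
C00479`.

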