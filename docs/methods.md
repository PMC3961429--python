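# Methods

## Model and assumptions

The network is Boolean and bipartite: reaction nodes are AND gates over
their substrate compounds, compound nodes are OR gates over their
producing reactions.  Stoichiometric coefficients, flux bounds and
compartments are deliberately out of scope; the model asks only whether
a compound *can* be made, not at what rate.  Source compounds are
assumed to have no incoming edges (they are environmental seeds held at
1); inputs that violate this are handled by a policy switch — the
default `strip` removes such edges with a warning, `strict` refuses the
input.

For an insertion set `V_a`, the evaluated subnetwork consists of the
host nodes, the inserted reactions, and every compound adjacent to an
active (host or inserted) reaction.  Compounds outside this subnetwork
read as 0.  Defining the compound set through adjacency (rather than
host membership alone) makes the fixpoint semantics and the integer
programs agree by construction, including on gadget-expanded networks
where host pass-through reactions touch non-host buffer compounds.

A *valid* assignment satisfies the three gate conditions; the *minimal*
valid assignment is the least fixpoint of the monotone update operator
started from the sources.  Uniqueness follows from the
source-connectedness argument: zeroing all non-source-connected nodes of
any valid assignment yields the same assignment.  The implementation
iterates synchronous Kleene sweeps (at most one sweep per node);
a chaotic worklist variant is kept and tested to give identical results,
as any fair iteration order of a monotone operator must.

## The three encodings

All Boolean gates are linearised exactly and two-sidedly
(`y = AND(x_i)` as `y ≤ x_i`, `y ≥ Σx_i − (k−1)`; `y = OR(x_i)` as
`y ≥ x_i`, `y ≤ Σx_i`).  Two-sidedness matters: with the insertion
variables fixed, the state variables of the sound encodings are *forced*
to the unique trajectory, which is what lets the final state coincide
with the minimal valid assignment.  "False" variables are eliminated by
the `1 − T` substitution throughout; the insertion decision `TER_r` of
an additional reaction joins its AND like a virtual substrate that never
changes over time.

* **A** uses time steps `t = 0..n` (`n` = node count, a safe bound on
  fixpoint convergence): state at `t+1` is the exact synchronous update
  of state at `t`, sources are 1 at every step, everything else is 0 at
  `t = 0`, and the target must be 1 at the last step.
* **B** drops time entirely.  On an acyclic network the equalities have
  a unique solution and B is exact; on a cyclic network a cycle may
  satisfy its equalities with all members at 1 without source support,
  so B may undercut the true optimum.  B is exposed only behind an
  explicit `allow_unsound` flag and its answers carry the verification
  verdict in their metadata.
* **C** splits each greedy-FVS reaction `r` into `r_in` (all in-edges)
  and `r_out` (all out-edges).  Time indices run `t = 0..|FVS|`.  Within
  each step the (now acyclic) graph is encoded timelessly; across steps
  the only coupling is the copy `r_out(t+1) = r_in(t)`, with
  `r_out(0) = 0` and the stationarity equality `r_in = r_out` at the
  final step.  Since the copy map is monotone on a lattice of dimension
  |FVS|, the trajectory converges within |FVS| transitions, the final
  equality is always satisfiable, and the final state is the least
  fixpoint — so C inherits A's exactness at a fraction of the variables.

### Border reactions

An insertable reaction with at least one host substrate (a *border*
reaction) is split into the same in/out shape as an FVS node, but its
two halves are equated within each step rather than copied across
steps.  Under this package's exact per-step equalities a cross-step copy
for border nodes would add nothing for correctness while requiring the
horizon to grow with the longest chain of border reactions (breaking the
|FVS|+1 step count that the single-FVS fixture pins down); the same-step
copy keeps the split structure, the step count, and exactness on every
instance, including chains of border reactions.

## Solving and verification

The MILP backend is HiGHS (`scipy.optimize.milp`), single-threaded and
deterministic for a fixed instance.  Feasibility is never inferred from
solver status alone: before any IP is built, one fixpoint evaluation
with *all* candidates inserted decides infeasibility, and one with none
decides triviality.  Every optimal IP answer is re-verified by the
fixpoint semantics; a verification failure raises instead of returning a
wrong set.  Relaxed values are rounded at 0.5 before extraction.
Alternate optima are enumerated with no-good cuts
(`Σ_{u∈V} x_u ≤ |V|−1` over the decision units of the previous
solution) until the objective degrades.

Reversible reactions are decomposed into opposed halves (`P`/`Q` for
KEGG `R`-numbers).  The default cost model charges one decision unit for
a reversible pair whose halves are both insertable — the reported
solutions of such pairs list both halves but count once — because
published insertion sets are reported as base reaction identifiers; a
`direction` cost model charging each half separately is available.  The
exhaustive oracle enumerates the same decision units, so oracle and IP
optimise the identical objective.

## Synthetic data

The fixtures encode the method's decision points at minimum size:
`CYCTRAP` (a 3-reaction honest path next to a 2-reaction self-feeding
cycle through the target; optimum 3, timeless trap 2), `BORDER` (an
insertable reaction fed by the host, no cycles), `CHAIN` (one missing
bridge) and `INFEASIBLE` (target with no producer).  The random
generator emulates the same anatomy: a host backbone chain from a single
seed, insertable reactions wiring random compound pairs (1–2 substrates
and products, matching the arity of typical small-molecule reactions),
optional injected two-reaction cycles, and — when solvability is
requested — one random insertable route of 1–3 reactions to the target.
It does not attempt genome-scale degree distributions, cofactor hubs, or
stoichiometry, so passing tests demonstrate algorithmic correctness on
cyclic bipartite AND/OR networks, not biological realism of any specific
pathway.  Test suites use instances whose decision-unit count stays
within the exhaustive-search bound (≤ 12) so every IP answer can be
cross-checked; suite sizes (200 random instances for the equivalence
suites, 100 graphs for the vertex-cover suite, ≤ 10-node networks for
the enumeration suite) keep the default test run in tens of seconds.

## Numerical and design choices

* Horizon of A is the node count — a safe upper bound; tightening it is
  an optimisation, not a correctness issue.
* Greedy FVS: iteratively trim nodes with in- or out-degree 0, then
  delete the remaining reaction node of maximum total degree, breaking
  ties by smallest identifier; deterministic by construction.  The MRI
  optimum is independent of the FVS used (tested greedy vs. minimum).
* Degree-bounding gadget: fan-ins/fan-outs above 2 are folded two at a
  time behind pass-through pairs (a single-input AND or OR is a copy).
  Intermediates are always host nodes — never insertion candidates — as
  any other choice would inflate the objective; insertion decisions
  remain on the original reactions, so the optimum is preserved.
* The vertex-cover instance generator marks the source, the edge
  compounds, the collector reaction and the target as host, and one
  reaction per graph vertex as insertable, making "k insertions ⇔ k
  cover vertices" exact.
* LP export sanitises `()`/`~` out of variable names to stay within the
  CPLEX-LP character set; in-memory names keep the `TC/TR/TER/TSR(t)`
  scheme.

## Known limitations

* The Boolean model ignores consumption: a compound used by many
  reactions is "available" to all of them at once.  Solutions may
  therefore be infeasible under flux balance; they are lower bounds on
  pathway size, not flux designs.
* IP-MRI-A's quadratic variable count makes it a cross-check, not a
  production path, beyond a few hundred nodes.
* KGML assembly unions direction annotations across maps; a reaction
  annotated with conflicting directions becomes reversible, which may
  admit insertions a curator would reject.
* Host maps are trusted as given: a reaction present in any host map is
  free, even if the organism's annotation is dubious.
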