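# Methods

## Modelling framework

A model is a time- and state-discrete dynamical system — a generalised
Boolean network.  Node `i` has `r_i` ordinal states (`2 ≤ r_i ≤ 5` under
the default cap), and a global state assigns one state to every node.
All nodes update **synchronously**: the successor of a global state is
obtained by evaluating every node's transition table against the same
current state.  Asynchronous and stochastic update schemes are out of
scope by design; with them the state space is no longer a functional
graph and the attractor/basin decomposition below does not apply.

Each node's update is a total lookup table (BSTT) over its regulators'
states plus its own state, the node's own state always occupying the
last column.  Default rows follow the additive rule
`next = clamp(self + Σ activator states − Σ inhibitor states)`.
Specific choices this package makes where the rule alone is ambiguous:

- **Single clamp after summation.**  Edge contributions accumulate as
  unclamped signed integers and the total is clamped once into the
  target's range.  Clamping each edge's effect separately would give
  different (and less symmetric) tables; per-edge views shown to a user
  are derived as `clamp(self + delta)`, never stored.
- **No incoming edges ⇒ identity.**  The additive rule with an empty sum
  leaves the node at its own state.  This is forced by the formalism but
  worth stating: source nodes are constants of the dynamics unless
  pinned or overridden.
- **Self-edges share the self column.**  A node never appears twice among
  its own table inputs; a self-edge's contribution is read from the same
  last column that carries the self state.  A 3-state node with a
  self-inhibition therefore updates to `clamp(c − c) = 0` for every `c`.
- **No rescaling across state counts.**  An edge contributes the raw
  integer source state even when source and target have different state
  counts; only the target-side clamp accounts for range differences.
  Users who want explicit rescaling attach a custom contribution table
  to the edge.
- **Overrides are row-local.**  An override replaces exactly one table
  row; removing it restores the additive default.  A fully overridden
  table expresses an arbitrary function.

## Attractor and basin analysis

The synchronous successor map on the `N = Π r_i` global states has
out-degree one, so every trajectory ends in a unique cycle (a steady
state when the cycle has length 1) and the cycles' basins partition the
space.  `find_attractors` first materialises the successor map as an
index array (vectorised over all states; each state's successor is
evaluated exactly once), then walks the iterated map from each
not-yet-classified state until the walk either meets itself (a new
cycle) or reaches an already classified state (an existing basin), and
labels the whole walked path.  Each state is touched a bounded number of
times, so the decomposition is linear in `N`; 559,872 states complete in
roughly a second on one CPU, and the degenerate worst case (every state
a fixed point) in a few seconds.

States are indexed mixed-radix with the first declared node as the most
significant digit, so lexicographic order of state tuples coincides with
numeric index order.  Node declaration order is canonical throughout
(state tuples, table row enumeration, indexing); enumeration order has
no effect on the attractors found.

Deterministic tie-breaks, fixed for reproducibility: each cycle is
rotated to start at its smallest state index, and attractors are
reported sorted by descending basin size, ties broken by smallest state
index on the cycle.  Basin percentages are printed to one decimal;
integer counts are kept internally.

Caps: exhaustive analysis refuses above 10^7 states and state-graph
construction above 2,600 displayed states (graphs beyond that are
unreadable and expensive to lay out); both caps are explicit arguments
and can be raised.  The per-node state-count cap of 5 is likewise a
validation default, not a mathematical limit, and is configurable.

## Experiments

An experiment pins nodes to constant states.  The pinned node's update
function is replaced by the constant — it ignores all inputs — while its
outgoing edges remain active, so a nonzero pin (overexpression,
knockdown reversal) propagates downstream exactly like a held input.
This constant-table semantics keeps the perturbed system total and
deterministic, so the analysis of a perturbed model is *complete*:
basins still sum to the full state-space size (states violating the pin
simply transition into the pinned subspace after one step) and limit
cycles of the perturbed system are found, not silently dropped.  An
empty experiment reproduces the unperturbed results bit for bit.

## Bundled fixtures and the random-model generator

Two didactic fixtures (the 2/2/3-state and 2/3/4-state `A → C ← B`
motifs) are pure additive defaults with hand-checkable dynamics.  The
floral organ-fate scaffold carries the published 15-node structure
(8 binary, 7 ternary; 559,872 states); its logical rules are third-party
published tables, so the package ships a loader plus transcription
template rather than the rules themselves.  The rules file gives, per
node, its regulator list and the complete output table in row-major
order over regulators plus self; the loader validates arity and output
ranges against the scaffold declarations.

The random-model generator exists for property-based testing.  It draws
per-node state counts from a configurable menu, places each possible
directed edge (self-edges included) independently with probability 0.3
by default, makes 40% of edges inhibitory, and can randomise a fraction
of BSTT rows to arbitrary valid outputs.  Randomness comes from NumPy's
named PCG64 generator, so a seed pins the model exactly across platforms.
These models emulate the *combinatorial* variety of wiring, state-count
mixtures, and table overrides; they do not emulate the topology of real
regulatory networks (degree distributions, motif enrichment, biological
rule structure).  Passing tests therefore certify the engine's
correctness on arbitrary models of this class, not the biological
fidelity of any particular network.

## Verification strategy and problem sizes

The analysis engine is checked against an independent brute-force
oracle that shares no code with it: the oracle recomputes every
successor directly from the model definition (additive rule over the
edge list, override lookup) and finds attractors by naively walking each
state's trajectory to its first repeat.  The acceptance suite compares
attractor sets and exact basin sizes on 200 seeded random models (each
kept below 2,000 states so the naive walk stays cheap), plus perturbed
variants for pin invariance; the whole suite runs in a few seconds.
Scale behaviour is demonstrated on a seeded synthetic 15-node model with
the floral state-count profile, where the full 559,872-state
decomposition must finish well under a minute.

## Serialisation

Models are stored as versioned JSON (schema_version 1.0).  States are
written as labels, with the integer mapping fixed by label order, and
node order in the file is the canonical order.  Serialisation is
canonical (fixed key order, two-space indent), so identical models
produce byte-identical files; unknown top-level fields survive a
load/save round trip.  Analysis summaries export as RFC 4180 CSV (one
row per attractor state, labels and integers side by side); state
graphs export as DOT or GraphML with attractor states flagged.

## Known limitations

- Exhaustive enumeration only: no sampling-based estimation and no
  SAT/BDD symbolic attractor detection, so state spaces beyond ~10^7
  states are out of reach by design.
- Synchronous deterministic semantics only.
- The floral rules transcription is user-supplied; the package cannot
  verify a transcription against the original publication beyond
  structural consistency and the published attractor counts.
- Perturbations are constant pins; time-varying perturbations and
  edge-specific knockouts are not modelled.
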