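# logicsim

Multi-state logical network models for molecular biology: build a
regulatory wiring diagram, compile it into a deterministic discrete
dynamical system, exhaustively enumerate every attractor and its basin
of attraction, and run in-silico knockout / overexpression experiments —
all scriptable from Python or a small CLI.

## Who this is for

Experimentalists and modellers who want qualitative dynamic models of
gene/protein networks without differential equations: each node takes a
small number of ordinal states (Off/On, Low/Medium/High, ...; 2–5 levels
by default), and the network updates synchronously in discrete time.
Steady states of such a model correspond to the stable phenotypes the
network can express, and the size of each basin of attraction is a proxy
for how likely that phenotype is.

## The model

A network is a set of nodes `x_1 .. x_n`, node `i` taking states
`0 .. r_i − 1`, with signed edges (activate / inhibit / custom).  Each
node updates by a total transition table over its regulators' states and
its own state (the "big state transition table", BSTT).  By default the
table is **additive**:

```
x_i(t+1) = clamp( x_i(t) + Σ_activators s_j(t) − Σ_inhibitors s_k(t) )
```

where `clamp` cuts the sum into `0 .. r_i − 1` — a value below the
lowest state becomes 0, above the highest becomes `r_i − 1`.  Any table
row can be overridden, so arbitrary logical rules (synergy, thresholds,
full custom tables) are expressible.  All nodes update simultaneously,
so the state space (of size `Π r_i`) is a functional graph: every global
state has exactly one successor, every trajectory ends in a steady state
or a limit cycle, and those attractors partition the space into basins.
`find_attractors` walks the memoised successor map from every state,
detecting each cycle at its first repeat — an exact, exhaustive
decomposition (about a second for ~10^6 states).

Experiments pin nodes to constant states: the pinned node's update is
replaced by the constant (state 0 = knockout; higher states = knockdown
reversal / overexpression), the pinned value still propagates to its
targets, and the analysis of the perturbed system is complete — steady
states *and* limit cycles.

## Worked example

The bundled three-node model: `A` (2 states) activates `C`, `B`
(2 states) inhibits `C` (3 states), so `C(t+1) = clamp(A − B + C)` and
`A`, `B` hold their states.

```pycon
>>> import logicsim as ls
>>> model = ls.fig1_model()
>>> result = ls.find_attractors(ls.compile_model(model))
>>> len(result.attractors), result.n_limit_cycles
(8, 0)
>>> [(a.cycle_states[0], a.basin_size) for a in result.attractors[:2]]
[((0, 1, 0), 3), ((1, 0, 2), 3)]
```

All 8 attractors are steady states.  When `A=1, B=0`, `C` climbs until
it saturates at 2, so the whole `(1,0,*)` slice (3 states) drains into
`(1,0,2)`; symmetrically `(0,1,*)` drains into `(0,1,0)`; and when
`A = B` the contributions cancel, leaving each of the remaining 6 states
fixed with a basin of 1.  The same from the command line, plus a B
knockout:

```
$ logicsim analyze fig1.json
Model: three_node_example (3 nodes, 12 states)
Attractors: 8 (8 steady states, 0 limit cycles)
id  length  basin  basin%  states
0   1       3      25.0    (0,1,0)
1   1       3      25.0    (1,0,2)
2   1       1      8.3     (0,0,0)
...

$ logicsim analyze fig1.json --knockout B
Attractors: 4 (4 steady states, 0 limit cycles)
```

With `B` pinned at 0 only the four fixed points reachable under `B=0`
remain: `(0,0,0)`, `(0,0,1)`, `(0,0,2)` and `(1,0,2)`.
`--summary out.csv` writes the attractor table, `--graph out.dot` (or
`.graphml`) the state-transition graph with attractor states flagged.

## The floral organ-fate network

The package bundles the node/state scaffold of the 15-node Arabidopsis
floral organ determination network (8 binary and 7 ternary nodes,
2^8 · 3^7 = 559,872 global states).  Its logical rules are published
third-party tables and are **not** redistributed here: call
`logicsim.write_floral_rules_template(path)` for a transcription
template, fill in each node's regulators and full transition table, and
load the complete dynamic model with
`logicsim.floral_scaffold(rules_path)`.  With a correct transcription
the wild-type analysis yields exactly 40 steady states (no cycles) and
the AP2 knockout 28; the corresponding test in
`tests/test_acceptance.py` runs the full check when a transcription is
placed at `data/floral_rules.json`.

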