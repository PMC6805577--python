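"""Independent brute-force oracle for attractor analysis.

Deliberately shares no code path with the package's compiled tables or
functional-graph decomposition: the successor is recomputed for every
state directly from the model definition (additive rule over the edge
list, override lookup), and attractors are found by naively walking each
state's trajectory to its first repeat.  Slow, simple, and only suitable
for small state spaces.
"""

from __future__ import annotations

import itertools
from collections import Counter

from logicsim.model import ModelSpec, bstt_inputs


def oracle_successor(
    model: ModelSpec, states: tuple[int, ...], pins: dict[str, int] | None = None
) -> tuple[int, ...]:
    pins = pins or {}
    by_name = dict(zip(model.node_names, states))
    nxt = []
    for node in model.nodes:
        if node.name in pins:
            nxt.append(pins[node.name])
            continue
        inputs = bstt_inputs(model, node.name)
        row = tuple(by_name[i] for i in inputs)
        overrides = model.bstt_overrides.get(node.name, {})
        if row in overrides:
            nxt.append(overrides[row])
            continue
        total = by_name[node.name]
        for e in model.edges:
            if e.target != node.name:
                continue
            s = by_name[e.source]
            if e.sign == "activate":
                total += s
            elif e.sign == "inhibit":
                total -= s
            else:
                total += e.contribution_table[s]
        nxt.append(min(max(total, 0), node.state_count - 1))
    return tuple(nxt)


def canonical_cycle(cycle: list[tuple[int, ...]]) -> tuple[tuple[int, ...], ...]:
    """Rotate a cycle to start at its lexicographically smallest state."""
    k = cycle.index(min(cycle))
    return tuple(cycle[k:] + cycle[:k])


def oracle_attractors(
    model: ModelSpec, pins: dict[str, int] | None = None
) -> dict[tuple[tuple[int, ...], ...], int]:
    """Map each attractor cycle (canonical rotation) to its basin size."""
    basins: Counter = Counter()
    terminal: dict[tuple[int, ...], tuple] = {}  # state -> its cycle
    for start in itertools.product(*(range(n.state_count) for n in model.nodes)):
        if start in terminal:
            continue
        path = [start]
        pos = {start: 0}
        x = start
        while True:
            x = oracle_successor(model, x, pins)
            if x in terminal:  # joins a known basin
                cycle = terminal[x]
                break
            if x in pos:  # closed a new cycle
                cycle = canonical_cycle(path[pos[x]:])
                break
            pos[x] = len(path)
            path.append(x)
        for y in path:
            terminal[y] = cycle
        basins[cycle] += len(path)
    return dict(basins)
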