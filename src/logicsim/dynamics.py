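"""Exhaustive synchronous state-space analysis.

The synchronous update of a deterministic logical model is a function on
a finite state space, so its transition graph is a functional graph: one
out-edge per state.  Every connected component contains exactly one
cycle — a steady state (length 1) or a limit cycle — and the component is
that attractor's basin.  :func:`find_attractors` decomposes the whole
space by walking the iterated map from each not-yet-classified state
until it meets either the current walk (a new cycle) or an already
classified state, then labelling the walked path; with the successor map
memoised, every state is touched a bounded number of times.

States are addressed both as tuples (one integer per node, canonical
node-declaration order) and as mixed-radix indices where the first node
is the most significant digit, so lexicographic tuple order coincides
with numeric index order.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .model import CompiledModel

__all__ = [
    "DEFAULT_ANALYSIS_CAP",
    "DEFAULT_GRAPH_CAP",
    "StateSpaceTooLarge",
    "state_to_index",
    "index_to_state",
    "successor",
    "Attractor",
    "AnalysisResult",
    "Trajectory",
    "find_attractors",
    "simulate",
    "StateGraph",
    "state_space_graph",
]

#: Refuse exhaustive analysis above this many states unless overridden.
DEFAULT_ANALYSIS_CAP = 10_000_000
#: Refuse state-graph construction above this many displayed states.
DEFAULT_GRAPH_CAP = 2600


class StateSpaceTooLarge(Exception):
    """The requested enumeration exceeds the configured cap."""


def state_to_index(states: Sequence[int], radices: Sequence[int]) -> int:
    """Mixed-radix index of a state tuple (first node most significant)."""
    if len(states) != len(radices):
        raise ValueError(f"{len(states)} components for {len(radices)} radices")
    index = 0
    for s, r in zip(states, radices):
        if not (0 <= s < r):
            raise ValueError(f"component {s} outside radix {r}")
        index = index * r + s
    return index


def index_to_state(index: int, radices: Sequence[int]) -> tuple[int, ...]:
    """Inverse of :func:`state_to_index`."""
    total = 1
    for r in radices:
        total *= r
    if not (0 <= index < total):
        raise ValueError(f"index {index} outside 0..{total - 1}")
    out = []
    for r in reversed(radices):
        out.append(index % r)
        index //= r
    return tuple(reversed(out))


def successor(compiled: CompiledModel, states: Sequence[int]) -> tuple[int, ...]:
    """Synchronous successor of one global state."""
    return compiled.successor(states)


@dataclass(frozen=True)
class Attractor:
    """A steady state or limit cycle together with its basin.

    ``cycle_states[k+1]`` is the successor of ``cycle_states[k]`` (and the
    first follows the last); the cycle is rotated to start at its smallest
    state index.  ``basin_size`` counts every state that eventually enters
    the cycle, cycle states included.
    """

    cycle_states: tuple[tuple[int, ...], ...]
    cycle_indices: tuple[int, ...]
    basin_size: int
    basin_pct: float

    @property
    def period(self) -> int:
        return len(self.cycle_states)

    @property
    def is_steady(self) -> bool:
        return len(self.cycle_states) == 1


@dataclass
class AnalysisResult:
    """Complete attractor/basin decomposition of a model's state space.

    ``attractors`` is sorted by descending basin size, ties broken by the
    smallest state index on the cycle.  ``assignment[i]`` gives the
    position in ``attractors`` of the attractor that state index ``i``
    evolves into.
    """

    compiled: CompiledModel
    attractors: list[Attractor]
    total_states: int
    elapsed_seconds: float
    assignment: np.ndarray = field(repr=False)

    @property
    def n_steady_states(self) -> int:
        return sum(1 for a in self.attractors if a.is_steady)

    @property
    def n_limit_cycles(self) -> int:
        return sum(1 for a in self.attractors if not a.is_steady)

    def attractor_of(self, states: Sequence[int]) -> Attractor:
        idx = state_to_index(states, self.compiled.radices)
        return self.attractors[int(self.assignment[idx])]


def find_attractors(
    compiled: CompiledModel, analysis_cap: int = DEFAULT_ANALYSIS_CAP
) -> AnalysisResult:
    """Enumerate all attractors and basins by exhaustive iteration.

    Walks the successor map from every state in index order; each walk
    stops at the first state already seen, which either closes a new
    cycle (first repeat inside the current walk) or joins a basin already
    labelled.  All states on the walk inherit the attractor label.
    """
    n = compiled.n_states
    if n > analysis_cap:
        raise StateSpaceTooLarge(
            f"state space has {n} states, above the analysis cap {analysis_cap}; "
            f"pass a larger analysis_cap to proceed"
        )
    t0 = time.perf_counter()
    succ = compiled.successor_array().tolist()
    label = [-1] * n           # attractor id per state
    walk_id = [-1] * n         # which walk last touched the state
    walk_pos = [0] * n         # position of the state inside that walk
    cycles: list[list[int]] = []

    for start in range(n):
        if label[start] >= 0:
            continue
        path: list[int] = []
        x = start
        while label[x] < 0 and walk_id[x] != start:
            walk_id[x] = start
            walk_pos[x] = len(path)
            path.append(x)
            x = succ[x]
        if label[x] >= 0:
            cid = label[x]
        else:  # x closed a cycle within this walk
            cid = len(cycles)
            cycles.append(path[walk_pos[x]:])
        for y in path:
            label[y] = cid

    counts = np.bincount(np.asarray(label, dtype=np.int64), minlength=len(cycles))
    radices = compiled.radices
    attractors = []
    order = []
    for cid, cycle in enumerate(cycles):
        # canonical rotation: cycle starts at its smallest state index
        k = cycle.index(min(cycle))
        cycle = cycle[k:] + cycle[:k]
        size = int(counts[cid])
        attractors.append(
            Attractor(
                cycle_states=tuple(index_to_state(i, radices) for i in cycle),
                cycle_indices=tuple(cycle),
                basin_size=size,
                basin_pct=size / n * 100.0,
            )
        )
        order.append(cid)
    order.sort(key=lambda cid: (-attractors[cid].basin_size, attractors[cid].cycle_indices[0]))
    rank = {cid: pos for pos, cid in enumerate(order)}
    assignment = np.array([rank[c] for c in label], dtype=np.int64)
    attractors = [attractors[cid] for cid in order]
    return AnalysisResult(
        compiled=compiled,
        attractors=attractors,
        total_states=n,
        elapsed_seconds=time.perf_counter() - t0,
        assignment=assignment,
    )


@dataclass
class Trajectory:
    """One deterministic time course from a chosen initial state.

    ``states`` lists the visited states up to (and excluding) the first
    repeat; ``terminal`` is the attractor cycle reached, rotated to start
    where the trajectory entered it; ``transient_length`` counts the steps
    taken before entering the cycle.  ``complete`` is False when
    ``max_steps`` ran out before any state repeated.
    """

    states: list[tuple[int, ...]]
    terminal: tuple[tuple[int, ...], ...] | None
    transient_length: int | None
    complete: bool


def simulate(
    compiled: CompiledModel, initial: Sequence[int], max_steps: int = 1000
) -> Trajectory:
    """Iterate the synchronous update from ``initial`` until a state
    repeats or ``max_steps`` transitions have been taken."""
    state = tuple(initial)
    seen: dict[tuple[int, ...], int] = {}
    states: list[tuple[int, ...]] = []
    for _ in range(max_steps + 1):
        if state in seen:
            first = seen[state]
            return Trajectory(
                states=states,
                terminal=tuple(states[first:]),
                transient_length=first,
                complete=True,
            )
        seen[state] = len(states)
        states.append(state)
        state = compiled.successor(state)
    return Trajectory(states=states, terminal=None, transient_length=None, complete=False)


@dataclass
class StateGraph:
    """Edge list of (a subset of) the state-transition graph.

    Nodes are state indices; every node has exactly one out-edge, its
    synchronous successor.  ``attractor_indices`` flags the states lying
    on a cycle, for visual distinction in exports.
    """

    compiled: CompiledModel
    edges: list[tuple[int, int]]
    attractor_indices: frozenset[int]

    @property
    def node_indices(self) -> list[int]:
        return sorted({i for e in self.edges for i in e})

    def state_label(self, index: int) -> str:
        states = index_to_state(index, self.compiled.radices)
        return "(" + ",".join(str(s) for s in states) + ")"

    def state_text(self, index: int) -> str:
        states = index_to_state(index, self.compiled.radices)
        return " ".join(
            node.label_of(s) for node, s in zip(self.compiled.model.nodes, states)
        )


def state_space_graph(
    compiled: CompiledModel,
    result: AnalysisResult | None = None,
    attractor: Attractor | None = None,
    graph_cap: int = DEFAULT_GRAPH_CAP,
) -> StateGraph:
    """Build the transition edge list, optionally restricted to one
    attractor's basin.

    Restriction requires the ``result`` the attractor came from (its
    basin assignment).  Refuses to build graphs above ``graph_cap``
    states — large state graphs are unreadable and expensive to lay out —
    unless the cap is raised explicitly.
    """
    if attractor is not None:
        if result is None:
            raise ValueError("restricting to a basin requires the AnalysisResult")
        aid = result.attractors.index(attractor)
        selected = np.flatnonzero(result.assignment == aid)
    else:
        selected = np.arange(compiled.n_states)
    if len(selected) > graph_cap:
        raise StateSpaceTooLarge(
            f"state graph would have {len(selected)} nodes, above the display cap "
            f"{graph_cap}; pass a larger graph_cap to proceed"
        )
    succ = compiled.successor_array()
    edges = [(int(i), int(succ[i])) for i in selected]
    if result is not None:
        cycle_idx = {i for a in result.attractors for i in a.cycle_indices}
    else:
        sel = set(int(i) for i in selected)
        cycle_idx = _cycle_indices(succ, sel)
    return StateGraph(
        compiled=compiled,
        edges=edges,
        attractor_indices=frozenset(i for i in cycle_idx if int(i) in {e[0] for e in edges}),
    )


def _cycle_indices(succ: np.ndarray, selected: set[int]) -> set[int]:
    """States of ``selected`` that lie on a cycle of the successor map."""
    on_cycle: set[int] = set()
    done: set[int] = set()
    for s in selected:
        if s in done:
            continue
        path = []
        pos = {}
        x = s
        while x not in pos and x not in done:
            pos[x] = len(path)
            path.append(x)
            x = int(succ[x])
        if x in pos:  # new cycle found in this walk
            on_cycle.update(path[pos[x]:])
        done.update(path)
    return {s for s in on_cycle if s in selected}
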