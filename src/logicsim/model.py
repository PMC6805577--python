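"""Multi-state logical network models and their compilation.

A model is a wiring diagram: nodes carrying a small number of ordinal
states (2-5 by default), signed regulatory edges, and optional row-level
overrides of each node's transition table.  Every node updates by a total
lookup table — the Big State Transition Table (BSTT) — mapping each
combination of its regulators' states plus its own state to its next
state.  With no overrides the table follows the additive rule

    next = clamp(self + sum(activator states) - sum(inhibitor states))

clamped into the target's state range ``0 .. state_count - 1``.  The sum
is accumulated unclamped over all incoming edges and clamped once; this
matches the printed arithmetic convention for multi-input nodes, and
differs from clamping each edge's effect separately.

Nodes with no incoming edges keep their state (the additive rule with an
empty sum is the identity).  A self-edge contributes through the same
(last) BSTT column that carries the node's own state: the node appears
exactly once among the table's inputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "ACTIVATE",
    "INHIBIT",
    "CUSTOM",
    "DEFAULT_MAX_STATES",
    "NodeSpec",
    "EdgeSpec",
    "TransitionTable",
    "ModelSpec",
    "Violation",
    "ValidationReport",
    "ModelError",
    "ModelValidationError",
    "ModelCompilationError",
    "clamp",
    "edge_contribution",
    "validate_model",
    "bstt_inputs",
    "build_bstt",
    "compile_model",
    "CompiledModel",
]

ACTIVATE = "activate"
INHIBIT = "inhibit"
CUSTOM = "custom"
EDGE_SIGNS = (ACTIVATE, INHIBIT, CUSTOM)

#: Hard cap on per-node state counts; a validation default, not a law of
#: nature — ``validate_model(..., max_states=N)`` lifts it.
DEFAULT_MAX_STATES = 5

#: Default ordinal label menus per state count, lowest state first.
DEFAULT_STATE_LABELS: dict[int, tuple[str, ...]] = {
    2: ("Off", "On"),
    3: ("Low", "Medium", "High"),
    4: ("Off", "Low", "Medium", "High"),
    5: ("Off", "Low", "Medium", "High", "Max"),
}


class ModelError(Exception):
    """Base class for model construction/compilation failures."""


class ModelCompilationError(ModelError):
    """A transition table could not be built (bad override or custom edge)."""


class ModelValidationError(ModelError):
    """Raised when compiling a model whose validation report is non-empty."""

    def __init__(self, report: "ValidationReport"):
        self.report = report
        lines = "; ".join(str(v) for v in report)
        super().__init__(f"invalid model: {lines}")


def clamp(value: int, max_state: int) -> int:
    """Clamp ``value`` into the state range ``0 .. max_state``.

    This is the arithmetic convention of the additive rule: a summed
    input below the lowest state yields 0, above the highest yields
    ``max_state``.
    """
    if max_state < 1:
        raise ValueError(f"max_state must be >= 1, got {max_state}")
    return min(max(value, 0), max_state)


@dataclass(frozen=True)
class NodeSpec:
    """One network node with ``state_count`` ordinal levels.

    Internally states are the integers ``0 .. state_count - 1``; the i-th
    label names state i.  Labels default to a standard menu (Off/On,
    Low/Medium/High, ...) when not given.
    """

    name: str
    state_count: int
    state_labels: tuple[str, ...] = ()
    position: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.state_labels:
            labels = DEFAULT_STATE_LABELS.get(
                self.state_count,
                tuple(str(i) for i in range(max(self.state_count, 0))),
            )
            object.__setattr__(self, "state_labels", tuple(labels))
        else:
            object.__setattr__(self, "state_labels", tuple(self.state_labels))
        if self.position is not None:
            object.__setattr__(self, "position", tuple(self.position))

    @property
    def max_state(self) -> int:
        return self.state_count - 1

    def label_of(self, state: int) -> str:
        return self.state_labels[state]

    def state_of(self, label: str) -> int:
        try:
            return self.state_labels.index(label)
        except ValueError:
            raise KeyError(
                f"node {self.name!r} has no state labelled {label!r} "
                f"(labels: {list(self.state_labels)})"
            ) from None


@dataclass(frozen=True)
class EdgeSpec:
    """A signed regulatory edge ``source -> target``.

    For the default signs the contribution of the edge to the target's
    additive sum is the raw source state: ``+s`` for an activator, ``-s``
    for an inhibitor.  A ``custom`` edge carries an explicit contribution
    table indexed by source state, which is how a user rescales inputs
    between nodes with differing state counts.
    """

    source: str
    target: str
    sign: str = ACTIVATE
    contribution_table: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.contribution_table is not None:
            object.__setattr__(
                self, "contribution_table", tuple(int(v) for v in self.contribution_table)
            )


def edge_contribution(edge: EdgeSpec, source_state: int) -> int:
    """Signed delta the edge adds to its target's additive sum."""
    if edge.sign == ACTIVATE:
        return source_state
    if edge.sign == INHIBIT:
        return -source_state
    if edge.sign == CUSTOM:
        table = edge.contribution_table
        if table is None or not (0 <= source_state < len(table)):
            raise ModelCompilationError(
                f"custom edge {edge.source}->{edge.target} has no contribution "
                f"for source state {source_state}"
            )
        return table[source_state]
    raise ModelCompilationError(
        f"edge {edge.source}->{edge.target} has unknown sign {edge.sign!r}"
    )


@dataclass(frozen=True)
class TransitionTable:
    """A node's total Big State Transition Table.

    ``input_order`` lists the regulator nodes in edge-declaration order
    with the target itself always last; ``rows`` maps every input-state
    tuple (in that order) to the target's next state.  ``overridden_rows``
    records which rows were user-set rather than additive defaults.
    """

    target: str
    input_order: tuple[str, ...]
    rows: Mapping[tuple[int, ...], int]
    overridden_rows: frozenset[tuple[int, ...]] = frozenset()

    def __len__(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class ModelSpec:
    """A complete wiring diagram with metadata.

    Node declaration order is canonical: it fixes the order of state
    tuples, the mixed-radix state index, and BSTT row enumeration.
    """

    name: str
    nodes: tuple[NodeSpec, ...]
    edges: tuple[EdgeSpec, ...] = ()
    bstt_overrides: Mapping[str, Mapping[tuple[int, ...], int]] = field(default_factory=dict)
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "edges", tuple(self.edges))
        canonical = {
            str(name): {tuple(int(s) for s in row): int(out) for row, out in rows.items()}
            for name, rows in dict(self.bstt_overrides).items()
        }
        object.__setattr__(self, "bstt_overrides", canonical)

    @property
    def node_names(self) -> tuple[str, ...]:
        return tuple(n.name for n in self.nodes)

    @property
    def radices(self) -> tuple[int, ...]:
        """Per-node state counts in canonical order."""
        return tuple(n.state_count for n in self.nodes)

    @property
    def n_states(self) -> int:
        total = 1
        for r in self.radices:
            total *= r
        return total

    def node(self, name: str) -> NodeSpec:
        for n in self.nodes:
            if n.name == name:
                return n
        raise KeyError(f"model {self.name!r} has no node named {name!r}")

    def node_index(self, name: str) -> int:
        for i, n in enumerate(self.nodes):
            if n.name == name:
                return i
        raise KeyError(f"model {self.name!r} has no node named {name!r}")

    def in_edges(self, target: str) -> tuple[EdgeSpec, ...]:
        return tuple(e for e in self.edges if e.target == target)


@dataclass(frozen=True)
class Violation:
    """One broken invariant, locating the offending node/edge/override."""

    code: str
    where: str
    message: str

    def __str__(self) -> str:
        return f"[{self.code}] {self.where}: {self.message}"


class ValidationReport(list):
    """List of :class:`Violation`; empty means the model is valid."""

    @property
    def ok(self) -> bool:
        return not self


def bstt_inputs(model: ModelSpec, target: str) -> tuple[str, ...]:
    """BSTT input columns for ``target``: edge sources in declaration
    order (the target excluded), then the target itself, always last."""
    sources = []
    for e in model.in_edges(target):
        if e.source != target and e.source not in sources:
            sources.append(e.source)
    return tuple(sources) + (target,)


def validate_model(model: ModelSpec, max_states: int = DEFAULT_MAX_STATES) -> ValidationReport:
    """Check every structural invariant; report all violations, raise none."""
    report = ValidationReport()
    seen: set[str] = set()
    for node in model.nodes:
        if node.name in seen:
            report.append(Violation("duplicate-node", node.name, "node name declared twice"))
        seen.add(node.name)
        if node.state_count < 2 or node.state_count > max_states:
            report.append(
                Violation(
                    "state-count",
                    node.name,
                    f"state_count {node.state_count} outside allowed 2..{max_states}",
                )
            )
        if len(node.state_labels) != node.state_count:
            report.append(
                Violation(
                    "label-count",
                    node.name,
                    f"{len(node.state_labels)} labels for {node.state_count} states",
                )
            )
        if len(set(node.state_labels)) != len(node.state_labels):
            report.append(Violation("duplicate-label", node.name, "state labels not unique"))

    names = {n.name for n in model.nodes}
    seen_pairs: set[tuple[str, str]] = set()
    for e in model.edges:
        where = f"{e.source}->{e.target}"
        if e.source not in names:
            report.append(Violation("unknown-source", where, f"source {e.source!r} is not a node"))
        if e.target not in names:
            report.append(Violation("unknown-target", where, f"target {e.target!r} is not a node"))
        if (e.source, e.target) in seen_pairs:
            report.append(Violation("duplicate-edge", where, "more than one edge for this pair"))
        seen_pairs.add((e.source, e.target))
        if e.sign not in EDGE_SIGNS:
            report.append(Violation("bad-sign", where, f"unknown edge sign {e.sign!r}"))
        if e.sign == CUSTOM:
            if e.source not in names:
                continue
            expected = model.node(e.source).state_count
            table = e.contribution_table
            if table is None:
                report.append(
                    Violation("custom-table-missing", where, "custom edge without contribution table")
                )
            elif len(table) != expected:
                report.append(
                    Violation(
                        "custom-table-arity",
                        where,
                        f"contribution table has {len(table)} entries for {expected} source states",
                    )
                )
        elif e.contribution_table is not None:
            report.append(
                Violation(
                    "unexpected-table", where, f"{e.sign} edge carries a contribution table"
                )
            )

    structural_ok = not report
    for name, rows in model.bstt_overrides.items():
        if name not in names:
            report.append(Violation("override-node", name, "override for unknown node"))
            continue
        if not structural_ok:
            continue  # input arity undefined while edges are broken
        inputs = bstt_inputs(model, name)
        arities = tuple(model.node(i).state_count for i in inputs)
        out_max = model.node(name).max_state
        for row, out in rows.items():
            where = f"{name}{row}"
            if len(row) != len(arities) or any(
                not (0 <= s < a) for s, a in zip(row, arities)
            ):
                report.append(
                    Violation(
                        "override-row",
                        where,
                        f"row does not index the {len(inputs)}-input table over {arities}",
                    )
                )
            if not (0 <= out <= out_max):
                report.append(
                    Violation("override-output", where, f"output {out} outside 0..{out_max}")
                )
    return report


def build_bstt(model: ModelSpec, target: str) -> TransitionTable:
    """Build the node's total transition table: additive defaults for
    every input combination, then the model's row overrides applied."""
    node = model.node(target)
    edges = model.in_edges(target)
    inputs = bstt_inputs(model, target)
    arities = tuple(model.node(i).state_count for i in inputs)

    rows: dict[tuple[int, ...], int] = {}
    for combo in itertools.product(*(range(a) for a in arities)):
        by_name = dict(zip(inputs, combo))
        total = combo[-1]  # the node's own state, always the last column
        for e in edges:
            total += edge_contribution(e, by_name[e.source])
        rows[combo] = clamp(total, node.max_state)

    overrides = model.bstt_overrides.get(target, {})
    overridden = []
    for row, out in overrides.items():
        if row not in rows:
            raise ModelCompilationError(
                f"override for {target} names nonexistent row {row} "
                f"(inputs {inputs}, arities {arities})"
            )
        if not (0 <= out <= node.max_state):
            raise ModelCompilationError(
                f"override {target}{row} -> {out} outside 0..{node.max_state}"
            )
        rows[row] = out
        overridden.append(row)
    return TransitionTable(target, inputs, rows, frozenset(overridden))


class CompiledModel:
    """Per-node total update functions over the global state tuple.

    Compilation flattens every node's BSTT into an output array indexed
    row-major over its inputs, so the synchronous successor of any global
    state is a handful of table lookups.  ``pins`` replaces the update of
    each pinned node by the constant pinned state (the knockout /
    overexpression semantics); pinned nodes ignore all inputs.
    """

    def __init__(
        self,
        model: ModelSpec,
        tables: Sequence[TransitionTable],
        pins: Mapping[str, int] | None = None,
    ):
        self.model = model
        self.tables = tuple(tables)
        self.pins = dict(pins or {})
        self.radices = model.radices
        self.n_nodes = len(model.nodes)
        self.n_states = model.n_states

        # weights[i] = product of radices after i: mixed-radix, first node
        # most significant, so tuple lexicographic order == index order.
        weights = [1] * self.n_nodes
        for i in range(self.n_nodes - 2, -1, -1):
            weights[i] = weights[i + 1] * self.radices[i + 1]
        self.weights = tuple(weights)

        self._input_pos: list[tuple[int, ...]] = []
        self._input_radices: list[tuple[int, ...]] = []
        self._outputs: list[np.ndarray] = []
        for node, table in zip(model.nodes, self.tables):
            if node.name in self.pins:
                self._input_pos.append(())
                self._input_radices.append(())
                self._outputs.append(np.array([self.pins[node.name]], dtype=np.int64))
                continue
            pos = tuple(model.node_index(i) for i in table.input_order)
            arities = tuple(model.node(i).state_count for i in table.input_order)
            flat = np.empty(int(np.prod(arities)) if arities else 1, dtype=np.int64)
            for k, combo in enumerate(itertools.product(*(range(a) for a in arities))):
                flat[k] = table.rows[combo]
            self._input_pos.append(pos)
            self._input_radices.append(arities)
            self._outputs.append(flat)
        self._succ_array: np.ndarray | None = None

    def table_for(self, name: str) -> TransitionTable:
        return self.tables[self.model.node_index(name)]

    def successor(self, states: Sequence[int]) -> tuple[int, ...]:
        """Synchronous update: every node reads the same current state."""
        states = tuple(states)
        if len(states) != self.n_nodes:
            raise ValueError(f"state has {len(states)} components, model has {self.n_nodes}")
        for s, r in zip(states, self.radices):
            if not (0 <= s < r):
                raise ValueError(f"state component {s} outside radix {r} in {states}")
        nxt = []
        for pos, arities, out in zip(self._input_pos, self._input_radices, self._outputs):
            row = 0
            for p, a in zip(pos, arities):
                row = row * a + states[p]
            nxt.append(int(out[row]))
        return tuple(nxt)

    def successor_array(self) -> np.ndarray:
        """The full successor map as an index array: ``succ[i]`` is the
        mixed-radix index of the successor of state ``i``.  Computed once
        (vectorised) and cached, so exhaustive analysis evaluates each
        state's successor exactly once."""
        if self._succ_array is None:
            n = self.n_states
            idx = np.arange(n, dtype=np.int64)
            digits = [
                (idx // w) % r for w, r in zip(self.weights, self.radices)
            ]
            succ = np.zeros(n, dtype=np.int64)
            for i, (pos, arities, out) in enumerate(
                zip(self._input_pos, self._input_radices, self._outputs)
            ):
                row = np.zeros(n, dtype=np.int64)
                for p, a in zip(pos, arities):
                    row = row * a + digits[p]
                succ += out[row] * self.weights[i]
            self._succ_array = succ
        return self._succ_array


def compile_model(
    model: ModelSpec,
    pins: Mapping[str, int] | None = None,
    max_states: int = DEFAULT_MAX_STATES,
) -> CompiledModel:
    """Validate and compile a model into per-node update functions.

    Raises :class:`ModelValidationError` when validation reports any
    violation, :class:`ModelCompilationError` on bad overrides/edges, and
    ``ValueError`` for out-of-range pins.
    """
    report = validate_model(model, max_states=max_states)
    if not report.ok:
        raise ModelValidationError(report)
    if pins:
        names = set(model.node_names)
        for name, state in pins.items():
            if name not in names:
                raise ValueError(f"pin on unknown node {name!r}")
            if not (0 <= state < model.node(name).state_count):
                raise ValueError(
                    f"pin {name}={state} outside 0..{model.node(name).max_state}"
                )
    tables = [build_bstt(model, n.name) for n in model.nodes]
    return CompiledModel(model, tables, pins=pins)
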