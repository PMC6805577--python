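"""Model documents (JSON), summary tables (CSV) and state graphs (DOT/GraphML).

The on-disk model format is a versioned JSON document.  States are
stored as their labels — human-editable and unambiguous, with the
integer mapping fixed by label order — and node order in the document is
the canonical order used for state tuples and indexing.  Serialisation
is canonical (fixed key order, 2-space indent, trailing newline), so
saving the same model twice yields byte-identical files.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx

from .dynamics import AnalysisResult, StateGraph, index_to_state
from .experiments import Experiment
from .model import (
    CUSTOM,
    DEFAULT_MAX_STATES,
    EdgeSpec,
    ModelSpec,
    ModelValidationError,
    NodeSpec,
    bstt_inputs,
    validate_model,
)

__all__ = [
    "SCHEMA_VERSION",
    "ModelIOError",
    "ModelDocument",
    "model_to_document",
    "document_to_model",
    "save_model",
    "load_model",
    "load_document",
    "export_summary",
    "export_graph",
]

SCHEMA_VERSION = "1.0"


class ModelIOError(Exception):
    """Malformed or schema-violating model document."""


@dataclass
class ModelDocument:
    """A parsed model file: the model, its experiments, and any unknown
    top-level fields (preserved verbatim on round trip)."""

    model: ModelSpec
    experiments: list[Experiment] = field(default_factory=list)
    extras: dict = field(default_factory=dict)


def _node_to_json(node: NodeSpec) -> dict:
    out: dict = {"name": node.name, "states": list(node.state_labels)}
    if node.position is not None:
        out["position"] = list(node.position)
    return out


def _edge_to_json(edge: EdgeSpec, model: ModelSpec) -> dict:
    out: dict = {"source": edge.source, "target": edge.target, "sign": edge.sign}
    if edge.sign == CUSTOM and edge.contribution_table is not None:
        labels = model.node(edge.source).state_labels
        out["contribution"] = {
            label: delta for label, delta in zip(labels, edge.contribution_table)
        }
    return out


def model_to_document(
    model: ModelSpec, experiments: Sequence[Experiment] = ()
) -> dict:
    """Canonical JSON-ready dict for a model and its experiments."""
    overrides_json: dict = {}
    for name in model.node_names:
        rows = model.bstt_overrides.get(name)
        if not rows:
            continue
        inputs = bstt_inputs(model, name)
        input_nodes = [model.node(i) for i in inputs]
        target = model.node(name)
        overrides_json[name] = [
            {
                "when": [n.label_of(s) for n, s in zip(input_nodes, row)],
                "then": target.label_of(out),
            }
            for row, out in sorted(rows.items())
        ]
    doc: dict = {
        "schema_version": SCHEMA_VERSION,
        "model": {
            "name": model.name,
            "nodes": [_node_to_json(n) for n in model.nodes],
            "edges": [_edge_to_json(e, model) for e in model.edges],
        },
    }
    if overrides_json:
        doc["model"]["bstt_overrides"] = overrides_json
    if model.metadata:
        doc["model"]["metadata"] = dict(model.metadata)
    if experiments:
        doc["experiments"] = [
            {
                "name": exp.name,
                "pins": {
                    node: model.node(node).label_of(state) if node in model.node_names else state
                    for node, state in exp.pins.items()
                },
            }
            for exp in experiments
        ]
    return doc


def _require(mapping: Mapping, key: str, where: str):
    if key not in mapping:
        raise ModelIOError(f"{where}: missing required field {key!r}")
    return mapping[key]


def _state_from(node: NodeSpec, value, where: str) -> int:
    """Accept a label or a bare integer for a state value."""
    if isinstance(value, bool):
        raise ModelIOError(f"{where}: state must be a label or integer, got {value!r}")
    if isinstance(value, int):
        if not (0 <= value < node.state_count):
            raise ModelIOError(
                f"{where}: state {value} outside 0..{node.max_state} of node {node.name!r}"
            )
        return value
    try:
        return node.state_of(str(value))
    except KeyError as exc:
        raise ModelIOError(f"{where}: {exc.args[0]}") from None


def document_to_model(doc: Mapping, max_states: int = DEFAULT_MAX_STATES) -> ModelDocument:
    """Parse and validate a model document dict."""
    if not isinstance(doc, Mapping):
        raise ModelIOError("document root must be a JSON object")
    version = _require(doc, "schema_version", "document")
    if str(version).split(".")[0] != SCHEMA_VERSION.split(".")[0]:
        raise ModelIOError(f"unsupported schema_version {version!r} (expected {SCHEMA_VERSION})")
    mdoc = _require(doc, "model", "document")

    nodes = []
    for i, ndoc in enumerate(_require(mdoc, "nodes", "model")):
        name = str(_require(ndoc, "name", f"nodes[{i}]"))
        labels = _require(ndoc, "states", f"node {name!r}")
        if not isinstance(labels, list) or not labels:
            raise ModelIOError(f"node {name!r}: 'states' must be a non-empty list of labels")
        position = tuple(ndoc["position"]) if "position" in ndoc else None
        nodes.append(
            NodeSpec(name, state_count=len(labels), state_labels=tuple(map(str, labels)),
                     position=position)
        )
    by_name = {n.name: n for n in nodes}

    edges = []
    for i, edoc in enumerate(mdoc.get("edges", [])):
        where = f"edges[{i}]"
        source = str(_require(edoc, "source", where))
        target = str(_require(edoc, "target", where))
        sign = str(edoc.get("sign", "activate"))
        table = None
        if "contribution" in edoc:
            src = by_name.get(source)
            if src is None:
                raise ModelIOError(f"{where}: source {source!r} is not a node")
            contrib = edoc["contribution"]
            missing = [l for l in src.state_labels if l not in contrib]
            if missing:
                raise ModelIOError(
                    f"{where}: contribution table missing source states {missing}"
                )
            table = tuple(int(contrib[l]) for l in src.state_labels)
        edges.append(EdgeSpec(source, target, sign, table))

    # overrides need the edge structure to resolve input order
    pre = ModelSpec(
        name=str(mdoc.get("name", "model")),
        nodes=tuple(nodes),
        edges=tuple(edges),
        metadata=dict(mdoc.get("metadata", {})),
    )
    overrides: dict[str, dict[tuple[int, ...], int]] = {}
    for name, rows in mdoc.get("bstt_overrides", {}).items():
        if name not in by_name:
            raise ModelIOError(f"bstt_overrides: unknown node {name!r}")
        inputs = bstt_inputs(pre, name)
        input_nodes = [by_name[i] for i in inputs if i in by_name]
        if len(input_nodes) != len(inputs):
            raise ModelIOError(f"bstt_overrides[{name!r}]: table inputs include unknown nodes")
        target = by_name[name]
        parsed: dict[tuple[int, ...], int] = {}
        for j, row in enumerate(rows):
            where = f"bstt_overrides[{name!r}][{j}]"
            when = _require(row, "when", where)
            if len(when) != len(input_nodes):
                raise ModelIOError(
                    f"{where}: 'when' has {len(when)} entries, table has inputs {inputs}"
                )
            key = tuple(
                _state_from(n, v, where) for n, v in zip(input_nodes, when)
            )
            parsed[key] = _state_from(target, _require(row, "then", where), where)
        overrides[name] = parsed

    model = ModelSpec(
        name=pre.name, nodes=pre.nodes, edges=pre.edges,
        bstt_overrides=overrides, metadata=pre.metadata,
    )
    report = validate_model(model, max_states=max_states)
    if not report.ok:
        raise ModelIOError(f"document fails model validation: "
                           + "; ".join(str(v) for v in report))

    experiments = []
    for i, xdoc in enumerate(doc.get("experiments", [])):
        where = f"experiments[{i}]"
        xname = str(_require(xdoc, "name", where))
        pins = {}
        for node, value in _require(xdoc, "pins", where).items():
            if node not in by_name:
                raise ModelIOError(f"{where}: pin on unknown node {node!r}")
            pins[node] = _state_from(by_name[node], value, f"{where}.pins[{node!r}]")
        experiments.append(Experiment(xname, pins))

    known = {"schema_version", "model", "experiments"}
    extras = {k: v for k, v in doc.items() if k not in known}
    return ModelDocument(model=model, experiments=experiments, extras=extras)


def dumps_model(model: ModelSpec, experiments: Sequence[Experiment] = (),
                extras: Mapping | None = None) -> str:
    doc = model_to_document(model, experiments)
    if extras:
        doc.update(extras)
    return json.dumps(doc, indent=2) + "\n"


def save_model(
    model: ModelSpec,
    path: str | Path,
    experiments: Sequence[Experiment] = (),
    extras: Mapping | None = None,
) -> None:
    Path(path).write_text(dumps_model(model, experiments, extras), encoding="utf-8")


def load_document(path: str | Path, max_states: int = DEFAULT_MAX_STATES) -> ModelDocument:
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ModelIOError(f"{path}: not valid JSON ({exc})") from None
    return document_to_model(doc, max_states=max_states)


def load_model(
    path: str | Path, max_states: int = DEFAULT_MAX_STATES
) -> tuple[ModelSpec, list[Experiment]]:
    """Read a model file; returns the model and its stored experiments."""
    doc = load_document(path, max_states=max_states)
    return doc.model, doc.experiments


# --------------------------------------------------------------------------
# analysis exports


def export_summary(result: AnalysisResult, path: str | Path) -> None:
    """Write the attractor summary table as RFC 4180 CSV (UTF-8).

    One row per attractor state, grouped by attractor; attractors in the
    result's order (descending basin size, ties by smallest state index).
    Columns: attractor id, cycle position and length, each node's state
    label and integer, basin size and basin percentage (one decimal).
    """
    model = result.compiled.model
    header = ["attractor_id", "cycle_position", "cycle_length"]
    for node in model.nodes:
        header += [node.name, f"{node.name}_state"]
    header += ["basin_size", "basin_pct"]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for aid, att in enumerate(result.attractors):
            for pos, states in enumerate(att.cycle_states):
                row: list = [aid, pos, att.period]
                for node, s in zip(model.nodes, states):
                    row += [node.label_of(s), s]
                row += [att.basin_size, f"{att.basin_pct:.1f}"]
                writer.writerow(row)


def _graph_to_networkx(graph: StateGraph) -> nx.DiGraph:
    g = nx.DiGraph()
    for i in graph.node_indices:
        g.add_node(
            i,
            label=graph.state_label(i),
            states=graph.state_text(i),
            attractor=i in graph.attractor_indices,
        )
    g.add_edges_from(graph.edges)
    return g


def export_graph(graph: StateGraph, path: str | Path, format: str = "dot") -> None:
    """Write a state-transition graph as DOT or GraphML.

    Nodes are labelled with their state tuples; states on an attractor
    cycle carry ``attractor=true`` (and doubled borders in DOT) so they
    are visually distinct in any standard viewer.
    """
    if format == "dot":
        lines = ["digraph state_space {", "  rankdir=LR;"]
        for i in graph.node_indices:
            attrs = [f'label="{graph.state_label(i)}"']
            if i in graph.attractor_indices:
                attrs += ["peripheries=2", 'attractor="true"']
            else:
                attrs += ['attractor="false"']
            lines.append(f'  "{i}" [{", ".join(attrs)}];')
        for a, b in graph.edges:
            lines.append(f'  "{a}" -> "{b}";')
        lines.append("}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif format == "graphml":
        nx.write_graphml(_graph_to_networkx(graph), str(path))
    else:
        raise ValueError(f"unknown graph format {format!r} (expected 'dot' or 'graphml')")
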