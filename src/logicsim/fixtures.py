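"""Bundled example models and a seeded random-model generator.

Two small didactic models (a three-node and a 2/3/4-state variant of the
same A -> C <- B motif) are built entirely from additive defaults.  The
15-node floral organ-fate scaffold carries the published node/state
structure of the Arabidopsis flower-development network; its logical
rules belong to a third-party publication and are not redistributed
here — a documented rules-file loader and template writer are provided
so a user can transcribe them and obtain the full dynamic model.

The random generator is for property-based testing: given a seed it is
fully deterministic (NumPy PCG64), and every model it emits validates.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .model import (
    ACTIVATE,
    INHIBIT,
    EdgeSpec,
    ModelSpec,
    NodeSpec,
    bstt_inputs,
)

__all__ = [
    "fig1_model",
    "running_example_model",
    "floral_scaffold",
    "write_floral_rules_template",
    "FloralRulesError",
    "RandomModelConfig",
    "random_model",
]


def fig1_model() -> ModelSpec:
    """Three-node model: A (2 states) activates C, B (2 states) inhibits
    C (3 states).  All tables are additive defaults, so C follows
    ``next = clamp(A - B + C)`` and A, B hold their states."""
    return ModelSpec(
        name="three_node_example",
        nodes=(
            NodeSpec("A", 2),
            NodeSpec("B", 2),
            NodeSpec("C", 3),
        ),
        edges=(
            EdgeSpec("A", "C", ACTIVATE),
            EdgeSpec("B", "C", INHIBIT),
        ),
    )


def running_example_model() -> ModelSpec:
    """Same motif with unequal state counts: A has 2 states, B has 3,
    C has 4; A activates C, B inhibits C."""
    return ModelSpec(
        name="running_example",
        nodes=(
            NodeSpec("A", 2),
            NodeSpec("B", 3),
            NodeSpec("C", 4),
        ),
        edges=(
            EdgeSpec("A", "C", ACTIVATE),
            EdgeSpec("B", "C", INHIBIT),
        ),
    )


# Node/state structure of the 15-node Arabidopsis floral organ
# determination network: 8 binary and 7 ternary nodes, 2^8 * 3^7 =
# 559,872 global states.
_FLORAL_BINARY = ("FT", "EMF1", "SEP", "AP2", "WUS", "UFO", "CLF", "LUG")
_FLORAL_TERNARY = ("LFY", "AP1", "FUL", "TFL1", "AG", "AP3", "PI")


class FloralRulesError(Exception):
    """A floral rules file is inconsistent with the scaffold declarations."""


def floral_scaffold(rules_path: str | Path | None = None) -> ModelSpec:
    """The floral organ-fate network scaffold, optionally with rules.

    Without ``rules_path`` the model has the 15 declared nodes (8 binary,
    7 ternary) and no edges — enough for structural checks such as the
    559,872-state space size.  With ``rules_path``, a JSON transcription
    of the published logical rules (see
    :func:`write_floral_rules_template`) supplies each node's regulators
    and complete transition table, yielding the full dynamic model.
    """
    nodes = tuple(NodeSpec(n, 2, ("Off", "On")) for n in _FLORAL_BINARY) + tuple(
        NodeSpec(n, 3, ("Low", "Medium", "High")) for n in _FLORAL_TERNARY
    )
    scaffold = ModelSpec(name="floral_organ_fate", nodes=nodes)
    if rules_path is None:
        return scaffold
    return _apply_rules(scaffold, Path(rules_path))


def _apply_rules(scaffold: ModelSpec, path: Path) -> ModelSpec:
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FloralRulesError(f"{path}: not valid JSON ({exc})") from None
    rules = doc.get("nodes")
    if not isinstance(rules, dict):
        raise FloralRulesError(f"{path}: expected a top-level 'nodes' object")
    known = set(scaffold.node_names)
    edges: list[EdgeSpec] = []
    overrides: dict[str, dict[tuple[int, ...], int]] = {}
    # first pass: edges, so that bstt input order is defined for all nodes
    for target, rule in rules.items():
        if target not in known:
            raise FloralRulesError(f"rules name unknown node {target!r}")
        for src in rule.get("inputs", []):
            if src not in known:
                raise FloralRulesError(f"node {target!r}: unknown input {src!r}")
            edges.append(EdgeSpec(src, target, ACTIVATE))
    model = ModelSpec(name=scaffold.name, nodes=scaffold.nodes, edges=tuple(edges))
    for target, rule in rules.items():
        inputs = bstt_inputs(model, target)
        arities = tuple(model.node(i).state_count for i in inputs)
        expected = int(np.prod(arities))
        table = rule.get("table", [])
        if len(table) != expected:
            raise FloralRulesError(
                f"node {target!r}: table has {len(table)} entries, "
                f"expected {expected} (inputs {inputs}, self last, row-major)"
            )
        limit = model.node(target).max_state
        rows = {}
        for combo, out in zip(itertools.product(*(range(a) for a in arities)), table):
            if not isinstance(out, int) or not (0 <= out <= limit):
                raise FloralRulesError(
                    f"node {target!r}: output {out!r} outside 0..{limit}"
                )
            rows[combo] = out
        overrides[target] = rows
    return ModelSpec(
        name=model.name, nodes=model.nodes, edges=model.edges, bstt_overrides=overrides
    )


def write_floral_rules_template(path: str | Path) -> None:
    """Write a skeleton rules file for transcribing the published floral
    logical rules.

    For each node, fill ``inputs`` with its regulators (the node itself
    is implicitly the last table input) and ``table`` with the full list
    of next-state outputs in row-major order over inputs + self.
    """
    scaffold = floral_scaffold()
    doc = {
        "_comment": (
            "Transcription template for the floral network logical rules. "
            "For each node list its regulator names under 'inputs' (do not "
            "include the node itself; it is always the implicit last table "
            "column) and give the complete output table under 'table': one "
            "integer next-state per input combination, enumerated row-major "
            "over the inputs in the listed order with the node's own state "
            "varying fastest."
        ),
        "nodes": {
            n.name: {"states": n.state_count, "inputs": [], "table": []}
            for n in scaffold.nodes
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


@dataclass(frozen=True)
class RandomModelConfig:
    """Parameters of the random-model generator.

    ``edge_probability`` is applied independently to every ordered node
    pair (self-edges included); ``inhibitor_fraction`` is the chance an
    edge inhibits rather than activates; ``override_fraction`` randomises
    that share of each node's BSTT rows to arbitrary valid outputs.
    """

    n_nodes: int = 5
    state_count_choices: tuple[int, ...] = (2, 3)
    edge_probability: float = 0.3
    inhibitor_fraction: float = 0.4
    override_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        for p in (self.edge_probability, self.inhibitor_fraction, self.override_fraction):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} outside [0, 1]")
        if any(not (2 <= c <= 5) for c in self.state_count_choices):
            raise ValueError("state_count_choices must lie in 2..5")


def random_model(config: RandomModelConfig) -> ModelSpec:
    """Generate a random valid model, deterministically from the seed."""
    rng = np.random.default_rng(config.seed)
    counts = rng.choice(np.asarray(config.state_count_choices), size=config.n_nodes)
    nodes = tuple(
        NodeSpec(f"X{i}", int(c)) for i, c in enumerate(counts)
    )
    edges = []
    for i in range(config.n_nodes):
        for j in range(config.n_nodes):
            if rng.random() < config.edge_probability:
                sign = INHIBIT if rng.random() < config.inhibitor_fraction else ACTIVATE
                edges.append(EdgeSpec(nodes[i].name, nodes[j].name, sign))
    model = ModelSpec(name=f"random_{config.seed}", nodes=nodes, edges=tuple(edges))
    if config.override_fraction > 0.0:
        overrides: dict[str, dict[tuple[int, ...], int]] = {}
        for node in nodes:
            inputs = bstt_inputs(model, node.name)
            arities = tuple(model.node(i).state_count for i in inputs)
            rows = {}
            for combo in itertools.product(*(range(a) for a in arities)):
                if rng.random() < config.override_fraction:
                    rows[combo] = int(rng.integers(0, node.state_count))
            if rows:
                overrides[node.name] = rows
        model = ModelSpec(
            name=model.name, nodes=nodes, edges=model.edges, bstt_overrides=overrides
        )
    return model
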