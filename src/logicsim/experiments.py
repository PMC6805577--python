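"""In-silico perturbation experiments: knockout, knockdown, overexpression.

An experiment pins one or more nodes to constant states.  A pinned
node's update function is replaced by the constant — the constant-BSTT
semantics — so the perturbed model remains a total deterministic system
and exhaustive analysis returns the *complete* attractor set, steady
states and limit cycles alike.  Pinning at 0 is a loss-of-function
knockout; pinning at a higher state models knockdown-reversal or
overexpression, and the pinned value still propagates to downstream
nodes (edges are made inert by the constant, not deleted).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .model import CompiledModel, ModelSpec, compile_model, DEFAULT_MAX_STATES

__all__ = ["Experiment", "ExperimentError", "knockout", "apply_experiment", "release"]


class ExperimentError(Exception):
    """An experiment refers to unknown nodes or out-of-range states."""


@dataclass(frozen=True)
class Experiment:
    """A named set of nodes pinned to constant states."""

    name: str
    pins: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "pins", {str(k): int(v) for k, v in dict(self.pins).items()})


def knockout(*nodes: str, name: str | None = None) -> Experiment:
    """Loss-of-function experiment: every listed node pinned to state 0."""
    return Experiment(name or "ko_" + "+".join(nodes), {n: 0 for n in nodes})


def validate_experiment(model: ModelSpec, exp: Experiment) -> None:
    names = set(model.node_names)
    for node, state in exp.pins.items():
        if node not in names:
            raise ExperimentError(
                f"experiment {exp.name!r} pins unknown node {node!r}"
            )
        limit = model.node(node).max_state
        if not (0 <= state <= limit):
            raise ExperimentError(
                f"experiment {exp.name!r} pins {node}={state}, outside 0..{limit}"
            )


def apply_experiment(
    model: ModelSpec, exp: Experiment, max_states: int = DEFAULT_MAX_STATES
) -> CompiledModel:
    """Compile the model with each pinned node's update replaced by its
    constant pinned value; unpinned nodes' tables are unchanged.

    An empty experiment compiles to exactly the unperturbed model.
    """
    validate_experiment(model, exp)
    return compile_model(model, pins=exp.pins, max_states=max_states)


def release(exp: Experiment, node: str) -> Experiment:
    """Undo one pin; with no pins left the experiment is the wild type."""
    if node not in exp.pins:
        raise ExperimentError(f"experiment {exp.name!r} does not pin node {node!r}")
    pins = {k: v for k, v in exp.pins.items() if k != node}
    return Experiment(exp.name, pins)
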