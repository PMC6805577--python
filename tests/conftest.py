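import pytest

from logicsim import (
    EdgeSpec,
    ModelSpec,
    NodeSpec,
    compile_model,
    fig1_model,
    save_model,
)


@pytest.fixture
def fig1():
    return fig1_model()


@pytest.fixture
def fig1_compiled(fig1):
    return compile_model(fig1)


@pytest.fixture
def fig1_file(fig1, tmp_path):
    path = tmp_path / "fig1.json"
    save_model(fig1, path)
    return path


@pytest.fixture
def not_cycle_model():
    """Two binary nodes, each the negation of the other: the synchronous
    dynamics has two fixed points and one period-2 cycle."""
    return ModelSpec(
        name="mutual_not",
        nodes=(NodeSpec("A", 2), NodeSpec("B", 2)),
        edges=(EdgeSpec("B", "A"), EdgeSpec("A", "B")),
        bstt_overrides={
            # inputs for A are (B, A); for B are (A, B); output = NOT(other)
            "A": {(b, a): 1 - b for b in range(2) for a in range(2)},
            "B": {(a, b): 1 - a for a in range(2) for b in range(2)},
        },
    )
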