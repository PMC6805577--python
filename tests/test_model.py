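"""Model definition, validation, and transition-table construction."""

import itertools

import pytest

from logicsim import (
    EdgeSpec,
    ModelSpec,
    ModelCompilationError,
    ModelValidationError,
    NodeSpec,
    RandomModelConfig,
    build_bstt,
    clamp,
    compile_model,
    edge_contribution,
    random_model,
    validate_model,
)


def two_nodes(**kwargs):
    return ModelSpec(
        name="m",
        nodes=(NodeSpec("A", 2), NodeSpec("B", 3)),
        **kwargs,
    )


class TestValidation:
    def test_valid_model_has_empty_report(self, fig1):
        assert validate_model(fig1).ok

    def test_duplicate_node_names_reported(self):
        m = ModelSpec("m", nodes=(NodeSpec("A", 2), NodeSpec("A", 2)))
        report = validate_model(m)
        assert any(v.code == "duplicate-node" and v.where == "A" for v in report)

    def test_state_count_cap(self):
        m = ModelSpec("m", nodes=(NodeSpec("A", 6),))
        assert any(v.code == "state-count" for v in validate_model(m))
        # the cap is configuration, not mathematics
        assert validate_model(m, max_states=6).ok
        assert any(v.code == "state-count" for v in validate_model(
            ModelSpec("m", nodes=(NodeSpec("A", 1),))))

    def test_label_arity_and_uniqueness(self):
        bad_arity = ModelSpec("m", nodes=(NodeSpec("A", 3, ("Low", "High")),))
        assert any(v.code == "label-count" for v in validate_model(bad_arity))
        dup = ModelSpec("m", nodes=(NodeSpec("A", 2, ("On", "On")),))
        assert any(v.code == "duplicate-label" for v in validate_model(dup))

    def test_edge_endpoints_must_exist(self):
        m = two_nodes(edges=(EdgeSpec("A", "Z"), EdgeSpec("Q", "B")))
        codes = {v.code for v in validate_model(m)}
        assert {"unknown-target", "unknown-source"} <= codes

    def test_at_most_one_edge_per_ordered_pair(self):
        m = two_nodes(edges=(EdgeSpec("A", "B"), EdgeSpec("A", "B", "inhibit")))
        assert any(v.code == "duplicate-edge" for v in validate_model(m))

    def test_custom_edge_requires_complete_table(self):
        missing = two_nodes(edges=(EdgeSpec("A", "B", "custom"),))
        assert any(v.code == "custom-table-missing" for v in validate_model(missing))
        short = two_nodes(edges=(EdgeSpec("A", "B", "custom", (0,)),))
        assert any(v.code == "custom-table-arity" for v in validate_model(short))
        ok = two_nodes(edges=(EdgeSpec("A", "B", "custom", (0, 2)),))
        assert validate_model(ok).ok

    def test_override_row_and_output_checked(self):
        m = two_nodes(bstt_overrides={"B": {(5,): 0}})
        assert any(v.code == "override-row" for v in validate_model(m))
        m = two_nodes(bstt_overrides={"B": {(1,): 9}})
        assert any(v.code == "override-output" for v in validate_model(m))
        m = two_nodes(bstt_overrides={"Z": {(0,): 0}})
        assert any(v.code == "override-node" for v in validate_model(m))

    def test_compile_raises_on_invalid(self):
        m = ModelSpec("m", nodes=(NodeSpec("A", 6),))
        with pytest.raises(ModelValidationError):
            compile_model(m)


class TestClamp:
    def test_below_range_clamps_to_zero(self):
        assert clamp(-1, 2) == 0

    def test_above_range_clamps_to_max(self):
        assert clamp(3, 2) == 2

    def test_in_range_identity(self):
        assert all(clamp(v, 4) == v for v in range(5))

    def test_degenerate_max_state_rejected(self):
        with pytest.raises(ValueError):
            clamp(0, 0)


class TestEdgeContribution:
    def test_signs(self):
        assert edge_contribution(EdgeSpec("A", "C"), 2) == 2
        assert edge_contribution(EdgeSpec("B", "C", "inhibit"), 1) == -1
        assert edge_contribution(EdgeSpec("A", "C", "custom", (0, 5, 1)), 1) == 5

    def test_zero_source_state_contributes_nothing(self):
        for sign in ("activate", "inhibit"):
            assert edge_contribution(EdgeSpec("A", "C", sign), 0) == 0

    def test_custom_without_entry_is_compilation_error(self):
        with pytest.raises(ModelCompilationError):
            edge_contribution(EdgeSpec("A", "C", "custom", (0,)), 1)


class TestBuildBstt:
    def test_fig1_c_table(self, fig1):
        table = build_bstt(fig1, "C")
        assert table.input_order == ("A", "B", "C")
        assert len(table) == 2 * 2 * 3
        # next C = clamp(A - B + C) on representative rows
        assert table.rows[(1, 0, 1)] == 2
        assert table.rows[(0, 1, 0)] == 0
        # activator and inhibitor at equal state cancel
        for c in range(3):
            assert table.rows[(1, 1, c)] == c
        assert all(0 <= out <= 2 for out in table.rows.values())

    def test_every_default_row_is_clamped_additive(self, fig1):
        table = build_bstt(fig1, "C")
        for (a, b, c), out in table.rows.items():
            assert out == clamp(a - b + c, 2)

    def test_no_incoming_edges_means_identity(self, fig1):
        for name, count in (("A", 2), ("B", 2)):
            table = build_bstt(fig1, name)
            assert table.input_order == (name,)
            assert table.rows == {(s,): s for s in range(count)}

    def test_self_inhibition_drives_to_zero(self):
        m = ModelSpec(
            "m", nodes=(NodeSpec("A", 3),), edges=(EdgeSpec("A", "A", "inhibit"),)
        )
        table = build_bstt(m, "A")
        # the self column serves both the edge and the self term: clamp(c - c)
        assert table.input_order == ("A",)
        assert table.rows == {(c,): 0 for c in range(3)}

    def test_override_changes_exactly_one_row(self, fig1):
        base = build_bstt(fig1, "C")
        m = ModelSpec(
            fig1.name, fig1.nodes, fig1.edges, bstt_overrides={"C": {(0, 0, 0): 2}}
        )
        table = build_bstt(m, "C")
        assert table.overridden_rows == {(0, 0, 0)}
        diff = {k for k in base.rows if base.rows[k] != table.rows[k]}
        assert diff == {(0, 0, 0)}
        # removing the override restores the additive default
        restored = build_bstt(fig1, "C")
        assert restored.rows == base.rows and not restored.overridden_rows

    def test_bad_override_is_compilation_error(self, fig1):
        bad_row = ModelSpec(fig1.name, fig1.nodes, fig1.edges,
                            bstt_overrides={"C": {(0, 0): 1}})
        with pytest.raises(ModelCompilationError):
            build_bstt(bad_row, "C")


class TestCompiledModel:
    def test_fig1_updates(self, fig1_compiled):
        # A and B identity, C additive — hand-evaluated rows
        assert fig1_compiled.successor((1, 0, 0)) == (1, 0, 1)
        assert fig1_compiled.successor((1, 0, 2)) == (1, 0, 2)
        assert fig1_compiled.successor((0, 1, 2)) == (0, 1, 1)

    def test_isolated_node_is_identity(self):
        m = ModelSpec("m", nodes=(NodeSpec("A", 2),))
        c = compile_model(m)
        assert c.successor((0,)) == (0,) and c.successor((1,)) == (1,)

    def test_compilation_is_deterministic(self, fig1):
        a, b = compile_model(fig1), compile_model(fig1)
        for ta, tb in zip(a.tables, b.tables):
            assert ta == tb
        assert (a.successor_array() == b.successor_array()).all()

    def test_invalid_state_rejected(self, fig1_compiled):
        with pytest.raises(ValueError):
            fig1_compiled.successor((0, 0, 3))
        with pytest.raises(ValueError):
            fig1_compiled.successor((0, 0))


@pytest.mark.parametrize("seed", range(8))
def test_default_tables_are_monotone_in_each_input(seed):
    """Without overrides the additive BSTT is non-decreasing in every
    activator input and the self input, non-increasing in every
    inhibitor — checked exhaustively on random wiring."""
    model = random_model(RandomModelConfig(
        n_nodes=4, state_count_choices=(2, 3), edge_probability=0.5,
        inhibitor_fraction=0.5, seed=seed,
    ))
    for node in model.nodes:
        table = build_bstt(model, node.name)
        signs = {}
        for e in model.in_edges(node.name):
            signs[e.source] = 1 if e.sign == "activate" else -1
        for col, input_name in enumerate(table.input_order):
            if input_name == node.name and input_name not in signs:
                direction = 1  # pure self input
            else:
                direction = signs[input_name]
                if input_name == node.name:
                    direction += 1  # self-edge: edge sign plus the +self term
            for row, out in table.rows.items():
                if row[col] + 1 >= model.node(input_name).state_count:
                    continue
                bumped = row[:col] + (row[col] + 1,) + row[col + 1:]
                delta = table.rows[bumped] - out
                if direction > 0:
                    assert delta >= 0
                elif direction < 0:
                    assert delta <= 0
                else:  # self-inhibition cancels the self term exactly
                    assert delta == 0
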