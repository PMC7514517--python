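"""Flow-row algebra, index-moment rows and reindexing schemes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from maxentpop import (
    MacroState,
    OrderingScheme,
    PanelError,
    ProbabilityVector,
    assemble_model,
    build_flow_constraint,
    build_moment_constraints,
    make_ordering,
    solve_maxent,
)
from conftest import make_records

positive_totals = st.lists(
    st.floats(min_value=0.1, max_value=1e6), min_size=3, max_size=12
)


class TestFlowConstraint:
    def test_two_unit_student_arithmetic(self):
        records = make_records(b=[50, 50], u=[3, 1])
        macro = MacroState.from_records(records)
        assert macro.A == pytest.approx(0.04)
        assert macro.u_bar == pytest.approx(2.5)  # (9 + 1) / 4
        row = build_flow_constraint(records, "students", macro)
        np.testing.assert_allclose(row.g, [0.18, 0.02])
        assert row.C == pytest.approx(0.1)
        # the true shares satisfy the restriction
        assert row.g @ np.array([0.5, 0.5]) == pytest.approx(row.C)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(b=positive_totals, u=positive_totals)
    def test_true_shares_satisfy_flow_row_identically(self, b, u):
        n = min(len(b), len(u))
        records = make_records(b=b[:n], u=u[:n])
        macro = MacroState.from_records(records)
        row = build_flow_constraint(records, "students", macro)
        shares = np.array([r.b for r in records]) / macro.B
        lhs = row.g @ shares
        assert lhs == pytest.approx(row.C, rel=1e-12, abs=1e-300)

    @pytest.mark.parametrize("variable, attr", [("electricity", "ce"), ("water", "cw")])
    def test_target_matches_direct_summation_oracle(self, rng, variable, attr):
        b = rng.uniform(1e4, 1e6, size=8)
        records = make_records(
            b=b,
            u=rng.uniform(10, 1e4, size=8),
            ce=rng.uniform(1e6, 1e9, size=8),
            cw=rng.uniform(1e5, 1e8, size=8),
        )
        macro = MacroState.from_records(records)
        row = build_flow_constraint(records, variable, macro)
        totals = np.array([getattr(r, attr) for r in records])
        assert row.C == pytest.approx(float((totals**2).sum() / macro.B), rel=1e-12)

    def test_mixed_years_rejected(self):
        records = make_records(b=[10, 20], u=[1, 2])
        other = make_records(b=[10], u=[1], year=2001)
        macro = MacroState.from_records(records)
        with pytest.raises(PanelError, match="year"):
            build_flow_constraint(records[:1] + other, "students", macro)

    def test_zero_national_total_rejected(self):
        with pytest.raises(PanelError, match="zero"):
            MacroState.from_records(make_records(b=[10, 20], u=[0, 0]))

    def test_self_weighted_mean_dominates_simple_mean(self, rng):
        for _ in range(10):
            records = make_records(
                b=rng.uniform(1, 100, 6), u=rng.uniform(0.1, 50, 6)
            )
            macro = MacroState.from_records(records)
            assert macro.u_bar >= macro.U / 6 - 1e-12
        equal = make_records(b=[10, 20, 30], u=[5, 5, 5])
        macro = MacroState.from_records(equal)
        assert macro.u_bar == pytest.approx(macro.U / 3)


class TestMomentConstraints:
    def test_reference_moment_arithmetic(self):
        p_ref = ProbabilityVector(np.array([0.5, 0.3, 0.2]))
        rows = build_moment_constraints(p_ref, 2)
        assert rows[0].C == pytest.approx(1.7)
        assert rows[1].C == pytest.approx(3.5)
        np.testing.assert_allclose(rows[1].g, [1.0, 4.0, 9.0])

    def test_uniform_first_moment_is_center_index(self):
        rows = build_moment_constraints(ProbabilityVector.uniform(3), 1)
        assert rows[0].C == pytest.approx(2.0)

    @pytest.mark.parametrize("m_max", [0, 3])
    def test_m_max_out_of_range_rejected(self, m_max):
        with pytest.raises(ValueError):
            build_moment_constraints(ProbabilityVector.uniform(3), m_max)

    def test_full_moment_set_reproduces_reference(self, rng):
        p = rng.dirichlet(np.ones(6) * 3)
        p = np.maximum(p, 1e-4)
        p_ref = ProbabilityVector(p / p.sum())
        cs = assemble_model(moment_rows=build_moment_constraints(p_ref, 5))
        sol = solve_maxent(cs)
        np.testing.assert_allclose(sol.p.p, p_ref.p, atol=1e-8)

    def test_targets_lie_strictly_inside_row_range(self, rng):
        p_ref = ProbabilityVector(rng.dirichlet(np.ones(10)))
        for row in build_moment_constraints(p_ref, 6):
            assert row.g.min() < row.C < row.g.max()


class TestOrdering:
    def test_descending_ranks_by_population(self):
        o = make_ordering({"TU1": 10, "TU2": 50, "TU3": 20}, "descending")
        assert o.permutation == {"TU2": 1, "TU3": 2, "TU1": 3}

    def test_bell_puts_largest_at_center(self):
        o = make_ordering({"A": 1, "B": 9, "C": 5}, "bell")
        assert o.permutation["B"] == 2
        o5 = make_ordering({c: 10 - i for i, c in enumerate("abcde")}, "bell")
        # largest at center index 3, then alternately right and left
        assert o5.permutation["a"] == 3
        assert o5.permutation["b"] == 4
        assert o5.permutation["c"] == 2

    def test_ties_break_by_ascending_tu_id(self):
        o = make_ordering({"Z": 5, "A": 5, "M": 5}, "descending")
        assert o.permutation == {"A": 1, "M": 2, "Z": 3}

    def test_original_scheme_uses_code_order(self):
        o = make_ordering({"03": 1, "01": 2, "02": 3}, "original")
        assert o.permutation == {"01": 1, "02": 2, "03": 3}

    @pytest.mark.parametrize("scheme", list(OrderingScheme))
    def test_reapplication_is_idempotent(self, rng, scheme):
        pops = {f"TU{i:02d}": float(v) for i, v in enumerate(rng.uniform(1, 100, 9))}
        first = make_ordering(pops, scheme)
        # populations re-expressed by index, then reordered again
        reordered = {t: pops[t] for t in first.sorted_tu_ids()}
        second = make_ordering(reordered, scheme)
        assert first.permutation == second.permutation


class TestAssembleModel:
    def test_combined_model_row_count(self, realistic_panel):
        year = 2005
        records = realistic_panel.records(year)
        macro = MacroState.from_records(records)
        ordering = make_ordering(realistic_panel.populations(year), "descending")
        flows = [
            build_flow_constraint(records, v, macro, ordering)
            for v in ("students", "electricity", "water")
        ]
        p_ref = realistic_panel.shares(year - 1, ordering)
        moments = build_moment_constraints(p_ref, 10)
        cs = assemble_model(flows, moments)
        assert cs.n_constraints == 13
        assert cs.n_units == 33

    def test_empty_selection_gives_uniform_model(self):
        cs = assemble_model(n_units=5)
        sol = solve_maxent(cs)
        np.testing.assert_allclose(sol.p.p, 0.2)

    def test_row_budget_enforced(self):
        p_ref = ProbabilityVector.uniform(6)
        rows = build_moment_constraints(p_ref, 5)
        with pytest.raises(ValueError):
            assemble_model(moment_rows=rows + rows[:1])
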