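"""Tree equations, constraint maps and parameter expansion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lineup2ht as l
from lineup2ht.model import PARAM_NAMES

unit = st.floats(0.0, 1.0, allow_nan=False)


def branch_products(params, tree, c):
    """Independent oracle: the category masses as explicit branch sums."""
    dP, dA, b, g = params.dP, params.dA, params.b, params.g
    if tree == l.TreeKind.CULPRIT_PRESENT:
        branches = {
            "suspect": [dP, (1 - dP) * b, (1 - dP) * (1 - b) * g * c],
            "filler": [(1 - dP) * (1 - b) * g * (1 - c)],
            "reject": [(1 - dP) * (1 - b) * (1 - g)],
        }
    else:
        branches = {
            "suspect": [(1 - dA) * b, (1 - dA) * (1 - b) * g * c],
            "filler": [(1 - dA) * (1 - b) * g * (1 - c)],
            "reject": [dA, (1 - dA) * (1 - b) * (1 - g)],
        }
    return tuple(sum(branches[k]) for k in ("suspect", "filler", "reject"))


class TestCategoryProbs:
    def test_certain_detection_forces_culprit_identification(self):
        p = l.category_probs(
            l.Params2HT(dP=1, dA=0.2, b=0.5, g=0.9),
            l.TreeKind.CULPRIT_PRESENT,
        )
        assert p == pytest.approx((1.0, 0.0, 0.0), abs=1e-15)

    @pytest.mark.parametrize("tree", list(l.TreeKind))
    def test_no_process_active_yields_rejection(self, tree):
        p = l.category_probs(l.Params2HT(dP=0, dA=0, b=0, g=0), tree)
        assert p == pytest.approx((0.0, 0.0, 1.0), abs=1e-15)

    def test_matches_branch_product_oracle(self):
        params = l.Params2HT(dP=0.0, dA=0.0, b=0.06, g=0.44)
        c = 0.16667
        got = l.category_probs(params, l.TreeKind.CULPRIT_PRESENT, c)
        expected = branch_products(params, l.TreeKind.CULPRIT_PRESENT, c)
        assert got == pytest.approx(expected, abs=1e-15)
        assert got.p_suspect == pytest.approx(0.12893, abs=5e-6)
        assert sum(got) == pytest.approx(1.0, abs=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(dP=unit, dA=unit, b=unit, g=unit,
           c=st.floats(0.01, 0.99), tree=st.sampled_from(list(l.TreeKind)))
    def test_probabilities_valid_and_sum_to_one(self, dP, dA, b, g, c, tree):
        p = l.category_probs(l.Params2HT(dP, dA, b, g), tree, c)
        assert all(0.0 <= x <= 1.0 + 1e-15 for x in p)
        assert sum(p) == pytest.approx(1.0, abs=1e-12)
        assert p == pytest.approx(branch_products(
            l.Params2HT(dP, dA, b, g), tree, c), abs=1e-12)

    def test_grid_sum_and_monotonicity(self):
        grid = np.linspace(0.0, 1.0, 20)
        for tree in l.TreeKind:
            for dP in grid:
                for b in grid[::4]:
                    for g in grid[::4]:
                        p = l.category_probs(
                            l.Params2HT(dP, dP, b, g), tree, 0.16667
                        )
                        assert abs(sum(p) - 1.0) < 1e-12
        # p_suspect (present tree) non-decreasing in dP, b and g
        base = dict(dA=0.3, b=0.2, g=0.4)
        for name in ("dP", "b", "g"):
            values = []
            for v in grid:
                kwargs = {"dP": 0.3, **base, name: v}
                values.append(l.category_probs(
                    l.Params2HT(**kwargs), l.TreeKind.CULPRIT_PRESENT
                ).p_suspect)
            assert np.all(np.diff(values) >= -1e-15)
        # p_reject (absent tree) non-decreasing in dA
        rejects = [
            l.category_probs(
                l.Params2HT(0.3, dA, 0.2, 0.4), l.TreeKind.CULPRIT_ABSENT
            ).p_reject
            for dA in grid
        ]
        assert np.all(np.diff(rejects) >= -1e-15)

    def test_equal_detection_gives_equal_filler_rates(self):
        # filler selection depends only on the non-detection mass
        grid = np.linspace(0.0, 1.0, 20)
        for d in grid:
            for g in grid[::3]:
                params = l.Params2HT(dP=d, dA=d, b=0.1, g=g)
                f_present = l.category_probs(
                    params, l.TreeKind.CULPRIT_PRESENT).p_filler
                f_absent = l.category_probs(
                    params, l.TreeKind.CULPRIT_ABSENT).p_filler
                assert f_present == pytest.approx(f_absent, abs=1e-14)

    @pytest.mark.parametrize("c", [0.0, 1.0, -0.1, 1.5])
    def test_degenerate_guess_split_rejected(self, c):
        with pytest.raises(ValueError, match="guessing split"):
            l.category_probs(
                l.Params2HT(0.5, 0.5, 0.5, 0.5), l.TreeKind.CULPRIT_PRESENT, c
            )

    @pytest.mark.parametrize("field", PARAM_NAMES)
    def test_out_of_range_parameter_names_offender(self, field):
        kwargs = dict(dP=0.5, dA=0.5, b=0.5, g=0.5)
        kwargs[field] = 1.2
        with pytest.raises(ValueError, match=field):
            l.Params2HT(**kwargs)


class TestBuildModel:
    def test_two_condition_base_model_has_six_free_params(self):
        spec = l.build_model(
            ["combined", "separate"], equalities={"b": "all", "dA": "all"}
        )
        assert spec.n_free == 6

    def test_four_condition_base_model_has_ten_free_params(self):
        spec = l.build_model(
            ["a", "b_", "c_", "d_"], equalities={"b": "all", "dA": "all"}
        )
        # 16 slots minus 2 x 3 merged = 10; oracle: count distinct indices
        assert spec.n_free == len(set(spec.constraint_map.values())) == 10

    def test_saturated_single_condition(self):
        spec = l.build_model(["only"])
        assert spec.n_free == 4

    def test_unknown_condition_in_equality_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            l.build_model(["a", "b_"], equalities={"dP": ["a", "nope"]})

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError, match="unknown parameter"):
            l.build_model(["a"], equalities={"zeta": "all"})

    def test_duplicate_condition_names_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            l.build_model(["a", "a"])

    def test_index_assignment_is_deterministic(self):
        spec = l.build_model(
            ["x", "y"], equalities={"b": "all", "dA": "all"}
        )
        # dP first (per condition), then dA shared, b shared, then g
        assert spec.constraint_map[("dP", "x")] == 0
        assert spec.constraint_map[("dP", "y")] == 1
        assert spec.constraint_map[("dA", "x")] == 2
        assert spec.constraint_map[("dA", "y")] == 2
        assert spec.constraint_map[("b", "x")] == 3
        assert spec.constraint_map[("g", "x")] == 4
        assert spec.constraint_map[("g", "y")] == 5


class TestExpand:
    def test_identity_model_pass_through(self):
        spec = l.build_model(["only"])
        params = l.expand([0.3, 0.1, 0.06, 0.44], spec)["only"]
        assert params == l.Params2HT(dP=0.3, dA=0.1, b=0.06, g=0.44)

    def test_shared_slots_receive_identical_values(self):
        spec = l.build_model(
            ["combined", "separate"], equalities={"b": "all", "dA": "all"}
        )
        out = l.expand([0.3, 0.25, 0.05, 0.06, 0.44, 0.42], spec)
        assert out["combined"].b == out["separate"].b == 0.06
        assert out["combined"].dA == out["separate"].dA == 0.05
        assert out["combined"].dP == 0.3
        assert out["separate"].g == 0.42

    def test_fixed_value_wins_over_free_vector(self):
        spec = l.build_model(["only"], fixed_values={"dA": {"only": 0.0}})
        assert spec.n_free == 3
        assert l.expand([0.9, 0.9, 0.9], spec)["only"].dA == 0.0

    def test_length_mismatch_rejected(self):
        spec = l.build_model(["only"])
        with pytest.raises(ValueError, match="length"):
            l.expand([0.1, 0.2], spec)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=6, max_size=6))
    def test_expand_collapse_round_trip(self, vector):
        # collapsing a consistent assignment back onto the same spec is the
        # identity on the free vector
        spec = l.build_model(
            ["combined", "separate"], equalities={"b": "all", "dA": "all"}
        )
        back = l.collapse_onto(vector, spec, spec)
        assert np.allclose(back, vector, atol=1e-12)


class TestWithEquality:
    def test_merging_reduces_free_count_by_group_size_minus_one(self, exp1_spec):
        restricted = l.with_equality(exp1_spec, "dP", ["combined", "separate"])
        assert restricted.n_free == exp1_spec.n_free - 1
        assert (
            restricted.constraint_map[("dP", "combined")]
            == restricted.constraint_map[("dP", "separate")]
        )

    def test_collapse_preserves_untouched_parameters(self, exp1_spec):
        restricted = l.with_equality(exp1_spec, "dP", ["combined", "separate"])
        vector = np.array([0.3, 0.2, 0.05, 0.06, 0.44, 0.42])
        collapsed = l.collapse_onto(vector, exp1_spec, restricted)
        out = l.expand(collapsed, restricted)
        assert out["combined"].dP == pytest.approx(0.25)  # mean of 0.3, 0.2
        assert out["combined"].g == pytest.approx(0.44)
        assert out["separate"].g == pytest.approx(0.42)

    def test_fixed_slot_cannot_join_equality(self):
        spec = l.build_model(
            ["a", "b_"], fixed_values={"dA": {"a": 0.0, "b_": 0.0}}
        )
        with pytest.raises(ValueError, match="fixed"):
            l.with_equality(spec, "dA", ["a", "b_"])


class TestEqnExport:
    def test_branch_sums_match_category_probs(self, exp1_spec):
        text = l.to_eqn(exp1_spec)
        lines = text.strip().splitlines()
        assert int(lines[0]) == len(lines) - 1
        rng = np.random.default_rng(3)
        x = rng.uniform(0.1, 0.9, exp1_spec.n_free)
        env = {f"x{i}": x[i] for i in range(exp1_spec.n_free)}
        sums: dict[tuple[int, int], float] = {}
        for line in lines[1:]:
            tree_no, cat, term = line.split(maxsplit=2)
            sums[(int(tree_no), int(cat))] = sums.get(
                (int(tree_no), int(cat)), 0.0
            ) + eval(term, {"__builtins__": {}}, env)
        params = l.expand(x, exp1_spec)
        tree_no = 0
        for cond in exp1_spec.condition_names:
            for tree in l.TreeKind:
                tree_no += 1
                p = l.category_probs(params[cond], tree, exp1_spec.guess_split_c)
                assert sums[(tree_no, 1)] == pytest.approx(p.p_suspect, abs=1e-9)
                assert sums[(tree_no, 2)] == pytest.approx(p.p_filler, abs=1e-9)
                assert sums[(tree_no, 3)] == pytest.approx(p.p_reject, abs=1e-9)
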