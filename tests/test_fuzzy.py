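"""Unit and property tests for the Mamdani engine."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cervidx as cx
from cervidx.fuzzy import (
    ConfigurationError,
    EngineOptions,
    InputError,
    NoRuleFiredError,
    classify_value,
    defuzzify_centroid,
    model_from_dict,
    model_to_dict,
)

YOUNG = cx.FuzzySet("young", "trapezoid", (10, 15, 18, 22))


class TestMembership:
    @pytest.mark.parametrize(
        "x, expected",
        [
            (16, 1.0),        # plateau
            (9, 0.0),         # outside support
            (20, 0.5),        # falling limb 1 - (20-18)/(22-18)
            (12.5, 0.5),      # rising limb
            (10, 0.0),
            (22, 0.0),
        ],
    )
    def test_trapezoid_piecewise_form(self, x, expected):
        assert cx.membership(YOUNG, x) == pytest.approx(expected)

    def test_degenerate_left_edge_is_vertical(self):
        no = cx.FuzzySet("no", "triangle", (0, 0, 0.5))
        assert cx.membership(no, 0) == 1.0
        assert cx.membership(no, 0.25) == 0.5
        assert cx.membership(no, 0.6) == 0.0

    def test_malformed_breakpoints_rejected(self):
        with pytest.raises(ConfigurationError):
            cx.FuzzySet("bad", "trapezoid", (5, 3, 8, 9))
        with pytest.raises(ConfigurationError):
            cx.FuzzySet("bad", "triangle", (1, 2, 3, 4))

    def test_non_finite_input_rejected(self):
        with pytest.raises(InputError):
            cx.membership(YOUNG, float("nan"))

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(min_value=-50, max_value=150, allow_nan=False))
    def test_degree_always_in_unit_interval(self, x):
        assert 0.0 <= cx.membership(YOUNG, x) <= 1.0


class TestFuzzify:
    def test_partners_at_three(self, risk_model):
        var = risk_model.input_by_name("partners")
        degrees = cx.fuzzify(var, 3)
        assert degrees == {"few": 1.0, "many": 0.0, "unusual": 0.0}

    def test_boolean_variable_at_zero(self, risk_model):
        var = risk_model.input_by_name("std_history")
        assert cx.fuzzify(var, 0) == {"no": 1.0, "yes": 0.0}

    def test_below_universe_clamps(self, risk_model):
        var = risk_model.input_by_name("age")
        assert cx.fuzzify(var, -5) == cx.fuzzify(var, var.universe[0])

    def test_gap_value_snaps_to_nearest_support(self, risk_model):
        # between (0 0 0.5) and (0.51 4 8) sits a transcription gap
        var = risk_model.input_by_name("pregnancies")
        degrees = cx.fuzzify(var, 0.505)
        assert max(degrees.values()) > 0.0


class TestFireRule:
    def test_min_of_antecedent_degrees(self):
        rule = cx.Rule({"a": "x", "b": "y", "c": "z"}, "out")
        degrees = {"a": {"x": 0.2}, "b": {"y": 1.0}, "c": {"z": 0.7}}
        assert cx.fire_rule(rule, degrees) == pytest.approx(0.2)
        assert cx.fire_rule(rule, degrees, and_op="product") == pytest.approx(0.14)

    def test_full_degrees_give_identity(self):
        rule = cx.Rule({"a": "x"}, "out")
        assert cx.fire_rule(rule, {"a": {"x": 1.0}}) == 1.0

    def test_disabled_rule_never_fires(self):
        rule = cx.Rule({"a": "x"}, "out", enabled=False)
        assert cx.fire_rule(rule, {"a": {"x": 1.0}}) == 0.0

    def test_missing_variable_is_input_error(self):
        rule = cx.Rule({"a": "x"}, "out")
        with pytest.raises(InputError):
            cx.fire_rule(rule, {"b": {"x": 1.0}})


def _single_set_variable(fset, universe=(0, 10)):
    return cx.FuzzyVariable("v", universe, (fset,))


class TestCentroid:
    def test_symmetric_triangle_apex(self):
        var = _single_set_variable(cx.FuzzySet("t", "triangle", (2, 5, 8)))
        assert defuzzify_centroid(var, {"t": 1.0}) == pytest.approx(5.0)

    def test_rectangle_midpoint_of_base(self):
        var = _single_set_variable(cx.FuzzySet("r", "trapezoid", (2, 2, 6, 6)))
        assert defuzzify_centroid(var, {"r": 1.0}) == pytest.approx(4.0)

    def test_right_triangle_third_of_base(self):
        # right angle at 0, base 3: centroid one third of the base away
        var = _single_set_variable(cx.FuzzySet("rt", "triangle", (0, 0, 3)))
        assert defuzzify_centroid(var, {"rt": 1.0}) == pytest.approx(1.0)

    def test_no_activation_raises(self):
        var = _single_set_variable(cx.FuzzySet("t", "triangle", (2, 5, 8)))
        with pytest.raises(NoRuleFiredError):
            defuzzify_centroid(var, {"t": 0.0})

    @pytest.mark.parametrize("k", [0.05, 0.3, 0.77, 1.0])
    def test_clipping_level_preserves_symmetric_centroid(self, k):
        # clipping a symmetric set at any level keeps a symmetric surface,
        # so the centroid must not move with the activation
        tri = _single_set_variable(cx.FuzzySet("t", "triangle", (2, 5, 8)))
        rect = _single_set_variable(cx.FuzzySet("r", "trapezoid", (2, 2, 6, 6)))
        assert defuzzify_centroid(tri, {"t": k}) == pytest.approx(5.0)
        assert defuzzify_centroid(rect, {"r": k}) == pytest.approx(4.0)

    def test_sampled_mode_approximates_exact(self, injury_model):
        out = injury_model.output
        acts = {"normal": 0.4, "agc": 0.9}
        exact = defuzzify_centroid(out, acts)
        sampled = defuzzify_centroid(
            out, acts, EngineOptions(defuzz_mode="sampled", resolution=20001)
        )
        assert sampled == pytest.approx(exact, rel=1e-5)

    def test_matches_fine_grid_oracle(self, injury_model):
        """Exact centroid vs brute-force trapezoid integration on 1e5 points."""
        out = injury_model.output
        rng = np.random.default_rng(7)
        grid = np.linspace(*out.universe, 100001)
        for _ in range(30):
            k = int(rng.integers(1, len(out.labels) + 1))
            chosen = rng.choice(list(out.labels), size=k, replace=False)
            acts = {l: float(rng.uniform(0.05, 1.0)) for l in chosen}
            value = defuzzify_centroid(out, acts)
            agg = np.zeros_like(grid)
            for l, a in acts.items():
                np.maximum(agg, np.minimum(a, out.set_by_label(l).membership(grid)), out=agg)
            ref = np.trapezoid(grid * agg, grid) / np.trapezoid(agg, grid)
            assert value == pytest.approx(ref, rel=1e-6)

    def test_inside_convex_hull_of_activated_supports(self, injury_model):
        out = injury_model.output
        rng = np.random.default_rng(11)
        for _ in range(50):
            acts = {
                l: float(rng.uniform(0, 1.0))
                for l in out.labels
                if rng.uniform() < 0.7
            }
            if not any(a > 0 for a in acts.values()):
                continue
            value = defuzzify_centroid(out, acts)
            los = [out.set_by_label(l).support[0] for l, a in acts.items() if a > 0]
            his = [out.set_by_label(l).support[1] for l, a in acts.items() if a > 0]
            assert min(los) <= value <= max(his)


class TestInfer:
    def _toy_model(self):
        return model_from_dict(
            {
                "name": "toy",
                "inputs": [
                    {
                        "name": "x",
                        "universe": [0, 10],
                        "sets": [
                            {"label": "low", "shape": "trapezoid", "params": [0, 0, 3, 5]},
                            {"label": "high", "shape": "trapezoid", "params": [5, 7, 10, 10]},
                        ],
                    }
                ],
                "output": {
                    "name": "y",
                    "universe": [0, 100],
                    "sets": [
                        {"label": "small", "shape": "triangle", "params": [0, 25, 50]},
                        {"label": "big", "shape": "triangle", "params": [50, 75, 100]},
                    ],
                },
                "rules": [
                    {"if": {"x": "low"}, "then": "small"},
                    {"if": {"x": "high"}, "then": "big"},
                ],
            }
        )

    def test_single_rule_reduces_to_clipped_centroid(self):
        model = self._toy_model()
        res = cx.infer(model, {"x": 1.0})
        assert res.value == pytest.approx(
            defuzzify_centroid(model.output, {"small": 1.0})
        )
        assert res.label == "small"

    def test_missing_input_raises(self):
        with pytest.raises(InputError):
            cx.infer(self._toy_model(), {})

    def test_no_rule_fired_propagates_inputs(self):
        model = self._toy_model().replace_rules([])
        with pytest.raises(NoRuleFiredError) as err:
            cx.infer(model, {"x": 1.0})
        assert err.value.inputs == {"x": 1.0}

    def test_deterministic(self):
        model = self._toy_model()
        a = cx.infer(model, {"x": 4.3})
        b = cx.infer(model, {"x": 4.3})
        assert a.value == b.value and a.label == b.label

    def test_tie_breaks_to_more_severe_label(self):
        model = self._toy_model()
        assert classify_value(model.output, 50.0) == "big"


class TestConfigRoundTrip:
    def test_model_dict_round_trip(self, injury_model):
        rebuilt = model_from_dict(model_to_dict(injury_model))
        assert rebuilt.output.labels == injury_model.output.labels
        assert len(rebuilt.rules) == len(injury_model.rules)
        x = {"nucleus_area": 3000, "staining": 65, "eccentricity": 0.6,
             "nucleoli": 0, "risk": 1.0}
        assert cx.infer(rebuilt, x).value == cx.infer(injury_model, x).value
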