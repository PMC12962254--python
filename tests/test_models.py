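import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from genjust.models import (MODELS, STATISTICAL_MODELS, delta_p_star,
                            normalize_to_scale, pooled_prevalence, predict,
                            prediction_table)

GRID = np.linspace(0.05, 0.95, 32)  # 32 x 32 = 1024 prevalence pairs


class TestPooledPrevalence:
    @pytest.mark.parametrize("pt,pr,expected", [
        (0.75, 0.55, 0.65), (0.50, 0.50, 0.50), (0.25, 0.05, 0.15)])
    def test_examples(self, pt, pr, expected):
        assert pooled_prevalence(pt, pr) == pytest.approx(expected)

    def test_weight_bounds(self):
        with pytest.raises(ValueError):
            pooled_prevalence(0.5, 0.5, weight_target=1.0)


class TestPredict:
    @pytest.mark.parametrize("model,pt,pr,vf,expected", [
        ("absolute", 0.75, 0.55, None, 0.75),
        ("subtraction", 0.75, 0.55, None, 0.20),
        ("general_fraction", 0.75, 0.55, None, 0.75 / 0.65),
        ("specific_fraction", 0.25, 0.05, None, 5.0),
        ("vrs_hybrid", 0.75, 0.55, 1.0, 0.20 / 0.45),
        ("vrs_hybrid", 0.75, 0.55, 1.5, 1.5 * 0.20 / 0.45),
    ])
    def test_examples(self, model, pt, pr, vf, expected):
        assert predict(model, pt, pr, value_f=vf) == pytest.approx(expected)

    @pytest.mark.parametrize("p", [0.25, 0.5, 0.8])
    def test_equal_prevalence_identities(self, p):
        assert predict("absolute", p, p) == pytest.approx(p)
        assert predict("subtraction", p, p) == 0.0
        assert predict("general_fraction", p, p) == pytest.approx(1.0)
        assert predict("specific_fraction", p, p) == pytest.approx(1.0)
        assert predict("vrs_hybrid", p, p, value_f=1.0) == 0.0

    @pytest.mark.parametrize("model,pt,pr,msg", [
        ("general_fraction", 0.0, 0.0, "pooled"),
        ("specific_fraction", 0.5, 0.0, "p_referent"),
        ("vrs_hybrid", 0.5, 1.0, "p_referent"),
    ])
    def test_domain_errors_name_the_denominator(self, model, pt, pr, msg):
        with pytest.raises(ZeroDivisionError, match=msg):
            predict(model, pt, pr, value_f=1.5)

    def test_hybrid_requires_value_f(self):
        with pytest.raises(ValueError):
            predict("vrs_hybrid", 0.5, 0.3)


class TestMonotonicity:
    """Raw scores ordered as the underlying probability theory demands."""

    @pytest.mark.parametrize("model", MODELS)
    def test_nondecreasing_in_target_prevalence(self, model):
        vf = 1.5 if model == "vrs_hybrid" else None
        for pr in GRID:
            scores = [predict(model, pt, pr, value_f=vf) for pt in GRID]
            assert np.all(np.diff(scores) >= -1e-12)

    @pytest.mark.parametrize("model", ["subtraction", "general_fraction",
                                       "specific_fraction", "vrs_hybrid"])
    def test_nonincreasing_in_referent_prevalence(self, model):
        vf = 1.5 if model == "vrs_hybrid" else None
        for pt in GRID:
            scores = [predict(model, pt, pr, value_f=vf) for pr in GRID]
            assert np.all(np.diff(scores) <= 1e-12)

    def test_absolute_ignores_referent(self):
        for pt in GRID:
            scores = {predict("absolute", pt, pr) for pr in GRID}
            assert scores == {pt}

    def test_delta_p_star_bounded_by_one(self):
        for pt in GRID:
            for pr in GRID:
                assert delta_p_star(pt, pr) <= 1 + 1e-12
        assert delta_p_star(1.0, 0.4) == pytest.approx(1.0)
        assert all(delta_p_star(pt, 0.4) < 1 for pt in GRID)


class TestNormalization:
    def test_endpoints(self):
        out = normalize_to_scale({"a": 0.0, "b": 1.0})
        assert out == {"a": -3.0, "b": 3.0}

    def test_affine_midpoint(self):
        out = normalize_to_scale({"a": 0.0, "b": 0.5, "c": 1.0})
        assert out["b"] == pytest.approx(0.0)

    def test_idempotent(self):
        raw = np.array([-1.0, 0.3, 2.0, 5.0])
        once = normalize_to_scale(raw)
        twice = normalize_to_scale(once)
        assert np.max(np.abs(once - twice)) < 1e-12

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_scale([2.0, 2.0, 2.0])

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=20).filter(
        lambda v: max(v) > min(v)))
    def test_order_and_ties_preserved(self, values):
        v = np.array(values)
        out = normalize_to_scale(v)
        order = np.argsort(v, kind="stable")
        assert np.all(np.diff(out[order]) >= -1e-9)
        same_in = v[:, None] == v[None, :]
        same_out = np.isclose(out[:, None], out[None, :], atol=1e-9)
        assert np.all(same_out[same_in]), "tied inputs must stay tied"
        assert out.min() == pytest.approx(-3) and out.max() == pytest.approx(3)


class TestPredictionTable:
    def test_statistical_models_ignore_dangerousness(self):
        for model in STATISTICAL_MODELS:
            df = prediction_table(model)
            piv = df.pivot_table(index=["abs_level", "rel_level"],
                                 columns="dangerous", values="normalized")
            assert np.allclose(piv[0], piv[1])

    def test_absolute_model_plateaus(self):
        df = prediction_table("absolute")
        for level, expected in (("low", -3.0), ("intermediate", 0.0),
                                ("high", 3.0)):
            vals = df.loc[df["abs_level"] == level, "normalized"]
            assert np.allclose(vals, expected)

    def test_subtraction_constant_within_relative_level(self):
        df = prediction_table("subtraction")
        for level, expected in (("negative", -3.0), ("equal", 0.0),
                                ("positive", 3.0)):
            vals = df.loc[df["rel_level"] == level, "normalized"]
            assert np.allclose(vals, expected)

    def test_fraction_models_same_order_specific_wider_low_row(self):
        gen = prediction_table("general_fraction")
        spec = prediction_table("specific_fraction")
        key = ["abs_level", "rel_level", "dangerous"]
        g = gen.set_index(key)["normalized"].sort_index()
        s = spec.set_index(key)["normalized"].sort_index()
        # identical rank order of the 18 cells
        assert list(g.rank(method="dense")) == list(s.rank(method="dense"))
        # stronger abs x rel interaction: the low-absolute row dominates the
        # specific-fraction pattern more (other rows are relatively flatter)
        def spread(df, level):
            vals = df.loc[df["abs_level"] == level, "normalized"]
            return vals.max() - vals.min()
        for other in ("intermediate", "high"):
            assert (spread(spec, "low") / spread(spec, other)
                    > spread(gen, "low") / spread(gen, other))

    def test_hybrid_with_unit_value_reduces_to_statistical_term(self):
        hyb = prediction_table("vrs_hybrid", value_f=1.0)
        key = ["abs_level", "rel_level", "dangerous"]
        piv = hyb.pivot_table(index=["abs_level", "rel_level"],
                              columns="dangerous", values="normalized")
        assert np.allclose(piv[0], piv[1])
        # and the raw scores are exactly delta P*
        from genjust.models import delta_p_star
        from genjust.design import nominal_prevalences, Condition
        for _, row in hyb.iterrows():
            c = Condition(row["abs_level"], row["rel_level"],
                          "dangerous" if row["dangerous"] else "non_dangerous")
            assert row["raw"] == pytest.approx(delta_p_star(*nominal_prevalences(c)))

    def test_hybrid_scales_dangerous_cells_before_normalization(self):
        hyb = prediction_table("vrs_hybrid", value_f=1.5)
        piv = hyb.pivot_table(index=["abs_level", "rel_level"],
                              columns="dangerous", values="raw")
        assert np.allclose(piv[1], 1.5 * piv[0])
        assert not np.allclose(
            hyb.pivot_table(index=["abs_level", "rel_level"],
                            columns="dangerous", values="normalized")[0],
            hyb.pivot_table(index=["abs_level", "rel_level"],
                            columns="dangerous", values="normalized")[1])
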