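import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import larvopt as lv
from larvopt.catalog import DesignPoint, design_space
from larvopt.moo import (
    DEFAULT_OBJECTIVES,
    GAConfig,
    ObjectiveSpec,
    dominates,
    enumerate_front,
    ga_front,
    predict_objectives,
    select_recommended_members,
)


class StubModel:
    """Duck-typed surrogate returning a fixed prediction table."""

    def __init__(self, frame: pd.DataFrame):
        self._frame = frame
        self.output_names = list(frame.columns)

    def predict(self, points):
        labels = [p.label() for p in points]
        return self._frame.loc[labels]


def stub_from_values(values: dict[DesignPoint, list[float]], names: list[str]):
    frame = pd.DataFrame(
        {p.label(): v for p, v in values.items()}, index=names
    ).T
    return StubModel(frame)


class TestDominates:
    def test_better_everywhere_dominates(self):
        spec = ObjectiveSpec(names=("a", "b", "c"), senses=(1, 1, -1))
        assert dominates([2, 2, 0], [1, 1, 1], spec)

    def test_equal_vectors_do_not_dominate(self):
        spec = ObjectiveSpec(names=("a", "b"), senses=(1, -1))
        assert not dominates([1, 1], [1, 1], spec)

    def test_tradeoff_blocks_dominance_both_ways(self):
        # better protein, worse ash (both maximized/minimized per direction)
        spec = ObjectiveSpec(names=("protein", "ash"), senses=(1, -1))
        assert not dominates([40, 5], [38, 4], spec)
        assert not dominates([38, 4], [40, 5], spec)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dominates([1, 2], [1, 2, 3], ObjectiveSpec(names=("a",), senses=(1,)))

    @settings(derandomize=True, max_examples=200)
    @given(
        st.lists(st.integers(0, 3), min_size=3, max_size=3),
        st.lists(st.integers(0, 3), min_size=3, max_size=3),
    )
    def test_matches_brute_force_definition(self, a, b):
        """Exhaustive re-check of the dominance definition on small integer
        vectors against an independent loop implementation."""
        spec = ObjectiveSpec(names=("x", "y", "z"), senses=(1, -1, 1))
        s = spec.senses
        geq = all(s[i] * a[i] >= s[i] * b[i] for i in range(3))
        gt = any(s[i] * a[i] > s[i] * b[i] for i in range(3))
        assert dominates(a, b, spec) == (geq and gt)

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0, 10, allow_nan=False), min_size=3, max_size=3),
           st.lists(st.floats(0, 10, allow_nan=False), min_size=3, max_size=3))
    def test_antisymmetry(self, a, b):
        spec = ObjectiveSpec(names=("x", "y", "z"), senses=(1, 1, -1))
        assert not (dominates(a, b, spec) and dominates(b, a, spec))


class TestEnumeration:
    def test_planted_noise_free_pipeline_gives_singleton_front(self):
        planted = DesignPoint("ZM", "mixture", 104)
        cfg = lv.plant_dominant_optimum(
            lv.GenerationConfig(seed=17, noise_sd_fraction=0.0), planted
        )
        mt = lv.aggregate_replicates(lv.generate_dataset(cfg))
        models = [
            lv.train(mt, g, hidden=10, activations=("identity", "identity"),
                     seed=i)[0]
            for i, g in enumerate(lv.GROUPS)
        ]
        front = enumerate_front(models)
        assert front.member_points == {planted}
        assert front.recommended == planted

    def test_identical_candidates_are_both_retained(self):
        pts = design_space()
        values = {p: [1.0, 2.0] for p in pts}  # all predictions identical
        stub = stub_from_values(values, ["a", "b"])
        spec = ObjectiveSpec(names=("a", "b"), senses=(1, 1))
        front = enumerate_front([stub], spec)
        assert len(front.members) == 18  # mutual non-domination keeps ties

    def test_single_objective_front_is_argmax_set(self):
        pts = design_space()
        values = {p: [float(i % 5)] for i, p in enumerate(pts)}
        stub = stub_from_values(values, ["a"])
        spec = ObjectiveSpec(names=("a",), senses=(1,))
        front = enumerate_front([stub], spec)
        best = max(v[0] for v in values.values())
        assert front.member_points == {p for p, v in values.items() if v[0] == best}

    def test_missing_objective_column_rejected(self):
        pts = design_space()
        stub = stub_from_values({p: [1.0] for p in pts}, ["a"])
        spec = ObjectiveSpec(names=("a", "b"), senses=(1, 1))
        with pytest.raises(ValueError, match="b"):
            enumerate_front([stub], spec)

    def test_front_members_not_dominated_by_any_candidate(self, identity_models):
        models = list(identity_models.values())
        front = enumerate_front(models)
        table = predict_objectives(models)
        all_values = table[list(DEFAULT_OBJECTIVES.names)].to_numpy(float)
        for _, member_values in front.members:
            for row in all_values:
                assert not dominates(row, member_values.to_numpy(), DEFAULT_OBJECTIVES)

    def test_direction_sanity_flipping_ash_changes_front(self):
        """On data with a protein/ash trade-off, treating ash as a benefit
        must change the nondominated set."""
        pts = design_space()
        rng = np.random.default_rng(5)
        values = {p: [float(rng.uniform(30, 45)), 0.0] for p in pts}
        for p in values:  # strict trade-off: high protein => high ash
            values[p][1] = values[p][0] / 5.0
        stub = stub_from_values(values, ["protein", "crude_ash"])
        front_min = enumerate_front(
            [stub], ObjectiveSpec(names=("protein", "crude_ash"), senses=(1, -1))
        )
        front_max = enumerate_front(
            [stub], ObjectiveSpec(names=("protein", "crude_ash"), senses=(1, 1))
        )
        assert front_min.member_points == set(pts)  # every point is a trade-off
        assert len(front_max.members) == 1  # one point best in both


class TestGA:
    def test_ga_equals_enumeration_oracle(self, identity_models):
        models = list(identity_models.values())
        oracle = enumerate_front(models).member_points
        for seed in range(5):
            front = ga_front(models, DEFAULT_OBJECTIVES, GAConfig(seed=seed))
            assert front.member_points == oracle

    def test_mutation_stress_still_matches_oracle(self, identity_models):
        models = list(identity_models.values())
        oracle = enumerate_front(models).member_points
        cfg = GAConfig(seed=3, mutation_rate=1.0, generations=30)
        assert ga_front(models, DEFAULT_OBJECTIVES, cfg).member_points == oracle

    def test_seeded_determinism(self, identity_models):
        models = list(identity_models.values())
        a = ga_front(models, DEFAULT_OBJECTIVES, GAConfig(seed=9))
        b = ga_front(models, DEFAULT_OBJECTIVES, GAConfig(seed=9))
        assert a.member_points == b.member_points
        assert a.recommended == b.recommended
        assert a.ga_stats == b.ga_stats

    def test_zero_generations_returns_initial_front(self, identity_models):
        models = list(identity_models.values())
        cfg = GAConfig(seed=1, generations=0, population=6)
        front = ga_front(models, DEFAULT_OBJECTIVES, cfg)
        assert 1 <= len(front.members) <= 6
        # soundness within the evaluated set
        for (p1, v1) in front.members:
            for (p2, v2) in front.members:
                assert not dominates(v2.to_numpy(), v1.to_numpy(), DEFAULT_OBJECTIVES)


class TestRecommendation:
    def test_singleton_front_returns_its_point(self):
        p = DesignPoint("TM", "carrot", 90)
        members = [(p, pd.Series({"a": 1.0}))]
        assert select_recommended_members(members, ObjectiveSpec(("a",), (1,))) == p

    def test_distance_to_ideal_hand_computed(self):
        """A = (1, 0.4), B = (0, 1), both maximized: normalized deficits give
        distance 0.6 for A and 1.0 for B, so A wins."""
        pa, pb = DesignPoint("TM", "carrot", 90), DesignPoint("ZM", "cabbage", 97)
        members = [
            (pa, pd.Series({"x": 1.0, "y": 0.4})),
            (pb, pd.Series({"x": 0.0, "y": 1.0})),
        ]
        spec = ObjectiveSpec(names=("x", "y"), senses=(1, 1))
        assert select_recommended_members(members, spec) == pa

    def test_symmetric_tie_breaks_by_level_order(self):
        """A = (1, 0), B = (0, 1): equal distances and equal best-counts, so
        the documented level order decides (TM before ZM)."""
        pa, pb = DesignPoint("ZM", "carrot", 90), DesignPoint("TM", "carrot", 90)
        members = [
            (pa, pd.Series({"x": 1.0, "y": 0.0})),
            (pb, pd.Series({"x": 0.0, "y": 1.0})),
        ]
        spec = ObjectiveSpec(names=("x", "y"), senses=(1, 1))
        assert select_recommended_members(members, spec) == pb

    def test_empty_front_rejected(self):
        with pytest.raises(ValueError):
            select_recommended_members([], DEFAULT_OBJECTIVES)
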