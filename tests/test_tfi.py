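"""Interaction screening: Hellinger strength, ranking, confounder check."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dpac import (
    CategoricalDistribution,
    DiscreteVariable,
    classify_effect,
    confounder_check,
    generate,
    hellinger,
    preset_beneficial,
    preset_confounded,
    preset_unconfounded,
    rank_interactions,
    tfi_strength,
)
from dpac.errors import BudgetError, SchemaError
from oracles import table_from_counts

MET = DiscreteVariable("metastasis", ("no", "yes"))


def dist(p_adverse: float) -> CategoricalDistribution:
    return CategoricalDistribution(MET, np.array([1 - p_adverse, p_adverse]))


class TestHellinger:
    def test_identical_distributions_have_distance_zero(self):
        assert hellinger(dist(0.05), dist(0.05)) == 0.0

    def test_disjoint_supports_have_distance_one(self):
        assert hellinger(dist(1.0), dist(0.0)) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # (0.01, 0.99) vs (0.5, 0.5): sqrt((0.1-√.5)² + (√.99-√.5)²)/√2
        assert hellinger(dist(0.99), dist(0.5)) == pytest.approx(
            0.47511, abs=5e-6
        )

    def test_mismatched_state_sets_are_schema_error(self):
        other = DiscreteVariable("x", ("lo", "hi"))
        q = CategoricalDistribution(other, np.array([0.5, 0.5]))
        with pytest.raises(SchemaError):
            hellinger(dist(0.5), q)

    @given(
        a=st.lists(st.floats(0.01, 1.0), min_size=3, max_size=3),
        b=st.lists(st.floats(0.01, 1.0), min_size=3, max_size=3),
        c=st.lists(st.floats(0.01, 1.0), min_size=3, max_size=3),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_metric_properties(self, a, b, c):
        v = DiscreteVariable("t", ("x", "y", "z"))
        p, q, r = (
            CategoricalDistribution(v, np.array(w) / np.sum(w))
            for w in (a, b, c)
        )
        d_pq, d_qp = hellinger(p, q), hellinger(q, p)
        assert d_pq == pytest.approx(d_qp)
        assert 0.0 <= d_pq <= 1.0
        assert d_pq <= hellinger(p, r) + hellinger(r, q) + 1e-12


class TestClassifyEffect:
    @pytest.mark.parametrize(
        "p_treated, p_untreated, label",
        [
            (0.01, 0.5, "effective"),     # strongly indicated
            (0.3, 0.02, "deleterious"),   # strongly contraindicated
            (0.05, 0.05, "neutral"),      # no interaction
        ],
    )
    def test_adverse_contrast(self, p_treated, p_untreated, label):
        got = classify_effect(dist(p_treated), dist(p_untreated), "yes")
        assert got == label


def _interaction_table(p_by_cell: dict, n_cell: int = 2000):
    """Table over (feature, treatment, target) hitting exact probabilities."""
    feature = DiscreteVariable("feature", ("neg", "pos"))
    treat = DiscreteVariable("rx", ("no", "yes"))
    variables = [feature, treat, MET]
    counts = {}
    for (f, t), p in p_by_cell.items():
        k = round(p * n_cell)
        counts[(f, t, "yes")] = k
        counts[(f, t, "no")] = n_cell - k
    return table_from_counts(variables, counts)


HERCEPTIN_CELLS = {
    ("pos", "yes"): 0.01, ("pos", "no"): 0.50,
    ("neg", "yes"): 0.30, ("neg", "no"): 0.02,
}
ER_CELLS = {
    ("pos", "yes"): 0.05, ("pos", "no"): 0.05,
    ("neg", "yes"): 0.03, ("neg", "no"): 0.03,
}


class TestStrength:
    def test_effective_and_deleterious_configs_give_min_of_maxima(self):
        table = _interaction_table(HERCEPTIN_CELLS, n_cell=100)
        result = tfi_strength(
            table, "rx", ["feature"], "metastasis", "yes", smoothing=0.0
        )
        assert result.strength == pytest.approx(0.30707, abs=5e-6)
        labels = {c.config[0]: c.label for c in result.per_config}
        assert labels == {"pos": "effective", "neg": "deleterious"}

    def test_identical_arms_give_strength_zero(self):
        table = _interaction_table(ER_CELLS, n_cell=100)
        result = tfi_strength(table, "rx", ["feature"], "metastasis", "yes")
        assert result.strength == 0.0

    def test_effective_everywhere_gives_strength_zero(self):
        cells = {
            ("pos", "yes"): 0.01, ("pos", "no"): 0.50,
            ("neg", "yes"): 0.02, ("neg", "no"): 0.30,
        }
        table = _interaction_table(cells, n_cell=100)
        result = tfi_strength(
            table, "rx", ["feature"], "metastasis", "yes", smoothing=0.0
        )
        assert result.strength == 0.0

    def test_invariant_to_feature_state_relabeling(self):
        table = _interaction_table(HERCEPTIN_CELLS, n_cell=100)
        flipped_var = DiscreteVariable("feature", ("pos", "neg"))
        flipped = table_from_counts(
            [flipped_var, table.variable("rx"), MET],
            {
                (f, t, y): int(
                    ((table.df["feature"] == f) & (table.df["rx"] == t)
                     & (table.df["metastasis"] == y)).sum()
                )
                for f in ("neg", "pos") for t in ("no", "yes")
                for y in ("no", "yes")
            },
        )
        a = tfi_strength(table, "rx", ["feature"], "metastasis", "yes")
        b = tfi_strength(flipped, "rx", ["feature"], "metastasis", "yes")
        assert a.strength == pytest.approx(b.strength)

    def test_sparse_configurations_are_excluded(self):
        cells = dict(HERCEPTIN_CELLS)
        table = _interaction_table(cells, n_cell=100)
        # remove nearly all treated records at feature=neg
        keep = ~((table.df["feature"] == "neg") & (table.df["rx"] == "yes"))
        keep[np.flatnonzero(~keep)[:5]] = True  # leave 5 < min_support
        from dpac import DataTable
        small = DataTable(table.variables, table.df[keep])
        result = tfi_strength(
            small, "rx", ["feature"], "metastasis", "yes", min_support=10
        )
        assert ("neg",) in result.excluded
        assert result.strength == 0.0  # only the effective config remains

    def test_permutation_null_concentrates_near_zero(self):
        config = preset_beneficial(20_000)
        table, _ = generate(config, seed=11)
        rng = np.random.default_rng(11)
        df = table.df.copy()
        df["therapy"] = rng.permutation(df["therapy"].to_numpy())
        from dpac import DataTable
        shuffled = DataTable(table.variables, df)
        null = tfi_strength(
            shuffled, "therapy", ["marker"], "metastasis", "yes"
        )
        signal = tfi_strength(
            table, "therapy", ["marker"], "metastasis", "yes"
        )
        assert null.strength < 0.03 < signal.strength


class TestRanking:
    def test_single_candidate_yields_one_set(self):
        table = _interaction_table(HERCEPTIN_CELLS, n_cell=50)
        ranked = rank_interactions(table, "rx", ["feature"], 1, "metastasis")
        assert len(ranked) == 1

    def test_subset_count_and_per_candidate_consistency(self):
        config = preset_beneficial(2000)
        table, _ = generate(config, seed=4)
        candidates = ["marker", "node_status", "f3"]
        ranked = rank_interactions(
            table, "therapy", candidates, 2, "metastasis"
        )
        assert len(ranked) == 6  # C(3,1) + C(3,2)
        singles = rank_interactions(
            table, "therapy", candidates, 1, "metastasis"
        )
        by_feature = {r.features: r.strength for r in ranked}
        for r in singles:
            assert by_feature[r.features] == pytest.approx(r.strength)

    def test_planted_interaction_ranks_first_among_singletons(self):
        config = preset_beneficial(50_000)
        table, _ = generate(config, seed=12)
        ranked = rank_interactions(
            table, "therapy",
            ["marker", "node_status", "f3", "f4", "f5"], 1, "metastasis",
        )
        assert ranked[0].features == ("marker",)

    def test_combinatorial_cap_raises(self):
        config = preset_beneficial(500)
        table, _ = generate(config, seed=4)
        with pytest.raises(BudgetError):
            rank_interactions(
                table, "therapy", ["marker", "node_status", "f3", "f4", "f5"],
                3, "metastasis", cap=5,
            )


class TestConfounderCheck:
    def test_unconfounded_process_passes(self):
        table, _ = generate(preset_unconfounded(4000), seed=21)
        report = confounder_check(
            table, "therapy", ("modifier",), "metastasis"
        )
        assert report.passed
        assert report.flagged_common_causes == []

    def test_planted_confounder_is_flagged(self):
        table, _ = generate(preset_confounded(4000), seed=21)
        report = confounder_check(
            table, "therapy", ("modifier",), "metastasis"
        )
        assert not report.passed
        assert report.flagged_common_causes == ["burden"]

    def test_conditioning_on_the_confounder_restores_pass(self):
        table, _ = generate(preset_confounded(4000), seed=21)
        report = confounder_check(
            table, "therapy", ("modifier", "burden"), "metastasis"
        )
        assert report.passed
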