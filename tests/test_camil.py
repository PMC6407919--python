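"""Leaky noisy-OR model: closed-form prediction, direct estimation, EM."""

import numpy as np
import pandas as pd
import pytest

from dpac import (
    CamilModel,
    DataTable,
    DiscreteVariable,
    HiddenGroup,
    OrdinalCamil,
    OrdinalGroup,
    em_fit,
    estimate_q_direct,
    generate,
    preset_beneficial,
)
from dpac.errors import SchemaError
from oracles import enumerate_camil_adverse, enumerate_ordinal

MET = DiscreteVariable("metastasis", ("no", "yes"))


def binary_model(qs: list[float], leak: float = 1.0) -> CamilModel:
    """One binary cause per group; q applies when the cause is present."""
    causes = [DiscreteVariable(f"c{i}", ("no", "yes")) for i in range(len(qs))]
    groups = [
        HiddenGroup((c.name,), np.array([1.0, q])) for c, q in zip(causes, qs)
    ]
    return CamilModel(causes, groups, leak, MET, "yes")


def random_model(rng: np.random.Generator, n_groups: int) -> CamilModel:
    causes, groups = [], []
    for i in range(n_groups):
        size = int(rng.integers(1, 3))
        parents = []
        for j in range(size):
            v = DiscreteVariable(
                f"g{i}p{j}", tuple(f"s{k}" for k in range(int(rng.integers(2, 4))))
            )
            causes.append(v)
            parents.append(v.name)
        n_cfg = int(np.prod([len(v.states) for v in causes[-size:]]))
        groups.append(HiddenGroup(tuple(parents), rng.uniform(0.3, 1.0, n_cfg)))
    return CamilModel(causes, groups, float(rng.uniform(0.8, 1.0)), MET, "yes")


class TestPredictAdverse:
    def test_all_baseline_reduces_to_the_leak(self):
        model = binary_model([0.7, 0.9], leak=0.95)
        record = {"c0": "no", "c1": "no"}
        assert model.predict_adverse(record) == pytest.approx(0.05)

    def test_product_of_active_inhibitions(self):
        model = binary_model([0.9, 0.8], leak=1.0)
        record = {"c0": "yes", "c1": "yes"}
        assert model.predict_adverse(record) == pytest.approx(0.28)

    @pytest.mark.parametrize("seed", range(6))
    def test_equals_hidden_layer_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        model = random_model(rng, n_groups=int(rng.integers(1, 6)))
        record = {
            v.name: v.states[rng.integers(v.n_states)] for v in model.causes
        }
        assert model.predict_adverse(record) == pytest.approx(
            enumerate_camil_adverse(model, record), abs=1e-12
        )

    def test_monotone_in_inhibition_parameters(self):
        model = binary_model([0.6, 0.7], leak=0.9)
        record = {"c0": "yes", "c1": "yes"}
        base = model.predict_adverse(record)
        stronger = binary_model([0.8, 0.7], leak=0.9)
        assert stronger.predict_adverse(record) < base
        leakier = binary_model([0.6, 0.7], leak=0.8)
        assert leakier.predict_adverse(record) > base

    def test_certain_inhibition_gives_zero_adverse(self):
        model = binary_model([0.5], leak=1.0)
        assert model.predict_adverse({"c0": "no"}) == 0.0

    def test_missing_cause_is_schema_error(self):
        model = binary_model([0.5])
        with pytest.raises(SchemaError):
            model.predict_adverse({})


def _data_from_codes(model, cause_rows, target_row):
    names = [v.name for v in model.causes]
    df = pd.DataFrame(
        [
            {**{n: model.cause(n).states[c] for n, c in zip(names, row)},
             "metastasis": MET.states[t]}
            for row, t in zip(cause_rows, target_row)
        ]
    )
    return DataTable(model.causes + [MET], df)


class TestDirectEstimation:
    def test_fraction_of_good_outcomes_among_qualifying_records(self):
        model = binary_model([0.5, 0.5])
        rows = [(1, 0)] * 10 + [(0, 1)] * 4 + [(1, 1)] * 3
        target = [0] * 9 + [1] + [0] * 4 + [0] * 3
        data = _data_from_codes(model, rows, target)
        q, defined = estimate_q_direct(data, model, 0)
        assert defined[1]
        assert q[1] == pytest.approx(0.9)

    def test_no_qualifying_records_is_flagged_undefined(self):
        model = binary_model([0.5, 0.5])
        data = _data_from_codes(model, [(0, 1), (1, 1)], [0, 1])
        q, defined = estimate_q_direct(data, model, 0)
        assert not defined[1]

    @pytest.mark.parametrize("seed", range(3))
    def test_agrees_with_record_filter_oracle(self, seed):
        rng = np.random.default_rng(seed)
        model = binary_model([0.5, 0.5, 0.5])
        rows = rng.integers(0, 2, size=(200, 3))
        target = rng.integers(0, 2, size=200)
        data = _data_from_codes(model, rows, target)
        for gi in range(3):
            q, defined = estimate_q_direct(data, model, gi)
            others = [j for j in range(3) if j != gi]
            sel = (rows[:, gi] == 1) & (rows[:, others] == 0).all(axis=1)
            if sel.sum() == 0:
                assert not defined[1]
            else:
                expect = (target[sel] == 0).sum() / sel.sum()
                assert q[1] == pytest.approx(expect)


class TestEmFit:
    def test_recovers_planted_parameters(self):
        config = preset_beneficial(20_000)
        table, info = generate(config, seed=31)
        truth = info["truth"]
        result = em_fit(truth.copy(), table, seed=0)
        for fitted, planted in zip(result.model.groups, truth.groups):
            assert np.allclose(fitted.q, planted.q, atol=0.03)
        assert result.model.leak_q == pytest.approx(truth.leak_q, abs=0.03)

    def test_loglik_trace_is_monotone_nondecreasing(self):
        table, info = generate(preset_beneficial(3000), seed=32)
        result = em_fit(info["truth"].copy(), table, seed=0)
        diffs = np.diff(result.loglik_trace)
        assert (diffs >= -1e-9).all()

    def test_fixed_point_matches_direct_estimate_when_fully_identifying(self):
        # single group; baseline records all non-adverse so the leak is inert
        model = binary_model([0.5])
        rows = [(0,)] * 50 + [(1,)] * 40
        target = [0] * 50 + [0] * 30 + [1] * 10
        data = _data_from_codes(model, rows, target)
        direct, _ = estimate_q_direct(data, model, 0)
        result = em_fit(model, data, tol=1e-14, max_iter=2000)
        assert result.model.groups[0].q[1] == pytest.approx(
            direct[1], abs=1e-6
        )

    def test_single_cycle_is_reproducible(self):
        table, info = generate(preset_beneficial(2000), seed=33)
        a = em_fit(info["truth"].copy(), table, tol=0.0, max_iter=1, seed=5)
        b = em_fit(info["truth"].copy(), table, tol=0.0, max_iter=1, seed=5)
        assert a.n_iter == 1 and not a.converged
        for ga, gb in zip(a.model.groups, b.model.groups):
            assert np.array_equal(ga.q, gb.q)
        assert a.model.leak_q == b.model.leak_q

    def test_beats_leak_only_baseline_on_held_out_data(self):
        config = preset_beneficial(8000)
        train, info = generate(config, seed=34)
        held, _ = generate(config, seed=35)
        fitted = em_fit(info["truth"].copy(), train, seed=0).model

        def loglik(model, data):
            names = [v.name for v in model.causes]
            total = 0.0
            for i in range(data.n_records):
                rec = data.record(i)
                p = model.predict_adverse({n: rec[n] for n in names})
                total += np.log(p if rec["metastasis"] == "yes" else 1 - p)
            return total

        baseline = fitted.copy()
        for g in baseline.groups:
            g.q = np.ones_like(g.q)
        adverse_rate = (train.df["metastasis"] == "yes").mean()
        baseline.leak_q = 1.0 - adverse_rate
        assert loglik(fitted, held) > loglik(baseline, held)


def ordinal_3level(rng=None) -> OrdinalCamil:
    target = DiscreteVariable("severity", ("low", "medium", "high"))
    c1 = DiscreteVariable("c1", ("no", "yes"))
    c2 = DiscreteVariable("c2", ("a", "b", "c"))
    c3 = DiscreteVariable("c3", ("no", "yes"))
    if rng is None:
        lp = lambda rows: np.asarray(rows, float)
        groups = [
            OrdinalGroup(("c1",), lp([[1.0, 0.0, 0.0], [0.5, 0.3, 0.2]])),
            OrdinalGroup(("c2",), lp([[1, 0, 0], [0.6, 0.3, 0.1], [0.2, 0.3, 0.5]])),
            OrdinalGroup(("c3",), lp([[1, 0, 0], [0.7, 0.2, 0.1]])),
        ]
        leak = [0.9, 0.07, 0.03]
    else:
        def rand_rows(n):
            return rng.dirichlet(np.ones(3), size=n)
        groups = [
            OrdinalGroup(("c1",), rand_rows(2)),
            OrdinalGroup(("c2",), rand_rows(3)),
            OrdinalGroup(("c3",), rand_rows(2)),
        ]
        leak = rng.dirichlet(np.ones(3))
    return OrdinalCamil([c1, c2, c3], groups, leak, target)


class TestOrdinal:
    def test_degenerate_groups_pin_the_lowest_level(self):
        model = ordinal_3level()
        for g in model.groups:
            g.level_probs = np.zeros_like(g.level_probs)
            g.level_probs[:, 0] = 1.0
        model.leak_probs = np.array([1.0, 0.0, 0.0])
        dist = model.predict({"c1": "no", "c2": "a", "c3": "no"})
        assert dist["low"] == pytest.approx(1.0)

    def test_two_levels_reduce_to_the_binary_model(self):
        binary = binary_model([0.8, 0.6], leak=0.9)
        target = DiscreteVariable("metastasis", ("no", "yes"))
        groups = [
            OrdinalGroup((g.parents[0],), np.column_stack([g.q, 1 - g.q]))
            for g in binary.groups
        ]
        ordinal = OrdinalCamil(
            binary.causes, groups, [0.9, 0.1], target
        )
        record = {"c0": "yes", "c1": "yes"}
        assert ordinal.predict(record)["yes"] == pytest.approx(
            binary.predict_adverse(record), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(4))
    def test_equals_hidden_level_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        model = ordinal_3level(rng)
        record = {
            v.name: v.states[rng.integers(v.n_states)] for v in model.causes
        }
        got = model.predict(record).probabilities
        assert np.allclose(got, enumerate_ordinal(model, record), atol=1e-12)


class TestSerialization:
    def test_yaml_round_trip_is_bit_exact(self, tmp_path):
        rng = np.random.default_rng(3)
        model = random_model(rng, 3)
        path = tmp_path / "model.yaml"
        model.to_yaml(path)
        loaded = CamilModel.from_yaml(path)
        assert loaded.leak_q == model.leak_q
        for a, b in zip(loaded.groups, model.groups):
            assert a.parents == b.parents
            assert np.array_equal(a.q, b.q)
        assert loaded.adverse_state == model.adverse_state
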