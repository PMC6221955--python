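import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emobio.wisard import (
    WisardClassifier,
    WisardModel,
    classify,
    fit_encoder,
    make_model,
    responses_at,
    train,
)


class TestEncoder:
    def test_thermometer_midpoint(self):
        enc = fit_encoder(np.array([[0.0], [1.0]]), bits=4)
        np.testing.assert_array_equal(enc.encode([[0.5]])[0], [1, 1, 0, 0])

    def test_clipping_below_and_above(self):
        enc = fit_encoder(np.array([[0.0], [1.0]]), bits=4)
        np.testing.assert_array_equal(enc.encode([[-5.0]])[0], [0, 0, 0, 0])
        np.testing.assert_array_equal(enc.encode([[99.0]])[0], [1, 1, 1, 1])

    def test_monotone_popcount(self):
        enc = fit_encoder(np.array([[0.0], [1.0]]), bits=16)
        vals = np.linspace(-0.5, 1.5, 41)
        pops = [enc.encode([[v]])[0].sum() for v in vals]
        assert all(a <= b for a, b in zip(pops, pops[1:]))

    @settings(max_examples=30, deadline=None)
    @given(
        v1=st.floats(-10, 10),
        v2=st.floats(-10, 10),
        bits=st.integers(2, 32),
    )
    def test_monotone_property(self, v1, v2, bits):
        enc = fit_encoder(np.array([[-1.0], [1.0]]), bits=bits)
        lo, hi = sorted([v1, v2])
        assert enc.encode([[lo]])[0].sum() <= enc.encode([[hi]])[0].sum()

    def test_constant_feature_warns_all_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            enc = fit_encoder(np.array([[2.0, 0.0], [2.0, 1.0]]), bits=4)
        assert enc.encode([[2.0, 0.5]])[0][:4].sum() == 0

    def test_min_max_from_training_only(self):
        enc = fit_encoder(np.array([[0.0], [2.0]]), bits=4)
        assert enc.mins[0] == 0.0 and enc.maxs[0] == 2.0

    def test_too_few_rows(self):
        with pytest.raises(ValueError, match="2 training rows"):
            fit_encoder(np.array([[1.0]]), bits=4)


class TestTrain:
    def test_single_example_counters(self):
        model = make_model(n_bits=8, n_tuple=4, seed=0)
        vec = np.array([1, 0, 1, 1, 0, 0, 1, 0], dtype=np.uint8)
        train(model, [vec], ["A"])
        assert set(model.discriminators) == {"A"}
        for ram, addr in zip(model.discriminators["A"], model._addresses(vec)):
            assert ram == {int(addr): 1}

    def test_double_training_doubles_counters(self):
        model = make_model(n_bits=8, n_tuple=4, seed=0)
        vec = np.ones(8, dtype=np.uint8)
        train(model, [vec, vec], ["A", "A"])
        for ram in model.discriminators["A"]:
            assert sum(ram.values()) == 2

    def test_counter_mass_conservation(self):
        rng = np.random.default_rng(0)
        model = make_model(n_bits=24, n_tuple=4, seed=1)
        X = (rng.random((10, 24)) > 0.5).astype(np.uint8)
        y = ["A"] * 6 + ["B"] * 4
        train(model, X, y)
        for label, n in (("A", 6), ("B", 4)):
            total = sum(sum(r.values()) for r in model.discriminators[label])
            assert total == n * model.n_tuples

    def test_length_mismatch(self):
        model = make_model(n_bits=8, n_tuple=4, seed=0)
        with pytest.raises(ValueError, match="expected 8 bits"):
            train(model, [np.ones(6, dtype=np.uint8)], ["A"])

    def test_mapping_is_permutation(self):
        model = make_model(n_bits=10, n_tuple=4, seed=3)
        assert len(model.mapping) == 12  # padded to a multiple of n_tuple
        assert sorted(model.mapping.tolist()) == list(range(12))


class TestClassify:
    def test_perfect_match_full_response(self):
        model = make_model(n_bits=8, n_tuple=4, seed=0)
        vec = np.array([1, 0, 1, 1, 0, 0, 1, 0], dtype=np.uint8)
        train(model, [vec], ["A"])
        label, resp, b = classify(model, vec)
        assert label == "A"
        assert resp["A"] == model.n_tuples
        assert b == 1

    def test_complementary_constant_vectors(self):
        model = make_model(n_bits=8, n_tuple=4, seed=0)
        a = np.ones(8, dtype=np.uint8)
        b = np.zeros(8, dtype=np.uint8)
        train(model, [a, b], ["A", "B"])
        assert classify(model, a)[0] == "A"
        assert classify(model, b)[0] == "B"

    def test_bleaching_resolves_tie_toward_double_trained(self):
        # both classes see the same vector once; A sees it a second time.
        # At b=1 the responses tie; bleaching to b=2 lets A win.
        model = make_model(n_bits=8, n_tuple=4, seed=0)
        vec = np.array([1, 1, 0, 0, 1, 0, 1, 0], dtype=np.uint8)
        train(model, [vec, vec, vec], ["A", "B", "A"])
        label, resp, b = classify(model, vec)
        assert label == "A"
        assert b == 2
        # exhaustive enumeration oracle on the 8-bit toy: expected responses
        # at each bleaching level derived from raw counters
        for level in (1, 2, 3):
            exp = {}
            for cls, rams in model.discriminators.items():
                addrs = model._addresses(vec)
                exp[cls] = sum(
                    ram.get(int(a), 0) >= level for ram, a in zip(rams, addrs)
                )
            assert responses_at(model, vec, level) == exp
        assert responses_at(model, vec, 2) == {"A": model.n_tuples, "B": 0}

    def test_persistent_tie_falls_back_to_lexicographic(self):
        model = make_model(n_bits=8, n_tuple=4, seed=0)
        vec = np.ones(8, dtype=np.uint8)
        train(model, [vec, vec], ["B", "A"])  # symmetric by construction
        label, _, _ = classify(model, vec)
        assert label == "A"

    def test_response_monotonic_in_bleaching(self):
        rng = np.random.default_rng(1)
        model = make_model(n_bits=32, n_tuple=4, seed=2)
        X = (rng.random((12, 32)) > 0.5).astype(np.uint8)
        train(model, X, ["A", "B"] * 6)
        probe = (rng.random(32) > 0.5).astype(np.uint8)
        prev = responses_at(model, probe, 1)
        for b in range(2, 6):
            cur = responses_at(model, probe, b)
            for cls in prev:
                assert cur[cls] <= prev[cls]
            prev = cur

    def test_untrained_raises(self):
        model = make_model(n_bits=8, n_tuple=4, seed=0)
        with pytest.raises(ValueError, match="no trained"):
            classify(model, np.zeros(8, dtype=np.uint8))


class TestWisardClassifier:
    def test_one_hot_training_accuracy_100(self):
        X = np.eye(6)
        y = [f"c{i % 3}" for i in range(6)]
        clf = WisardClassifier(bits_per_feature=8, n_tuple=4, seed=0)
        clf.fit(X, y)
        assert clf.score(X, y) == 1.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((12, 5))
        y = ["A", "B"] * 6
        p1 = WisardClassifier(seed=7).fit(X, y).predict(X)
        p2 = WisardClassifier(seed=7).fit(X, y).predict(X)
        np.testing.assert_array_equal(p1, p2)

    def test_separable_clusters(self):
        rng = np.random.default_rng(3)
        Xa = rng.normal(0.0, 0.1, size=(10, 4))
        Xb = rng.normal(5.0, 0.1, size=(10, 4))
        X = np.vstack([Xa, Xb])
        y = ["A"] * 10 + ["B"] * 10
        clf = WisardClassifier(seed=0).fit(X, y)
        assert clf.score(X, y) == 1.0
        assert (clf.predict(rng.normal(5.0, 0.1, size=(3, 4))) == "B").all()

    def test_unfitted_predict_raises(self):
        with pytest.raises(ValueError, match="not fitted"):
            WisardClassifier().predict(np.zeros((1, 3)))


def test_model_json_round_trip(tmp_path):
    rng = np.random.default_rng(4)
    model = make_model(n_bits=16, n_tuple=4, seed=5)
    X = (rng.random((6, 16)) > 0.5).astype(np.uint8)
    train(model, X, ["A", "B"] * 3)
    p = tmp_path / "model.json"
    model.to_json(p)
    back = WisardModel.from_json(p)
    assert back.n_tuple == model.n_tuple
    np.testing.assert_array_equal(back.mapping, model.mapping)
    assert back.discriminators == model.discriminators
    probe = (rng.random(16) > 0.5).astype(np.uint8)
    assert classify(back, probe) == classify(model, probe)
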