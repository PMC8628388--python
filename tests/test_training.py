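import numpy as np
import pytest
from scipy import stats as st

from pathsem.kg_core import KnowledgeGraph, Triple
from pathsem.models import ModelConfig, ModelParams, PathScorer, PRAFeatureIndex, PRAModel
from pathsem.path_sampler import Path, QueryInstance
from pathsem.training import (CorruptionStats, LabeledSets, TrainConfig,
                              corrupt_triple, grid_search, make_negatives,
                              nll_loss, train_model)


@pytest.fixture
def corruption_kg():
    triples = []
    for i in range(20):
        triples.append(Triple(f"h{i}", "rq", f"t{i % 7}"))
    for i in range(30):
        triples.append(Triple(f"x{i}", "other", f"y{i % 11}"))
    return KnowledgeGraph(triples)


class TestCorruptTriple:
    def test_output_never_equals_input(self, corruption_kg):
        rng = np.random.default_rng(0)
        t = Triple("h0", "rq", "t0")
        for slot in ("head", "tail", "relation"):
            for _ in range(50):
                new = corrupt_triple(t, corruption_kg, slot, rng)
                assert new != t

    def test_only_chosen_slot_changes(self, corruption_kg):
        rng = np.random.default_rng(1)
        t = Triple("h0", "rq", "t0")
        for _ in range(30):
            new = corrupt_triple(t, corruption_kg, "tail", rng)
            assert new.head == t.head and new.relation == t.relation
            assert new.tail != t.tail

    def test_negatives_filtered_against_graph(self, corruption_kg):
        rng = np.random.default_rng(2)
        t = Triple("h0", "rq", "t0")
        for _ in range(200):
            new = corrupt_triple(t, corruption_kg, "tail", rng)
            assert not corruption_kg.has_triple(new)

    def test_same_relation_bias_within_binomial_ci(self, corruption_kg):
        """10,000 draws: same-pool fraction inside the 99% CI around 0.7."""
        rng = np.random.default_rng(3)
        stats = CorruptionStats()
        t = Triple("h0", "rq", "t0")
        n = 10_000
        for i in range(n):
            slot = "head" if i % 2 else "tail"
            corrupt_triple(t, corruption_kg, slot, rng,
                           same_relation_prob=0.7, stats=stats)
        draws = stats.n_entity_draws
        lo, hi = st.binom.ppf([0.005, 0.995], draws, 0.7) / draws
        assert lo <= stats.same_pool_fraction <= hi

    def test_degenerate_pool_falls_back_uniform(self):
        # rq has a single head participant: pool minus original is empty
        kg = KnowledgeGraph([Triple("h0", "rq", "t0"),
                             Triple("a", "other", "b"),
                             Triple("c", "other", "d")])
        rng = np.random.default_rng(4)
        stats = CorruptionStats()
        for _ in range(50):
            corrupt_triple(Triple("h0", "rq", "t0"), kg, "head", rng,
                           stats=stats)
        # every draw decision (including rejected candidates) fell back
        assert stats.n_fallback == stats.n_entity_draws >= 50

    def test_invalid_slot(self, corruption_kg):
        with pytest.raises(ValueError):
            corrupt_triple(Triple("h0", "rq", "t0"), corruption_kg, "middle",
                           np.random.default_rng(0))

    def test_make_negatives_never_positive(self, corruption_kg):
        rng = np.random.default_rng(5)
        positives = sorted(corruption_kg.triples)
        negatives = make_negatives(corruption_kg, positives, rng,
                                   neg_ratio=4.0)
        assert len(negatives) > 100
        for n in negatives:
            assert n not in corruption_kg.triples


class TestNllLoss:
    def test_single_positive_half_is_ln2(self):
        assert nll_loss([0.5], [1]) == pytest.approx(np.log(2))

    def test_confident_correct_approaches_zero(self):
        assert nll_loss([1.0 - 1e-13, 1e-13], [1, 0]) < 1e-9

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(0.01, 0.99, size=16)
            y = (rng.random(16) < 0.5).astype(int)
            expected = 0.0
            for pi, yi in zip(p, y):
                expected += -np.log(pi) if yi else -np.log(1 - pi)
            assert nll_loss(p, y) == pytest.approx(expected, abs=1e-9)

    def test_l2_term_uses_weight_matrices(self):
        config = ModelConfig(d=2, k=2, H=2)
        params = ModelParams.initialize(config, ["r"], ["t"], ["r"], seed=0)
        lam = 0.1
        base = nll_loss([0.5], [1])
        full = nll_loss([0.5], [1], params=params, l2_lambda=lam)
        expected_penalty = lam * sum(
            float(np.sum(params.arrays[n] ** 2))
            for n in ("W1", "W2", "W3", "T", "P_ent", "P_path"))
        assert full - base == pytest.approx(expected_penalty)

    def test_clamps_degenerate_scores(self):
        assert np.isfinite(nll_loss([0.0, 1.0], [1, 0]))


def separable_sets(n=40):
    """One path type perfectly predicts the label."""
    kg = KnowledgeGraph([Triple("A", "good", "B"), Triple("A", "bad", "B"),
                         Triple("A", "rq", "B")])
    good = Path("A", "B", (("good", "B"),))
    bad = Path("A", "B", (("bad", "B"),))
    pos = [QueryInstance(f"p{i}", "rq", "B", 1, paths=[good]) for i in range(n)]
    neg = [QueryInstance(f"n{i}", "rq", "B", 0, paths=[bad]) for i in range(n)]
    train = LabeledSets(pos[: n // 2], neg[: n // 2])
    dev = LabeledSets(pos[n // 2:], neg[n // 2:])
    return kg, train, dev


class TestTrainModel:
    def test_separable_set_learns(self):
        kg, train, dev = separable_sets()
        model = PathScorer(ModelConfig(d=8, k=4, H=4, entity_mode="none"),
                           kg, seed=0)
        config = TrainConfig(epochs=50, batch_size=8, seed=0)
        _, history = train_model(train, dev, model, config)
        losses = [h["loss"] for h in history]
        assert all(l2 < l1 for l1, l2 in zip(losses[:5], losses[1:6]))
        assert max(h["dev_accuracy"] for h in history) >= 0.95

    def test_early_stop_fires_at_patience_plus_one(self):
        kg, train, dev = separable_sets(n=8)
        model = PathScorer(ModelConfig(d=4, k=2, H=2, entity_mode="none"),
                           kg, seed=0)
        config = TrainConfig(epochs=100, patience_epochs=4,
                             min_improve=np.inf, seed=0)
        _, history = train_model(train, dev, model, config)
        assert len(history) == config.patience_epochs + 1

    def test_same_seed_identical_history(self):
        kg, train, dev = separable_sets(n=12)
        histories = []
        for _ in range(2):
            model = PathScorer(ModelConfig(d=4, k=2, H=2, entity_mode="none"),
                               kg, seed=3)
            config = TrainConfig(epochs=5, seed=3)
            _, h = train_model(train, dev, model, config)
            histories.append(h)
        assert histories[0] == histories[1]

    def test_best_checkpoint_restored(self):
        kg, train, dev = separable_sets(n=12)
        model = PathScorer(ModelConfig(d=4, k=2, H=2, entity_mode="none"),
                           kg, seed=0)
        best, history = train_model(train, dev, model,
                                    TrainConfig(epochs=10, seed=0))
        for name, arr in best.items():
            assert np.array_equal(model.leaves[name].value, arr)

    def test_pra_trains_on_separable_set(self):
        kg, train, dev = separable_sets(n=20)
        model = PRAModel(PRAFeatureIndex.from_instances(train.all), seed=0)
        _, history = train_model(train, dev, model,
                                 TrainConfig(epochs=30, batch_size=8, seed=0))
        assert max(h["dev_accuracy"] for h in history) >= 0.95

    def test_empty_train_errors(self):
        kg, train, dev = separable_sets(n=4)
        model = PathScorer(ModelConfig(d=2, k=2, H=2, entity_mode="none"),
                           kg, seed=0)
        with pytest.raises(ValueError):
            train_model(LabeledSets(), dev, model, TrainConfig())


class TestTrainConfigValidation:
    def test_probability_bounds(self):
        with pytest.raises(ValueError):
            TrainConfig(same_relation_prob=1.5)

    def test_positive_rates(self):
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0.0)


class TestGridSearch:
    def test_singleton_grid(self):
        best, score = grid_search({"lr": [0.1]}, lambda c: 1.0)
        assert best == {"lr": 0.1} and score == 1.0

    def test_rigged_oracle_selected(self):
        target = {"lr": 0.002, "d": 100}
        best, _ = grid_search(
            {"lr": [0.001, 0.002], "d": [50, 100]},
            lambda c: 1.0 if c == target else 0.0,
        )
        assert best == target

    def test_two_by_two_matches_exhaustive(self):
        def noisy_eval(c):
            return np.sin(c["lr"] * 100) + np.cos(c["d"])

        grid = {"lr": [0.01, 0.02], "d": [1, 2]}
        best, score = grid_search(grid, noisy_eval)
        import itertools
        exhaustive = max(
            (noisy_eval(dict(zip(grid, combo)))
             for combo in itertools.product(*grid.values())),
        )
        assert score == pytest.approx(exhaustive)

    def test_tie_breaks_to_first(self):
        best, _ = grid_search({"lr": [0.1, 0.2]}, lambda c: 1.0)
        assert best == {"lr": 0.1}

    def test_empty_grid_errors(self):
        with pytest.raises(ValueError):
            grid_search({}, lambda c: 0.0)
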