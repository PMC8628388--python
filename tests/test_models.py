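import numpy as np
import pytest
from scipy.special import expit

from pathsem.kg_core import Entity, KnowledgeGraph, Triple
from pathsem.models import (DUMMY_RELATION, ModelConfig, ModelParams,
                            PairContext, PathScorer, PRAFeatureIndex,
                            PRAModel, attention_weights, combine_paths,
                            encode_path_rnn, encode_path_text,
                            entity_representation, logsumexp_pool,
                            path_match_score, pra_features, pra_score,
                            rnn_step, score_pair)
from pathsem.path_sampler import Path, QueryInstance
from pathsem.text_encoder import StubEncoder

from conftest import random_kg


def tiny_params(d=3, k=3, H=4, seed=0, **kw):
    config = ModelConfig(d=d, k=k, H=H, **kw)
    return config, ModelParams.initialize(
        config, ["r1", "r2", "rq"], ["disease", "symptom", "department"],
        ["rq", "r1", "r2"], seed=seed)


class TestRnnStep:
    def test_zero_weights_give_zero(self):
        config, params = tiny_params()
        for name in ("W1", "W2", "W3"):
            params.arrays[name][...] = 0.0
        out = rnn_step(np.ones(3), np.ones(3), np.ones(3), params)
        assert np.array_equal(out, np.zeros(3))

    def test_identity_matrices_sum_inputs(self):
        config, params = tiny_params(d=2, k=2)
        for name in ("W1", "W2", "W3"):
            params.arrays[name][...] = np.eye(2)
        out = rnn_step(np.array([1.0, 0.0]), np.array([0.0, 1.0]),
                       np.array([1.0, 1.0]), params)
        assert np.allclose(out, [2.0, 2.0])

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(0)
        config, params = tiny_params()
        for _ in range(20):
            h, r, e = rng.normal(size=(3, 3))
            expected = np.empty(3)
            for i in range(3):  # independent scalar-loop arithmetic
                acc = 0.0
                for j in range(3):
                    acc += params.W1[i, j] * h[j]
                    acc += params.W2[i, j] * r[j]
                    acc += params.W3[i, j] * e[j]
                expected[i] = max(acc, 0.0)
            assert np.allclose(rnn_step(h, r, e, params), expected, atol=1e-6)

    def test_outputs_nonnegative(self):
        rng = np.random.default_rng(1)
        config, params = tiny_params()
        out = rnn_step(*rng.normal(size=(3, 3)), params)
        assert np.all(out >= 0.0)

    def test_shape_mismatch_errors(self):
        config, params = tiny_params()
        with pytest.raises(ValueError):
            rnn_step(np.zeros(4), np.zeros(3), np.zeros(3), params)


class TestEntityRepresentation:
    def test_single_type_is_its_embedding(self):
        config, params = tiny_params(entity_mode="types")
        e = Entity("x", "x", ("disease",))
        v = entity_representation(e, params, config)
        assert np.array_equal(v, params.type_emb[params.type_index["disease"]])

    def test_two_types_average(self):
        config, params = tiny_params(entity_mode="types")
        e = Entity("x", "x", ("disease", "symptom"))
        v = entity_representation(e, params, config)
        expected = (params.type_emb[params.type_index["disease"]]
                    + params.type_emb[params.type_index["symptom"]]) / 2
        assert np.allclose(v, expected)

    def test_typeless_entity_zero_vector(self):
        config, params = tiny_params(entity_mode="types")
        v = entity_representation(Entity("x", "x"), params, config)
        assert np.array_equal(v, np.zeros(3))

    def test_zero_projection_gives_zero(self):
        config, params = tiny_params(entity_mode="types_plus_text")
        params.arrays["P_ent"][...] = 0.0
        enc = StubEncoder(H=4, seed=0)
        v = entity_representation(Entity("x", "x", ("disease",)), params,
                                  config, encoder=enc)
        assert np.array_equal(v, np.zeros(3))

    def test_mode_none_uses_shared_vector(self):
        config, params = tiny_params(entity_mode="none")
        v = entity_representation(Entity("x", "x", ("disease",)), params, config)
        assert np.array_equal(v, params.entity_shared)


class TestEncodePathRnn:
    @pytest.fixture
    def kg(self, chain_kg):
        return chain_kg

    def test_one_hop_unrolls_two_steps(self, kg):
        """dummy+source first, then the hop relation and target entity."""
        config, params = tiny_params(entity_mode="types")
        path = Path("A", "B", (("r1", "B"),))
        pi = encode_path_rnn(path, kg, params, config)
        h = rnn_step(np.zeros(3),
                     params.relation_emb[params.relation_index[DUMMY_RELATION]],
                     entity_representation(kg.entity("A"), params, config),
                     params)
        h = rnn_step(h, params.relation_emb[params.relation_index["r1"]],
                     entity_representation(kg.entity("B"), params, config),
                     params)
        assert np.allclose(pi, h)

    def test_multi_hop_matches_hand_unrolled(self, kg):
        config, params = tiny_params(entity_mode="types")
        path = Path("A", "C", (("r1", "B"), ("r2", "C")))
        pi = encode_path_rnn(path, kg, params, config)
        h = np.zeros(3)
        for rel, eid in [(DUMMY_RELATION, "A"), ("r1", "B"), ("r2", "C")]:
            h = rnn_step(h, params.relation_emb[params.relation_index[rel]],
                         entity_representation(kg.entity(eid), params, config),
                         params)
        assert np.allclose(pi, h)

    def test_zero_parameters_zero_vector(self, kg):
        config, params = tiny_params(entity_mode="types")
        for arr in params.arrays.values():
            arr[...] = 0.0
        path = Path("A", "C", (("r1", "B"), ("r2", "C")))
        assert np.array_equal(encode_path_rnn(path, kg, params, config),
                              np.zeros(3))

    def test_unknown_relation_errors(self, kg):
        config, params = tiny_params()
        path = Path("A", "B", (("mystery", "B"),))
        with pytest.raises(KeyError):
            encode_path_rnn(path, kg, params, config)


class TestEncodePathText:
    def test_deterministic_and_identical_for_identical_statements(self, chain_kg):
        config, params = tiny_params(path_mode="text", entity_mode="none")
        enc = StubEncoder(H=4, seed=0)
        path = Path("A", "C", (("r1", "B"), ("r2", "C")))
        a = encode_path_text(path, chain_kg, params, config, enc)
        b = encode_path_text(path, chain_kg, params, config, enc)
        assert np.array_equal(a, b)

    def test_zero_projection_zero_vector(self, chain_kg):
        config, params = tiny_params(path_mode="text", entity_mode="none")
        params.arrays["P_path"][...] = 0.0
        enc = StubEncoder(H=4, seed=0)
        path = Path("A", "B", (("r1", "B"),))
        assert np.array_equal(
            encode_path_text(path, chain_kg, params, config, enc), np.zeros(3))


class TestPoolingPrimitives:
    def test_match_score_zero_T(self):
        config, params = tiny_params()
        params.arrays["T"][...] = 0.0
        assert path_match_score(np.ones(3), np.ones(3), params) == 0.0

    def test_match_score_bounded_by_delta_l1(self):
        rng = np.random.default_rng(0)
        config, params = tiny_params()
        for _ in range(50):
            pi, delta = rng.normal(size=(2, 3)) * 5
            assert abs(path_match_score(pi, delta, params)) <= \
                np.abs(delta).sum() + 1e-12

    def test_match_score_scalar_loop_oracle(self):
        rng = np.random.default_rng(2)
        config, params = tiny_params(d=2, k=2)
        for _ in range(20):
            pi, delta = rng.normal(size=(2, 2))
            acc = 0.0
            for j in range(2):
                inner = sum(pi[i] * params.T[i, j] for i in range(2))
                acc += np.tanh(inner) * delta[j]
            assert path_match_score(pi, delta, params) == pytest.approx(acc, abs=1e-6)

    @pytest.mark.parametrize("z,expected", [
        ([0.0, 0.0], [0.5, 0.5]),
        ([0.0], [1.0]),
        ([np.log(3), 0.0], [0.75, 0.25]),
    ])
    def test_attention_closed_forms(self, z, expected):
        assert np.allclose(attention_weights(z), expected)

    def test_attention_normalized_random(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            z = rng.normal(scale=10, size=rng.integers(1, 8))
            a = attention_weights(z)
            assert np.all(a >= 0)
            assert a.sum() == pytest.approx(1.0, abs=1e-9)

    def test_attention_empty_errors(self):
        with pytest.raises(ValueError):
            attention_weights([])

    def test_combine_single_path_is_tanh(self):
        pi = np.array([0.3, -0.8])
        ctx = combine_paths([pi], [1.0])
        assert np.allclose(ctx.vector, np.tanh(pi))

    def test_combine_zero_paths_zero(self):
        ctx = combine_paths([np.zeros(3), np.zeros(3)], [0.5, 0.5])
        assert np.array_equal(ctx.vector, np.zeros(3))

    def test_combine_weighted_hand_computation(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=(2, 2))
        ctx = combine_paths([a, b], [0.25, 0.75])
        assert np.allclose(ctx.vector, np.tanh(0.25 * a + 0.75 * b), atol=1e-6)

    def test_combine_length_mismatch(self):
        with pytest.raises(ValueError):
            combine_paths([np.zeros(2)], [0.5, 0.5])

    @pytest.mark.parametrize("z,expected", [
        ([4.2], 4.2),
        ([1.5] * 7, 1.5 + np.log(7)),
    ])
    def test_logsumexp_closed_forms(self, z, expected):
        assert logsumexp_pool(z) == pytest.approx(expected)

    def test_logsumexp_bounds_max(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            z = rng.normal(scale=5, size=rng.integers(1, 6))
            assert logsumexp_pool(z) >= z.max()

    def test_uniform_attention_identity_combiner_reduces_to_mean(self):
        """Sanity reduction: uniform α + identity combiner = mean of scores."""
        rng = np.random.default_rng(9)
        config, params = tiny_params()
        pis = [rng.normal(size=3) for _ in range(4)]
        delta = rng.normal(size=3)
        alpha = np.full(4, 0.25)
        ctx = combine_paths(pis, alpha, activation=lambda x: x)
        pooled = float(ctx.vector @ delta)
        assert pooled == pytest.approx(np.mean([pi @ delta for pi in pis]))


class TestScorePair:
    @pytest.fixture
    def setup(self, chain_kg):
        config, params = tiny_params(entity_mode="types")
        inst = QueryInstance("A", "rq", "C", 1,
                             paths=[Path("A", "C", (("r1", "B"), ("r2", "C")))])
        return chain_kg, config, params, inst

    def test_sigmoid_closed_forms(self):
        assert expit(0.0) == pytest.approx(0.5)
        # ep·δ = ln 3 → p = 0.75 through the model's own scoring path
        config, params = tiny_params(d=1, k=1)
        inst = QueryInstance("A", "rq", "B", 1,
                             paths=[Path("A", "B", (("r1", "B"),))])
        kg = KnowledgeGraph([Triple("A", "r1", "B")])
        # rig parameters so the single path yields ep·δ = ln 3
        params.arrays["T"][...] = 0.0
        params.arrays["W1"][...] = 0.0
        params.arrays["W2"][...] = 0.0
        params.arrays["W3"][...] = 0.0
        # π = 0 → ep = tanh(0) = 0 → score 0.5
        assert score_pair(inst, params, config, kg=kg) == pytest.approx(0.5)

    def test_matches_hand_unrolled_forward(self, setup):
        kg, config, params, inst = setup
        p = score_pair(inst, params, config, kg=kg)
        pi = encode_path_rnn(inst.paths[0], kg, params, config)
        delta = params.query_emb[params.query_index["rq"]]
        z = path_match_score(pi, delta, params)
        ep = combine_paths([pi], attention_weights([z]))
        assert p == pytest.approx(float(expit(ep.vector @ delta)))

    def test_result_strictly_in_unit_interval(self, setup):
        kg, config, params, inst = setup
        p = score_pair(inst, params, config, kg=kg)
        assert 0.0 < p < 1.0

    def test_zero_paths_errors(self, setup):
        kg, config, params, inst = setup
        empty = QueryInstance("A", "rq", "C", 1, paths=[])
        with pytest.raises(ValueError):
            score_pair(empty, params, config, kg=kg)

    def test_permutation_invariance(self, figure_kg):
        from pathsem.path_sampler import enumerate_paths
        config = ModelConfig(d=4, k=4, H=4, entity_mode="none")
        kg = figure_kg
        params = ModelParams.initialize(
            config, sorted(kg.relations), [], kg.relation_ids(), seed=3)
        paths = enumerate_paths(kg, "drainage", "medicine", max_len=3).paths
        inst_fwd = QueryInstance("drainage", "disease_related_symptoms",
                                 "medicine", 1, paths=list(paths))
        inst_rev = QueryInstance("drainage", "disease_related_symptoms",
                                 "medicine", 1, paths=list(reversed(paths)))
        for pooling in ("attention", "logsumexp"):
            config.pooling = pooling
            a = score_pair(inst_fwd, params, config, kg=kg)
            b = score_pair(inst_rev, params, config, kg=kg)
            assert a == pytest.approx(b, abs=1e-12)


class TestScorerTwin:
    """The autodiff training graph and the NumPy functional path agree."""

    @pytest.mark.parametrize("preset", ["att-types", "single-types", "att",
                                        "single", "text-path", "text-entity"])
    def test_two_routes_agree(self, figure_kg, preset):
        from pathsem.models import MODEL_PRESETS
        from pathsem.path_sampler import enumerate_paths
        kg = figure_kg
        for eid, e in kg.entities.items():
            e.types = ("disease",) if eid.startswith("d") else ("symptom",)
        enc = StubEncoder(H=6, seed=0)
        config = ModelConfig(d=4, k=3, H=6, **MODEL_PRESETS[preset])
        scorer = PathScorer(config, kg, encoder=enc, seed=5)
        paths = enumerate_paths(kg, "drainage", "medicine", max_len=3).paths
        inst = QueryInstance("drainage", "disease_related_symptoms",
                             "medicine", 1, paths=paths)
        functional = score_pair(inst, scorer.params, config, encoder=enc, kg=kg)
        assert scorer.score(inst) == pytest.approx(functional, abs=1e-10)


class TestGradients:
    def _numeric_grad(self, scorer, inst, name, idx, h=1e-6):
        arr = scorer.leaves[name].value
        orig = arr[idx]
        arr[idx] = orig + h
        up = scorer.logit(inst).item()
        arr[idx] = orig - h
        down = scorer.logit(inst).item()
        arr[idx] = orig
        return (up - down) / (2 * h)

    @pytest.mark.parametrize("preset", ["att-types", "single-types",
                                        "text-path", "text-entity"])
    def test_analytic_vs_central_differences(self, figure_kg, preset):
        """Gradients of the full scoring pipeline at d=k=3."""
        from pathsem.models import MODEL_PRESETS
        from pathsem.path_sampler import enumerate_paths
        kg = figure_kg
        for eid, e in kg.entities.items():
            e.types = ("disease",) if eid.startswith("d") else ("symptom",)
        enc = StubEncoder(H=5, seed=0)
        config = ModelConfig(d=3, k=3, H=5, **MODEL_PRESETS[preset])
        scorer = PathScorer(config, kg, encoder=enc, seed=11)
        paths = enumerate_paths(kg, "drainage", "medicine", max_len=3).paths
        inst = QueryInstance("drainage", "disease_related_symptoms",
                             "medicine", 1, paths=paths)
        scorer.zero_grad()
        out = scorer.logit(inst)
        out.backward()
        rng = np.random.default_rng(0)
        checked = 0
        for name, leaf in scorer.leaves.items():
            if leaf.grad is None:
                continue
            flat = leaf.grad.reshape(-1)
            for _ in range(min(5, flat.size)):
                idx = np.unravel_index(rng.integers(leaf.value.size),
                                       leaf.value.shape)
                num = self._numeric_grad(scorer, inst, name, idx)
                ana = leaf.grad[idx]
                if abs(num) < 1e-8 and abs(ana) < 1e-8:
                    continue
                rel = abs(ana - num) / max(abs(ana), abs(num))
                assert rel < 1e-4, f"{preset}:{name}{idx}: {ana} vs {num}"
                checked += 1
        assert checked > 10


class TestPRA:
    def make_instances(self):
        p1 = Path("A", "C", (("r1", "B"), ("r2", "C")))
        p2 = Path("A", "C", (("r3", "B"), ("r2", "C")))
        i1 = QueryInstance("A", "rq", "C", 1, paths=[p1])
        i2 = QueryInstance("A", "rq", "C", 0, paths=[p2])
        return [i1, i2]

    def test_feature_construction_matches_type_sets(self):
        insts = self.make_instances()
        index = PRAFeatureIndex.from_instances(insts)
        expected_types = {p.path_type() for i in insts for p in i.paths}
        assert set(index.columns) == expected_types
        x = pra_features(insts[0], index)
        assert x.sum() == 1.0
        assert x[index.columns[("r1", "r2")]] == 1.0

    def test_zero_weights_score_half(self):
        insts = self.make_instances()
        index = PRAFeatureIndex.from_instances(insts)
        w = np.zeros(index.n_features)
        assert pra_score(insts[0], index, (w, 0.0)) == pytest.approx(0.5)

    def test_ln3_weight_scores_three_quarters(self):
        insts = self.make_instances()
        index = PRAFeatureIndex.from_instances(insts)
        w = np.zeros(index.n_features)
        w[index.columns[("r1", "r2")]] = np.log(3)
        assert pra_score(insts[0], index, (w, 0.0)) == pytest.approx(0.75)

    def test_unseen_path_type_contributes_zero(self):
        insts = self.make_instances()
        index = PRAFeatureIndex.from_instances(insts[:1])
        x = pra_features(insts[1], index)
        assert np.all(x[1:] == 0) and index.n_unseen == 1

    def test_pra_model_gradcheck(self):
        insts = self.make_instances()
        model = PRAModel(PRAFeatureIndex.from_instances(insts), seed=0)
        model.zero_grad()
        out = model.logit(insts[0])
        out.backward()
        w = model.leaves["pra_w"]
        h = 1e-6
        for idx in range(w.value.size):
            orig = w.value[idx]
            w.value[idx] = orig + h
            up = model.logit(insts[0]).item()
            w.value[idx] = orig - h
            down = model.logit(insts[0]).item()
            w.value[idx] = orig
            assert w.grad[idx] == pytest.approx((up - down) / (2 * h), abs=1e-6)


class TestCheckpoint:
    def test_save_load_round_trips_bit_exact(self, tmp_path):
        config, params = tiny_params()
        params.save(tmp_path / "ck")
        back = ModelParams.load(tmp_path / "ck")
        assert back.relation_index == params.relation_index
        assert back.query_index == params.query_index
        for name, arr in params.arrays.items():
            assert np.array_equal(back.arrays[name], arr)

    def test_dummy_relation_present(self):
        config, params = tiny_params()
        assert DUMMY_RELATION in params.relation_index

    def test_pair_context_validates_attention(self):
        with pytest.raises(ValueError):
            PairContext(vector=np.zeros(2), attention=np.array([0.5, 0.6]))
        with pytest.raises(ValueError):
            PairContext(vector=np.array([1.5]))
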