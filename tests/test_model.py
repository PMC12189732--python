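import numpy as np
import pytest

from crossdti.model import (
    ModelConfig,
    ModelState,
    attention_weights,
    bce_backward,
    bce_sigmoid_loss,
    classify,
    cross_attention,
    forward,
    init_model,
    project,
    sigmoid,
    triplet_backward,
    triplet_loss,
)


def brute_force_project(x, state, prefix):
    """Independent step-by-step recomputation of the projection stack."""
    P = state.params
    h = x
    for layer in ("1", "2", "3"):
        W, b = P[f"{prefix}_W{layer}"], P[f"{prefix}_b{layer}"]
        out = np.zeros(W.shape[1])
        for j in range(W.shape[1]):
            acc = b[j]
            for i in range(W.shape[0]):
                acc += h[i] * W[i, j]
            out[j] = max(acc, 0.0)
        h = out
    return h


def brute_force_attention(lt, lc, state):
    """Loop-based attention oracle for arbitrary token counts."""
    cfg, P = state.config, state.params
    t, td, hd = cfg.token_count, cfg.token_dim, cfg.head_dim
    T = lt.reshape(t, td)
    C = lc.reshape(t, td)
    outs = []
    for head, (Qs, Ks) in (("h1", (T, C)), ("h2", (C, T))):
        Q = Qs @ P[f"{head}_Wq"]
        K = Ks @ P[f"{head}_Wk"]
        V = Ks @ P[f"{head}_Wv"]
        O = np.zeros((t, hd))
        for i in range(t):
            scores = np.array([Q[i] @ K[j] / np.sqrt(hd) for j in range(t)])
            w = np.exp(scores - scores.max())
            w /= w.sum()
            for j in range(t):
                O[i] += w[j] * V[j]
        outs.append(O.ravel())
    return np.concatenate(outs) @ P["WG"]


def brute_force_classify(lt, lc, A, state):
    cfg, P = state.config, state.params
    ahat = lt + lc + A
    mu = ahat.mean()
    var = ((ahat - mu) ** 2).mean()
    xhat = (ahat - mu) / np.sqrt(var + cfg.epsilon)
    return float((xhat * P["ln_alpha"] + P["ln_beta"]) @ P["W4"] + P["b4"][0])


class TestProject:
    def test_zero_weights_annihilate(self, tiny_state, rng):
        st = tiny_state.copy()
        for k in st.params:
            if k.startswith("t_"):
                st.params[k] = np.zeros_like(st.params[k])
        out = project(rng.normal(size=(2, 5)), st, "target")
        assert np.allclose(out, 0.0)

    def test_identity_stack_on_nonnegative_input(self):
        cfg = ModelConfig(target_dim=4, compound_dim=4, p=4, hidden=4, token_count=1, seed=0)
        st = init_model(cfg)
        for layer in ("1", "2", "3"):
            st.params[f"t_W{layer}"] = np.eye(4)
            st.params[f"t_b{layer}"] = np.zeros(4)
        x = np.array([0.0, 1.0, 2.5, 0.1])
        assert np.allclose(project(x, st, "target")[0], x)

    def test_matches_brute_force(self, tiny_state, rng):
        for _ in range(20):
            x = rng.normal(size=5)
            fast = project(x, tiny_state, "target")[0]
            slow = brute_force_project(x, tiny_state, "t")
            assert np.allclose(fast, slow, atol=1e-6)

    def test_dimension_mismatch_names_layer(self, tiny_state):
        with pytest.raises(Exception, match="layer 1"):
            project(np.zeros((1, 9)), tiny_state, "target")

    def test_output_nonnegative(self, tiny_state, rng):
        out = project(rng.normal(size=(10, 6)), tiny_state, "compound")
        assert (out >= 0).all()


class TestCrossAttention:
    def test_singleton_softmax_weight_is_one(self, tiny_state, rng):
        lt, lc = rng.normal(size=8), rng.normal(size=8)
        w1, w2 = attention_weights(lt, lc, tiny_state)
        assert np.allclose(w1, 1.0) and np.allclose(w2, 1.0)
        # hence A = concat(V2, V1) @ WG exactly
        P = tiny_state.params
        V2 = lc @ P["h1_Wv"]
        V1 = lt @ P["h2_Wv"]
        expected = np.concatenate([V2, V1]) @ P["WG"]
        assert np.allclose(cross_attention(lt, lc, tiny_state)[0], expected)

    def test_weights_are_probability_distribution(self, rng):
        cfg = ModelConfig(target_dim=5, compound_dim=6, p=8, hidden=7, token_count=2, seed=1)
        st = init_model(cfg)
        w1, w2 = attention_weights(rng.normal(size=8), rng.normal(size=8), st)
        for w in (w1, w2):
            assert (w >= 0).all()
            assert np.allclose(w.sum(axis=-1), 1.0)

    @pytest.mark.parametrize("token_count", [1, 2])
    def test_matches_brute_force(self, token_count, rng):
        cfg = ModelConfig(target_dim=5, compound_dim=6, p=8, hidden=7, token_count=token_count, seed=2)
        st = init_model(cfg)
        for _ in range(20):
            lt, lc = rng.normal(size=8), rng.normal(size=8)
            assert np.allclose(
                cross_attention(lt, lc, st)[0], brute_force_attention(lt, lc, st), atol=1e-6
            )

    def test_zero_value_maps_annihilate(self, tiny_state, rng):
        st = tiny_state.copy()
        st.params["h1_Wv"] = np.zeros_like(st.params["h1_Wv"])
        st.params["h2_Wv"] = np.zeros_like(st.params["h2_Wv"])
        st.params["WG"] = np.eye(8)
        assert np.allclose(cross_attention(rng.normal(size=8), rng.normal(size=8), st), 0.0)

    def test_odd_p_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(target_dim=4, compound_dim=4, p=7)


class TestClassify:
    def test_standardization_identity(self, tiny_state, rng):
        st = tiny_state.copy()
        st.params["ln_alpha"] = np.ones(8)
        st.params["ln_beta"] = np.zeros(8)
        cache = {}
        classify(rng.normal(size=8), rng.normal(size=8), rng.normal(size=8), st, cache)
        xhat = cache["cls"]["xhat"][0]
        assert abs(xhat.mean()) < 1e-10
        assert abs(xhat.var() - 1.0) < 1e-3  # epsilon shrinks variance slightly

    def test_constant_input_finite_via_epsilon(self, tiny_state):
        ones = np.ones(8)
        logit = classify(ones, ones, ones, tiny_state)
        assert np.isfinite(logit).all()

    def test_matches_brute_force(self, tiny_state, rng):
        for _ in range(20):
            lt, lc, A = rng.normal(size=8), rng.normal(size=8), rng.normal(size=8)
            assert np.allclose(
                classify(lt, lc, A, tiny_state)[0], brute_force_classify(lt, lc, A, tiny_state),
                atol=1e-6,
            )


class TestLosses:
    def test_bce_at_logit_zero_is_ln2(self):
        assert bce_sigmoid_loss(np.array([0.0]), np.array([1])) == pytest.approx(np.log(2), abs=1e-12)
        assert bce_sigmoid_loss(np.array([0.0]), np.array([0])) == pytest.approx(np.log(2), abs=1e-12)

    def test_bce_saturation(self):
        assert bce_sigmoid_loss(np.array([20.0]), np.array([1])) < 1e-8

    def test_bce_matches_direct_formula(self, rng):
        z = rng.normal(scale=3, size=200)
        y = rng.integers(0, 2, size=200)
        s = 1 / (1 + np.exp(-z))
        direct = -(y * np.log(s) + (1 - y) * np.log(1 - s)).mean()
        assert bce_sigmoid_loss(z, y) == pytest.approx(direct, abs=1e-9)

    def test_bce_label_validation(self):
        with pytest.raises(ValueError):
            bce_sigmoid_loss(np.array([0.0]), np.array([2]))

    def test_triplet_equal_distances_gives_margin(self, rng):
        a = rng.normal(size=8)
        p = a + np.array([1.0] + [0.0] * 7)
        # negatives on a sphere of the same radius around the anchor
        negs = []
        for _ in range(5):
            v = rng.normal(size=8)
            negs.append(a + v / np.linalg.norm(v))
        assert triplet_loss(a, p, np.array(negs), margin=0.7) == pytest.approx(0.7, abs=1e-12)

    def test_triplet_hinge_zero_when_negatives_far(self, rng):
        a = rng.normal(size=8)
        p = a.copy()
        negs = a + 100 * np.eye(8)[:3]
        assert triplet_loss(a, p, negs, margin=1.0) == 0.0

    def test_triplet_is_mean_of_individual_hinges(self, rng):
        a, p = rng.normal(size=8), rng.normal(size=8)
        negs = rng.normal(size=(50, 8))
        singles = [triplet_loss(a, p, negs[k : k + 1], margin=1.0) for k in range(50)]
        assert triplet_loss(a, p, negs, margin=1.0) == pytest.approx(np.mean(singles), abs=1e-12)

    def test_triplet_empty_negatives_raises(self, rng):
        with pytest.raises(ValueError):
            triplet_loss(rng.normal(size=4), rng.normal(size=4), np.empty((0, 4)))


class TestEndToEnd:
    def test_forward_deterministic(self, tiny_state, rng):
        E1, E2 = rng.normal(size=(3, 5)), rng.normal(size=(3, 6))
        assert np.array_equal(forward(E1, E2, tiny_state), forward(E1, E2, tiny_state))

    def test_serialization_round_trip_logits(self, tiny_state, tmp_path, rng):
        E1, E2 = rng.normal(size=(4, 5)), rng.normal(size=(4, 6))
        before = forward(E1, E2, tiny_state)
        tiny_state.save(tmp_path / "m")
        loaded = ModelState.load(tmp_path / "m")
        assert np.array_equal(before, forward(E1, E2, loaded))

    @pytest.mark.parametrize("token_count", [1, 2])
    def test_bce_gradient_check(self, token_count, rng):
        cfg = ModelConfig(target_dim=5, compound_dim=6, p=8, hidden=7, token_count=token_count, seed=3)
        st = init_model(cfg)
        E1, E2 = rng.normal(size=(3, 5)), rng.normal(size=(3, 6))
        y = np.array([1.0, 0.0, 1.0])
        _, grads = bce_backward(E1, E2, y, st)
        h = 1e-6
        for key in ("t_W1", "c_W3", "h1_Wq", "WG", "ln_alpha", "W4"):
            flat = st.params[key].ravel()
            for idx in rng.choice(flat.size, size=3, replace=False):
                old = flat[idx]
                flat[idx] = old + h
                lp, _ = bce_backward(E1, E2, y, st)
                flat[idx] = old - h
                lm, _ = bce_backward(E1, E2, y, st)
                flat[idx] = old
                assert (lp - lm) / (2 * h) == pytest.approx(grads[key].ravel()[idx], abs=1e-4)

    def test_triplet_gradient_check(self, tiny_state, rng):
        a, p = rng.normal(size=(1, 5)), rng.normal(size=(1, 6))
        negs = rng.normal(size=(4, 6))
        _, grads = triplet_backward(a, p, negs, tiny_state, margin=1.0)
        h = 1e-6
        for key in ("t_W2", "c_W1", "c_b3"):
            flat = tiny_state.params[key].ravel()
            for idx in rng.choice(flat.size, size=3, replace=False):
                old = flat[idx]
                flat[idx] = old + h
                lp, _ = triplet_backward(a, p, negs, tiny_state, 1.0)
                flat[idx] = old - h
                lm, _ = triplet_backward(a, p, negs, tiny_state, 1.0)
                flat[idx] = old
                assert (lp - lm) / (2 * h) == pytest.approx(grads[key].ravel()[idx], abs=1e-4)
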