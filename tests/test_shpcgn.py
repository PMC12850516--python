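"""Hybrid classifier blocks: chaotic map, composite activation, updated
batch normalization, attention, ghost modules, soft voting, training."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seizpipe import shpcgn as sh


class TestChaoticMap:
    def test_hand_iterated_sequence(self):
        np.testing.assert_allclose(
            sh.chaotic_map_sequence(0.3, 0.5, 5), [0.6, 0.8, 0.4, 0.8, 0.4]
        )

    @settings(deadline=None, max_examples=50)
    @given(
        st.floats(0.01, 0.99, allow_nan=False),
        st.floats(0.01, 0.99, allow_nan=False),
    )
    def test_iterates_stay_in_unit_interval(self, x0, q):
        seq = sh.chaotic_map_sequence(x0, q, 200)
        assert (seq >= 0).all() and (seq <= 1).all()

    def test_boundary_case_x0_equals_q(self):
        seq = sh.chaotic_map_sequence(0.4, 0.4, 2)
        assert seq[0] == pytest.approx(1.0)  # x >= q branch: (1-0.4)/(1-0.4)... iterate hits 1

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            sh.chaotic_map_sequence(0.0, 0.5, 3)
        with pytest.raises(ValueError):
            sh.chaotic_map_sequence(0.5, 1.0, 3)


class TestStGEActivation:
    def test_zero_is_fixed_point(self):
        assert sh.stge_activation(0.0) == pytest.approx(0.0)

    def test_positive_branch_value(self):
        # x*tanh(softplus(x)) at x=1: tanh(ln(1+e))
        assert sh.stge_activation(1.0) == pytest.approx(0.8651, abs=1e-4)

    def test_continuity_at_zero(self):
        left = sh.stge_activation(-1e-9, 0.3, 0.7)
        right = sh.stge_activation(1e-9, 0.3, 0.7)
        assert abs(left - right) < 1e-8

    def test_finite_everywhere(self):
        x = np.linspace(-500, 500, 2001)
        assert np.isfinite(sh.stge_activation(x, 0.4, 0.6)).all()


class TestMixedPool:
    def test_endpoints_and_midpoint(self):
        s = np.array([1.0, 3.0])
        assert sh.mixed_pool(s, 1.0) == 3.0
        assert sh.mixed_pool(s, 0.0) == 2.0
        assert sh.mixed_pool(s, 0.5) == 2.5

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            sh.mixed_pool(np.array([]), 0.5)


class TestAttentionNorm:
    def test_constant_input_guarded_to_zero(self):
        np.testing.assert_allclose(sh.attention_norm(np.full(6, 2.0)), 0.0)

    def test_zero_weights_give_uniform_softmax(self, rng):
        x = rng.standard_normal(8)
        out = sh.attention_norm(x, w1=0.0, b=0.0)
        std = (x - x.mean()) / x.std()
        np.testing.assert_allclose(out, std * (1 + 1 / 8), atol=1e-12)
        assert out.mean() == pytest.approx(0.0, abs=1e-12)


class TestUBN:
    def test_identity_gate_reduces_to_batch_norm(self, rng):
        x = rng.standard_normal((32, 5))
        x = (x - x.mean(0)) / x.std(0)  # zero-mean unit-var batch
        out = sh.ubn_forward(x, sh.UBNState(q_mode="identity"))
        np.testing.assert_allclose(out, x, atol=1e-4)

    def test_standardized_moments(self, rng):
        x = 3.0 + 2.0 * rng.standard_normal((64, 6, 10))
        _, z = sh.ubn_forward(x, sh.UBNState(), return_standardized=True)
        np.testing.assert_allclose(z.mean(axis=(0, 2)), 0.0, atol=1e-6)
        np.testing.assert_allclose(z.var(axis=(0, 2)), 1.0, atol=1e-4)

    def test_constant_channel_guarded(self):
        x = np.ones((8, 3))
        x[:, 1] = np.arange(8)
        _, z = sh.ubn_forward(x, sh.UBNState(q_mode="identity"), return_standardized=True)
        np.testing.assert_allclose(z[:, 0], 0.0, atol=1e-10)

    def test_single_sample_training_batch_rejected(self):
        with pytest.raises(ValueError):
            sh.ubn_forward(np.ones((1, 4)), sh.UBNState())

    def test_inference_uses_stored_statistics(self, rng):
        x = rng.standard_normal((16, 4))
        state = sh.UBNState(q_mode="identity")
        sh.ubn_forward(x, state, training=True)
        one = sh.ubn_forward(x[:1], state, training=False)
        np.testing.assert_allclose(
            one, (x[:1] - state.running_mean) / np.sqrt(state.running_var + state.eps)
        )


class TestSPCII:
    def test_shape_preserved_and_profiles_in_unit_interval(self, rng):
        att = sh.SPCIIAttention(8, seed=0)
        x = rng.standard_normal((3, 8, 5, 7))
        out = att(x)
        assert out.shape == x.shape
        p_h, p_w = att.profiles(x)
        for p in (p_h, p_w):
            assert (p > 0).all() and (p < 1).all()

    def test_zero_map_gets_half_profiles(self):
        att = sh.SPCIIAttention(8, seed=1)
        z = np.zeros((2, 8, 4, 6))
        p_h, p_w = att.profiles(z)
        np.testing.assert_allclose(p_h, 0.5)
        np.testing.assert_allclose(p_w, 0.5)
        np.testing.assert_allclose(att(z), 0.0)

    def test_degenerate_spatial_dims_rejected(self):
        att = sh.SPCIIAttention(4, seed=0)
        with pytest.raises(ValueError):
            att(np.zeros((4, 1, 5)))


class TestGhostModule:
    def test_channel_arithmetic(self, rng):
        gm = sh.GhostModule(8, 64, ratio=2, seed=0)
        out = gm(rng.standard_normal((2, 8, 6, 6)))
        assert out.shape == (2, 64, 6, 6)
        assert gm.w_primary.shape[0] == 32  # intrinsic maps

    def test_parameter_count_below_dense_conv(self):
        gm = sh.GhostModule(16, 64, ratio=2)
        assert gm.param_count < sh.GhostModule.dense_param_count(16, 64)

    def test_identity_cheap_op_duplicates_intrinsic(self, rng):
        gm = sh.GhostModule(4, 8, ratio=2, seed=3, cheap_init="identity")
        out = gm(rng.standard_normal((1, 4, 6, 6)))
        np.testing.assert_allclose(out[:, :4], out[:, 4:], atol=1e-12)

    def test_indivisible_out_channels_rejected(self):
        with pytest.raises(ValueError):
            sh.GhostModule(4, 9, ratio=2)


def blob_features(rng, n, d_eeg=64, d_img=64, gap=2.0):
    y = np.arange(n) % 2
    rng.shuffle(y)
    Xe = rng.standard_normal((n, d_eeg)) + gap * y[:, None]
    Xf = rng.standard_normal((n, d_img)) - gap * y[:, None]
    subjects = np.array([f"s{i % 12}" for i in range(n)])
    return Xe, Xf, y, subjects


def small_iapc(seed=0, **kw):
    return sh.IAPCNet(
        sh.IAPCNetConfig(eeg_dim=64, fmri_dim=64, fmri_map_shape=(8, 8), seed=seed, **kw)
    )


class TestIAPCNet:
    def test_probability_simplex_and_determinism(self, rng):
        Xe, Xf, y, _ = blob_features(rng, 60)
        net = small_iapc()
        net.fit((Xe[:40], Xf[:40]), y[:40], (Xe[40:], Xf[40:]), y[40:],
                sh.TrainConfig(epochs=3, seed=0))
        p1 = net.predict_proba((Xe, Xf))
        assert p1.shape == (60, 2)
        np.testing.assert_allclose(p1.sum(axis=1), 1.0, atol=1e-6)
        net2 = small_iapc()
        net2.fit((Xe[:40], Xf[:40]), y[:40], (Xe[40:], Xf[40:]), y[40:],
                 sh.TrainConfig(epochs=3, seed=0))
        np.testing.assert_allclose(p1, net2.predict_proba((Xe, Xf)))

    def test_sample_permutation_equivariance(self, rng):
        Xe, Xf, y, _ = blob_features(rng, 40)
        net = small_iapc()
        net.fit((Xe[:30], Xf[:30]), y[:30], (Xe[30:], Xf[30:]), y[30:],
                sh.TrainConfig(epochs=2, seed=0))
        perm = rng.permutation(40)
        p = net.predict_proba((Xe, Xf))
        pp = net.predict_proba((Xe[perm], Xf[perm]))
        np.testing.assert_allclose(pp, p[perm], atol=1e-10)

    def test_dimension_mismatch_diagnostic(self, rng):
        net = small_iapc()
        with pytest.raises(ValueError, match="expected"):
            net.encode((np.zeros((4, 32)), np.zeros((4, 64))))


class TestSoftVote:
    def test_weighted_average_and_argmax(self):
        a = np.array([[0.6, 0.4]])
        b = np.array([[0.2, 0.8]])
        labels, fused = sh.soft_vote([a, b])
        np.testing.assert_allclose(fused, [[0.4, 0.6]])
        assert labels[0] == 1

    def test_identical_inputs_pass_through(self, rng):
        p = rng.dirichlet(np.ones(2), size=10)
        labels, fused = sh.soft_vote([p, p])
        np.testing.assert_allclose(fused, p)
        np.testing.assert_array_equal(labels, p.argmax(axis=1))

    def test_degenerate_weight_selects_single_classifier(self, rng):
        a = rng.dirichlet(np.ones(2), size=8)
        b = rng.dirichlet(np.ones(2), size=8)
        labels, fused = sh.soft_vote([a, b], psi=np.array([1.0, 0.0]))
        np.testing.assert_allclose(fused, a)

    def test_tie_breaks_to_class_zero(self):
        a = np.array([[0.5, 0.5]])
        labels, _ = sh.soft_vote([a, a])
        assert labels[0] == 0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sh.soft_vote([np.ones((3, 2)) / 2, np.ones((4, 2)) / 2])


class TestTraining:
    def test_separated_blobs_reach_high_validation_accuracy(self, rng):
        Xe, Xf, y, subjects = blob_features(rng, 240, gap=2.0)
        net = small_iapc()
        _, history, split = sh.train(
            net, (Xe, Xf), y, subjects, sh.TrainConfig(epochs=20, seed=0)
        )
        assert max(history["val_acc"]) >= 0.95
        # linear oracle on the same split confirms the data are separable
        from sklearn.linear_model import LogisticRegression

        X = np.concatenate([Xe, Xf], axis=1)
        lin = LogisticRegression(max_iter=1000).fit(X[split["train"]], y[split["train"]])
        assert lin.score(X[split["val"]], y[split["val"]]) >= 0.95

    def test_label_shuffle_gives_chance_accuracy(self, rng):
        Xe, Xf, y, subjects = blob_features(rng, 800, gap=2.0)
        y_shuf = np.random.default_rng(99).permutation(y)
        ghost = sh.GhostNetClassifier(
            sh.GhostClassifierConfig(in_dim=128, map_shape=(8, 16), seed=0)
        )
        Xc = np.concatenate([Xe, Xf], axis=1)
        model, _, split = sh.train(ghost, Xc, y_shuf, subjects, sh.TrainConfig(epochs=15, seed=1))
        acc = (model.predict(Xc[split["test"]]) == y_shuf[split["test"]]).mean()
        assert 0.4 <= acc <= 0.6

    def test_training_is_seed_deterministic(self, rng):
        Xe, Xf, y, subjects = blob_features(rng, 80)
        runs = []
        for _ in range(2):
            net = small_iapc()
            _, history, _ = sh.train(net, (Xe, Xf), y, subjects, sh.TrainConfig(epochs=5, seed=2))
            runs.append(history["val_loss"])
        np.testing.assert_allclose(runs[0], runs[1])

    def test_single_class_validation_rejected(self, rng):
        net = small_iapc()
        Xe, Xf, y, _ = blob_features(rng, 40)
        with pytest.raises(ValueError):
            net.fit((Xe[:30], Xf[:30]), y[:30], (Xe[30:], Xf[30:]), np.zeros(10),
                    sh.TrainConfig(epochs=2))


class TestEnsembleDominance:
    def test_soft_vote_never_below_worst_and_near_best(self, rng):
        """Over 20 seeded runs the fused accuracy never drops below the
        worse member and stays within 0.02 of the better member on average."""
        fused_accs, best_accs, worst_accs = [], [], []
        for seed in range(20):
            r = np.random.default_rng(seed)
            Xe, Xf, y, subjects = blob_features(r, 160, gap=1.2)
            Xc = np.concatenate([Xe, Xf], axis=1)
            net = small_iapc(seed=seed)
            ghost = sh.GhostNetClassifier(
                sh.GhostClassifierConfig(in_dim=128, map_shape=(8, 16), seed=seed)
            )
            tc = sh.TrainConfig(epochs=10, seed=seed)
            _, _, split = sh.train(net, (Xe, Xf), y, subjects, tc)
            sh.train(ghost, Xc, y, subjects, tc)
            te = split["test"]
            p1 = net.predict_proba((Xe[te], Xf[te]))
            p2 = ghost.predict_proba(Xc[te])
            labels, _ = sh.soft_vote([p1, p2])
            acc = lambda p: (p.argmax(1) == y[te]).mean()
            a1, a2 = acc(p1), acc(p2)
            fused_accs.append((labels == y[te]).mean())
            best_accs.append(max(a1, a2))
            worst_accs.append(min(a1, a2))
        fused_accs = np.array(fused_accs)
        assert (fused_accs >= np.array(worst_accs) - 1e-12).all()
        assert fused_accs.mean() >= np.mean(best_accs) - 0.02
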