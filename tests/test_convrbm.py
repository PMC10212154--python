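import itertools

import numpy as np
import pytest

from mocapkit import synthetic
from mocapkit.convrbm import (
    ConvRBMModel,
    Embedding,
    SimilarityConfig,
    encode,
    find_similar_frames,
    frames_to_slabs,
    free_energy,
    hidden_conditional,
    init_model,
    rbm_energy,
    standardize,
    train_cd,
)
from mocapkit.kinematics import pose_features


def tiny_model(rng=None, visible_type="bernoulli", scale=0.5):
    """Dense 3-visible / 2-hidden RBM expressed as a ConvRBM: one channel,
    three positions, full-width kernels -> one hidden position per filter."""
    rng = rng or np.random.default_rng(0)
    return ConvRBMModel(
        filters=scale * rng.standard_normal((2, 1, 3)),
        hidden_bias=scale * rng.standard_normal(2),
        visible_bias=scale * rng.standard_normal((1, 3)),
        visible_type=visible_type,
    )


def dense_energy_oracle(model, v3, h2):
    """Independent dense-RBM energy: hand-rolled loops, no convolution."""
    W = model.filters[:, 0, :]  # (2, 3)
    a = model.visible_bias[0]
    b = model.hidden_bias
    if model.visible_type == "bernoulli":
        e = -sum(a[i] * v3[i] for i in range(3))
    else:
        e = sum((v3[i] - a[i]) ** 2 / 2.0 for i in range(3))
    for k in range(2):
        e -= h2[k] * b[k]
        for i in range(3):
            e -= h2[k] * W[k, i] * v3[i]
    return e


def enumerate_states():
    for v in itertools.product([0.0, 1.0], repeat=3):
        for h in itertools.product([0.0, 1.0], repeat=2):
            yield np.array(v), np.array(h)


def partition_oracle(model):
    return sum(
        np.exp(-dense_energy_oracle(model, v, h)) for v, h in enumerate_states()
    )


class TestEnergy:
    def test_zero_parameters_gaussian(self):
        model = ConvRBMModel(
            filters=np.zeros((2, 1, 3)),
            hidden_bias=np.zeros(2),
            visible_bias=np.zeros((1, 3)),
            visible_type="gaussian",
        )
        v = np.array([[1.0, -2.0, 0.5]])
        for h in ([[0.0], [0.0]], [[1.0], [1.0]], [[1.0], [0.0]]):
            assert rbm_energy(model, v, np.array(h)) == pytest.approx(
                0.5 * np.sum(v**2)
            )

    def test_filter_swap_symmetry(self):
        rng = np.random.default_rng(3)
        f = rng.standard_normal((1, 1, 3))
        model = ConvRBMModel(
            filters=np.vstack([f, f]),
            hidden_bias=np.array([0.4, 0.4]),
            visible_bias=rng.standard_normal((1, 3)),
        )
        v = rng.standard_normal((1, 3))
        h = np.array([[1.0], [0.0]])
        h_swapped = np.array([[0.0], [1.0]])
        assert rbm_energy(model, v, h) == pytest.approx(
            rbm_energy(model, v, h_swapped), abs=1e-12
        )

    def test_partition_function_matches_enumeration_oracle(self):
        for seed in range(5):
            model = tiny_model(np.random.default_rng(seed))
            z_impl = sum(
                np.exp(-rbm_energy(model, v[None, :], h[:, None]))
                for v, h in enumerate_states()
            )
            assert z_impl == pytest.approx(partition_oracle(model), rel=1e-10)

    def test_energy_matches_oracle_statewise(self):
        model = tiny_model(np.random.default_rng(7))
        for v, h in enumerate_states():
            assert rbm_energy(model, v[None, :], h[:, None]) == pytest.approx(
                dense_energy_oracle(model, v, h), abs=1e-12
            )

    def test_shape_mismatch(self):
        model = tiny_model()
        with pytest.raises(ValueError):
            rbm_energy(model, np.zeros((1, 4)), np.zeros((2, 1)))
        with pytest.raises(ValueError):
            rbm_energy(model, np.zeros((1, 3)), np.zeros((3, 1)))


class TestHiddenConditional:
    def test_zero_parameters_half(self):
        model = ConvRBMModel(
            filters=np.zeros((4, 3, 5)),
            hidden_bias=np.zeros(4),
            visible_bias=np.zeros((3, 32)),
        )
        p = hidden_conditional(model, np.random.default_rng(0).standard_normal((3, 32)))
        np.testing.assert_array_equal(p, 0.5)

    def test_bias_monotonicity(self):
        model = tiny_model()
        v = np.array([[0.3, -0.8, 0.1]])
        p0 = hidden_conditional(model, v)[0, 0]
        boosted = model.copy()
        boosted.hidden_bias = boosted.hidden_bias + np.array([2.0, 0.0])
        assert hidden_conditional(boosted, v)[0, 0] > p0

    def test_matches_enumerated_joint(self):
        model = tiny_model(np.random.default_rng(11))
        for v in itertools.product([0.0, 1.0], repeat=3):
            v = np.array(v)
            # brute-force P(h_k=1 | v) from the enumerated joint
            num = np.zeros(2)
            den = 0.0
            for h in itertools.product([0.0, 1.0], repeat=2):
                h = np.array(h)
                w = np.exp(-dense_energy_oracle(model, v, h))
                den += w
                num += h * w
            p = hidden_conditional(model, v[None, :])[:, 0]
            np.testing.assert_allclose(p, num / den, atol=1e-12)

    def test_in_open_unit_interval(self):
        model = init_model(seed=1)
        p = hidden_conditional(model, np.random.default_rng(2).standard_normal((3, 32)))
        assert np.all(p > 0) and np.all(p < 1)


class TestFreeEnergy:
    def test_log_likelihood_matches_enumeration(self):
        # acceptance-grade identity: free energy - log Z == log P(v)
        model = tiny_model(np.random.default_rng(13))
        logz = np.log(partition_oracle(model))
        for v in itertools.product([0.0, 1.0], repeat=3):
            v = np.array(v)
            brute = (
                sum(
                    np.exp(-dense_energy_oracle(model, v, np.array(h)))
                    for h in itertools.product([0.0, 1.0], repeat=2)
                )
                / partition_oracle(model)
            )
            log_p = -free_energy(model, v[None, :]) - logz
            assert log_p == pytest.approx(np.log(brute), abs=1e-10)


def exact_avg_log_likelihood(model, samples):
    z = sum(
        np.exp(-rbm_energy(model, v[None, :], h[:, None]))
        for v, h in enumerate_states()
    )
    logz = np.log(z)
    return float(np.mean([-free_energy(model, v[None, :]) - logz for v in samples]))


def sample_tiny_rbm(model, n, seed):
    """Exact ancestral sampling of v by enumerating the marginal."""
    vs = list(itertools.product([0.0, 1.0], repeat=3))
    probs = np.array(
        [
            sum(
                np.exp(-rbm_energy(model, np.array(v)[None, :], np.array(h)[:, None]))
                for h in itertools.product([0.0, 1.0], repeat=2)
            )
            for v in vs
        ]
    )
    probs /= probs.sum()
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(vs), size=n, p=probs)
    return np.array([vs[i] for i in idx])


class TestTrainCD:
    def test_lr_zero_is_identity(self):
        model = tiny_model()
        data = np.zeros((8, 1, 3))
        data[::2, 0, 0] = 1.0
        trained, _ = train_cd(model, data, lr=0.0, epochs=3, seed=0)
        np.testing.assert_array_equal(trained.filters, model.filters)
        np.testing.assert_array_equal(trained.hidden_bias, model.hidden_bias)
        np.testing.assert_array_equal(trained.visible_bias, model.visible_bias)

    def test_same_seed_bit_identical(self):
        model = init_model(n_filters=3, kernel_width=4, seed=5)
        data = np.random.default_rng(9).standard_normal((30, 3, 32))
        data, _ = standardize(data)
        m1, t1 = train_cd(model, data, lr=1e-2, epochs=3, seed=77)
        m2, t2 = train_cd(model, data, lr=1e-2, epochs=3, seed=77)
        np.testing.assert_array_equal(m1.filters, m2.filters)
        assert t1 == t2

    def test_cd_improves_exact_likelihood(self):
        # teacher RBM with clear structure; exact sampling; CD-1 learning
        teacher = tiny_model(np.random.default_rng(21), scale=1.5)
        samples = sample_tiny_rbm(teacher, 400, seed=1)
        medians = []
        for seed in range(5):
            student = tiny_model(np.random.default_rng(100 + seed), scale=0.1)
            before = exact_avg_log_likelihood(student, samples)
            trained, _ = train_cd(
                student, samples[:, None, :], k=1, lr=0.05, epochs=30,
                batch=20, seed=seed,
            )
            after = exact_avg_log_likelihood(trained, samples)
            medians.append(after - before)
        assert np.median(medians) > 0

    def test_divergence_detected(self):
        model = tiny_model()
        data = np.zeros((4, 1, 3))
        model.filters[0, 0, 0] = np.inf
        with pytest.raises((FloatingPointError, ValueError)):
            train_cd(model, data, lr=1.0, epochs=1, seed=0)

    def test_unstandardized_warns(self):
        model = init_model(n_filters=2, kernel_width=3, seed=0)
        data = 5.0 + np.random.default_rng(0).standard_normal((10, 3, 32))
        with pytest.warns(UserWarning, match="standardized"):
            train_cd(model, data, lr=1e-3, epochs=1, seed=0)


class TestEncode:
    def test_duplicate_frames_identical_embeddings(self, walking):
        feats = pose_features(walking)
        model = init_model(seed=0)
        pcs = np.stack([f.point_cloud for f in feats[:5]])
        pcs[3] = pcs[1]
        emb = encode(model, pcs)
        np.testing.assert_array_equal(emb.vectors[3], emb.vectors[1])

    def test_dimension_is_filter_count(self, walking):
        feats = pose_features(walking)
        model = init_model(n_filters=6, seed=0)
        emb = encode(model, feats[:10])
        assert emb.dim == 6
        assert emb.n_frames == 10

    def test_temporal_window_too_large(self):
        model = init_model(temporal_window=5, seed=0)
        with pytest.raises(ValueError, match="temporal_window"):
            encode(model, np.zeros((3, 96)))

    def test_style_separation(self, humanoid):
        # styles with disjoint frequency content must separate in
        # embedding space; distances checked against a brute-force oracle
        model = init_model(n_filters=8, seed=4)
        embs = {}
        for name in ("walking", "running"):
            seq = synthetic.gen_motion(
                humanoid, synthetic.STYLES[name], n_frames=80, seed=11
            )
            pcs = np.stack([f.point_cloud for f in pose_features(seq)])
            slabs = frames_to_slabs(pcs)
            std, stats = standardize(slabs)
            embs[name] = encode(model, pcs, stats=stats)
        w, r = embs["walking"].vectors, embs["running"].vectors

        def mean_dist(A, B):
            total, n = 0.0, 0
            for a in A:
                for b in B:
                    total += float(np.sqrt(np.sum((a - b) ** 2)))
                    n += 1
            return total / n

        between = mean_dist(w, r)
        within = 0.5 * (mean_dist(w, w) + mean_dist(r, r))
        assert between > within


class TestFindSimilarFrames:
    def test_zero_threshold_distinct(self, rng):
        a = Embedding(rng.standard_normal((20, 4)), source="a")
        b = Embedding(rng.standard_normal((25, 4)), source="b")
        assert find_similar_frames(a, b, SimilarityConfig(0.0)) == []

    def test_infinite_threshold_self_count(self, rng):
        F, e = 30, 5
        emb = Embedding(rng.standard_normal((F, 3)), source="x")
        pairs = find_similar_frames(emb, emb, SimilarityConfig(np.inf, exclusion=e))
        # analytic count: all i<j with j - i >= e
        expected = sum(1 for i in range(F) for j in range(i + e, F))
        assert len(pairs) == expected

    def test_matches_brute_force_oracle(self, rng):
        a = Embedding(rng.standard_normal((40, 5)), source="a")
        b = Embedding(rng.standard_normal((35, 5)), source="b")
        got = find_similar_frames(a, b, SimilarityConfig(0.5))
        brute = []
        for i in range(40):
            for j in range(35):
                d = float(np.sqrt(np.sum((a.vectors[i] - b.vectors[j]) ** 2)))
                if d <= 0.5:
                    brute.append((i, j, d))
        assert set((i, j) for i, j, _ in got) == set((i, j) for i, j, _ in brute)
        dists = [d for _, _, d in got]
        assert dists == sorted(dists)

    def test_symmetry_under_swap(self, rng):
        a = Embedding(rng.standard_normal((15, 4)), source="a")
        b = Embedding(rng.standard_normal((15, 4)), source="b")
        ab = find_similar_frames(a, b, SimilarityConfig(1.0))
        ba = find_similar_frames(b, a, SimilarityConfig(1.0))
        assert {(i, j) for i, j, _ in ab} == {(j, i) for i, j, _ in ba}

    def test_dim_mismatch(self, rng):
        a = Embedding(rng.standard_normal((5, 4)))
        b = Embedding(rng.standard_normal((5, 3)))
        with pytest.raises(ValueError):
            find_similar_frames(a, b, SimilarityConfig(1.0))


class TestHistoryOrderZeroEquivalence:
    def test_plain_path_identical(self):
        rng = np.random.default_rng(5)
        base = init_model(n_filters=3, kernel_width=4, seed=2)
        with_history = init_model(
            n_filters=3, kernel_width=4, history_order=2, seed=2
        )
        # same core parameters
        with_history.filters = base.filters.copy()
        with_history.hidden_bias = base.hidden_bias.copy()
        with_history.visible_bias = base.visible_bias.copy()
        v = rng.standard_normal((3, 32))
        h = (rng.random((3, 29)) < 0.5).astype(float)
        # no history supplied -> reduces exactly to the plain RBM
        assert rbm_energy(with_history, v, h) == rbm_energy(base, v, h)
        np.testing.assert_array_equal(
            hidden_conditional(with_history, v), hidden_conditional(base, v)
        )


class TestTrainingTrace:
    def test_reconstruction_error_trend(self, humanoid):
        # median over 5 seeds of the smoothed trace must not increase
        seq = synthetic.gen_motion(
            humanoid, synthetic.STYLES["walking"], n_frames=100, seed=2
        )
        pcs = np.stack([f.point_cloud for f in pose_features(seq)])
        slabs, _ = standardize(frames_to_slabs(pcs))
        firsts, lasts = [], []
        for seed in range(5):
            model = init_model(n_filters=4, kernel_width=5, seed=seed)
            _, trace = train_cd(model, slabs, lr=5e-3, epochs=8, seed=seed)
            smooth = np.convolve(trace, np.ones(3) / 3, mode="valid")
            firsts.append(smooth[0])
            lasts.append(smooth[-1])
        assert np.median(lasts) <= np.median(firsts) + 1e-9
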