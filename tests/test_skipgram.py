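import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import spearmanr

import mpdisnet as mp
from mpdisnet import skipgram
from mpdisnet.skipgram import (
    NoiseDistribution,
    mean_objective,
    pair_gradients,
    pair_objective,
)
from mpdisnet.walker import WalkCorpus

D, M, G = mp.NodeType.DISEASE, mp.NodeType.MIRNA, mp.NodeType.GENE


def _corpus(walks, metapath=mp.M1, steps=1):
    return WalkCorpus(walks, [True] * len(walks), metapath, steps)


class TestExtractContexts:
    def test_window_one_enumeration(self):
        pairs = list(mp.extract_contexts(_corpus([["D1", "M1", "G1"]]), window=1))
        assert pairs == [
            ("D1", "M1", M),
            ("M1", "D1", D),
            ("M1", "G1", G),
            ("G1", "M1", M),
        ]

    def test_singleton_walk_yields_nothing(self):
        assert list(mp.extract_contexts(_corpus([["D1"]]), window=3)) == []

    def test_window_two_center_contexts(self):
        walk = ["D1", "M1", "G1", "G2", "M2", "D2"]
        pairs = list(mp.extract_contexts(_corpus([walk]), window=2))
        for_g1 = [(c, t) for v, c, t in pairs if v == "G1"]
        assert sorted(for_g1) == sorted(
            [("D1", D), ("M1", M), ("G2", G), ("M2", M)]
        )

    def test_window_larger_than_walk_is_in_bounds(self):
        pairs = list(mp.extract_contexts(_corpus([["D1", "M1"]]), window=10))
        assert len(pairs) == 2

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            list(mp.extract_contexts(_corpus([["D1", "M1"]]), window=0))


class TestNegativeSampling:
    def test_single_node_always_drawn(self):
        dist = NoiseDistribution({M: ["m1"]}, {"m1": 3}, 1.0)
        rng = np.random.default_rng(0)
        assert all(dist.sample(M, rng) == "m1" for _ in range(20))

    def test_draw_ratio_follows_counts(self):
        """Counts 8:1 at exponent 1.0 give an ~8:1 draw ratio."""
        dist = NoiseDistribution({M: ["a", "b"]}, {"a": 8, "b": 1}, 1.0)
        rng = np.random.default_rng(42)
        draws = dist.sample(M, rng, size=10_000)
        n_a = draws.count("a")
        # binomial: p=8/9, sd = sqrt(p(1-p)n) ~ 31.4
        assert abs(n_a - 10_000 * 8 / 9) < 4 * np.sqrt(10_000 * (8 / 9) * (1 / 9))

    def test_small_exponent_limit_is_uniform(self):
        dist = NoiseDistribution({M: ["a", "b"]}, {"a": 8, "b": 1}, 1e-9)
        rng = np.random.default_rng(7)
        draws = dist.sample(M, rng, size=10_000)
        assert abs(draws.count("a") - 5000) < 4 * np.sqrt(10_000 * 0.25)

    def test_negatives_share_context_type(self):
        vocab = {M: ["m1", "m2"], G: ["g1", "g2", "g3"]}
        counts = {"m1": 2, "m2": 5, "g1": 1, "g2": 1, "g3": 4}
        cfg = mp.SkipgramConfig(dimension=4)
        rng = np.random.default_rng(0)
        for _ in range(50):
            assert mp.negative_sample(vocab, G, counts, cfg, rng).startswith("g")

    def test_empty_type_vocabulary_errors(self):
        dist = NoiseDistribution({M: ["m1"]}, {"m1": 1}, 0.75)
        with pytest.raises(ValueError, match="empty vocabulary"):
            dist.sample(G, np.random.default_rng(0))


class TestSgdStep:
    def test_zero_learning_rate_is_identity(self):
        rng = np.random.default_rng(0)
        W = rng.normal(size=(6, 5))
        before = W.copy()
        mp.sgd_step(W, 0, 1, [2, 3], learning_rate=0.0)
        np.testing.assert_array_equal(W, before)

    def test_orthogonal_pair_update_has_half_magnitude(self):
        # x_c . x_v = 0 => sigma(0) = 0.5 and the positive-pair pull on the
        # center is 0.5 * x_c (ascent direction increases the dot product).
        W = np.zeros((2, 2))
        W[0] = [1.0, 0.0]  # center
        W[1] = [0.0, 1.0]  # context
        mp.sgd_step(W, 0, 1, [], learning_rate=1.0)
        np.testing.assert_allclose(W[0], [1.0, 0.5])
        np.testing.assert_allclose(W[1], [0.5, 1.0])
        assert W[0] @ W[1] > 0

    def test_update_increases_pair_objective(self):
        rng = np.random.default_rng(3)
        W = rng.normal(scale=0.3, size=(8, 6))
        before = pair_objective(W, 0, 1, [2, 3, 4])
        mp.sgd_step(W, 0, 1, [2, 3, 4], learning_rate=0.05)
        assert pair_objective(W, 0, 1, [2, 3, 4]) > before

    def test_analytic_gradient_matches_finite_differences(self):
        """Spot check of the negative-sampling gradient (the acceptance
        suite sweeps 100 random configurations)."""
        rng = np.random.default_rng(11)
        W = rng.normal(scale=0.4, size=(7, 5))
        center, context, negs = 0, 1, [2, 3, 1]
        grad_v, targets, grad_t = pair_gradients(W, center, context, negs)
        h = 1e-6
        rows = {center: grad_v.copy()}
        for t, g in zip(targets, grad_t):
            rows[t] = rows.get(t, 0) + g
        for row, analytic in rows.items():
            for k in range(W.shape[1]):
                Wp, Wm = W.copy(), W.copy()
                Wp[row, k] += h
                Wm[row, k] -= h
                fd = (
                    pair_objective(Wp, center, context, negs)
                    - pair_objective(Wm, center, context, negs)
                ) / (2 * h)
                assert abs(fd - analytic[k]) < 1e-5 * max(1.0, abs(fd))


class TestTrain:
    def test_deterministic_given_seed(self, small_corpus):
        cfg = mp.SkipgramConfig(dimension=12, epochs=2, seed=9)
        e1 = mp.train(small_corpus, cfg)
        e2 = mp.train(small_corpus, cfg)
        assert e1.ids == e2.ids
        np.testing.assert_array_equal(e1.vectors, e2.vectors)

    def test_zero_epochs_returns_initialization(self, small_corpus):
        cfg = mp.SkipgramConfig(dimension=12, epochs=0, seed=9)
        emb = mp.train(small_corpus, cfg)
        assert np.abs(emb.vectors).max() <= 0.5 / 12

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            mp.SkipgramConfig(dimension=0)
        with pytest.raises(ValueError):
            mp.SkipgramConfig(noise_exponent=1.5)
        with pytest.raises(ValueError):
            mp.SkipgramConfig(window=0)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mp.train(_corpus([]), mp.SkipgramConfig(dimension=4))

    def test_every_corpus_node_has_finite_vector(self, small_corpus):
        emb = mp.train(small_corpus, mp.SkipgramConfig(dimension=8, epochs=1, seed=0))
        seen = {n for w in small_corpus.walks for n in w}
        assert seen == set(emb.ids)
        assert np.isfinite(emb.vectors).all()

    def test_objective_improves_over_training(self, small_corpus):
        """Mean Eq.-style objective on a held-out pair sample rises from
        the random initialization to the trained embedding."""
        cfg = mp.SkipgramConfig(dimension=16, epochs=3, seed=4)
        init = mp.train(small_corpus, mp.SkipgramConfig(dimension=16, epochs=0, seed=4))
        trained = mp.train(small_corpus, cfg)
        assert init.ids == trained.ids
        idx = init.index
        pairs_all = list(mp.extract_contexts(small_corpus, cfg.window))
        rng = np.random.default_rng(0)
        sample = [pairs_all[i] for i in rng.choice(len(pairs_all), 300, replace=False)]
        by_type = trained.type_vocab()
        counts = {}
        for w in small_corpus.walks:
            for n in w:
                counts[n] = counts.get(n, 0) + 1
        dist = NoiseDistribution(by_type, counts, cfg.noise_exponent)
        pairs_idx, negs_idx = [], []
        for v, c, t in sample:
            pairs_idx.append((idx[v], idx[c]))
            negs_idx.append([idx[u] for u in dist.sample(t, rng, size=cfg.negatives)])
        assert mean_objective(trained, pairs_idx, negs_idx) > mean_objective(
            init, pairs_idx, negs_idx
        )

    def test_training_negatives_always_share_context_type(
        self, small_corpus, monkeypatch
    ):
        """Hard assertion over a full run: every negative row fed to the
        SGD kernel belongs to the same type as its context node."""
        captured = []
        real = skipgram._epoch_kernel

        def spy(W, c, x, negs, *args):
            captured.append((x.copy(), negs.copy()))
            return real(W, c, x, negs, *args)

        monkeypatch.setattr(skipgram, "_epoch_kernel", spy)
        cfg = mp.SkipgramConfig(dimension=8, epochs=2, seed=1)
        emb = mp.train(small_corpus, cfg)
        types = emb.node_types
        assert captured
        for x, negs in captured:
            ctx_types = np.array([types[emb.ids[i]].value for i in x])
            for m in range(negs.shape[1]):
                neg_types = np.array([types[emb.ids[i]].value for i in negs[:, m]])
                assert (neg_types == ctx_types).all()

    def test_planted_cliques_separate(self, two_cliques):
        cfg = mp.WalkConfig(steps_per_walk=6, walks_per_node=60, seed=0)
        corpus = mp.generate_corpus(two_cliques, mp.M1, cfg)
        emb = mp.train(corpus, mp.SkipgramConfig(dimension=16, epochs=3, seed=0))
        a = [f"A{i}" for i in range(1, 6)]
        b = [f"B{i}" for i in range(1, 6)]
        within, between = [], []
        for grp in (a, b):
            for i in range(5):
                for j in range(i + 1, 5):
                    within.append(mp.cosine_similarity(emb.get(grp[i]), emb.get(grp[j])))
        for x in a:
            for y in b:
                between.append(mp.cosine_similarity(emb.get(x), emb.get(y)))
        assert np.mean(within) > np.mean(between)


class TestFullSoftmaxOracle:
    def test_cosine_ranking_agrees_with_full_softmax(self):
        """On a single-type 10-node graph the negative-sampling trainer's
        pairwise-cosine ranking correlates (Spearman > 0.7) with a
        brute-force full-softmax solution of the same objective."""
        # two 5-cliques joined by one bridge edge
        edges = []
        for base in (0, 5):
            for i in range(5):
                for j in range(i + 1, 5):
                    edges.append(
                        mp.TypedEdge(f"n{base + i}", f"n{base + j}", "gene-gene")
                    )
        edges.append(mp.TypedEdge("n4", "n5", "gene-gene"))
        net = mp.build_network(edges)
        gg = mp.MetaPath("GG", (G, G))
        corpus = mp.generate_corpus(
            net, gg, mp.WalkConfig(steps_per_walk=8, walks_per_node=40, seed=0)
        )

        cfg = mp.SkipgramConfig(dimension=8, window=3, epochs=5, seed=2)
        emb = mp.train(corpus, cfg)
        ids = emb.ids
        idx = emb.index

        # independent oracle: full-batch gradient ascent on the exact
        # log-softmax likelihood over the same (center, context) pairs
        rng = np.random.default_rng(5)
        Wo = (rng.random((len(ids), 8)) - 0.5) / 8
        pairs = [(idx[v], idx[c]) for v, c, _ in mp.extract_contexts(corpus, 3)]
        centers = np.array([p[0] for p in pairs])
        contexts = np.array([p[1] for p in pairs])
        for _ in range(150):
            logits = Wo[centers] @ Wo.T  # (n_pairs, vocab)
            logits -= logits.max(axis=1, keepdims=True)
            P = np.exp(logits)
            P /= P.sum(axis=1, keepdims=True)
            G_ctx = -P
            G_ctx[np.arange(len(pairs)), contexts] += 1.0
            grad = np.zeros_like(Wo)
            np.add.at(grad, centers, G_ctx @ Wo)
            grad += G_ctx.T @ Wo[centers]
            Wo += (0.5 / len(pairs)) * grad

        def pair_cosines(Wm):
            out = []
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    out.append(mp.cosine_similarity(Wm[i], Wm[j]))
            return out

        rho = spearmanr(pair_cosines(emb.vectors), pair_cosines(Wo)).statistic
        assert rho > 0.7


class TestEmbeddingIO:
    def test_tsv_roundtrip(self, small_corpus, tmp_path):
        emb = mp.train(small_corpus, mp.SkipgramConfig(dimension=6, epochs=1, seed=0))
        p = tmp_path / "emb.tsv"
        emb.to_tsv(p)
        back = mp.EmbeddingMatrix.from_tsv(p)
        assert back.ids == emb.ids
        np.testing.assert_array_equal(back.vectors, emb.vectors)
        assert p.read_text().startswith("#dim=6\n")
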