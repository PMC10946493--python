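import numpy as np
import pytest

from svcsim.nets import AutoassocNet, CompetitiveNet, HeteroassocNet
from svcsim.patterns import overlap
from svcsim.synth import gen_sparse_patterns


class TestCompetitiveNet:
    def test_single_winner_at_low_sparseness(self, rng):
        net = CompetitiveNet(20, 10, 0.1, rng=rng)
        out = net.infer(rng.random(20))
        assert out.sum() == 1

    def test_inference_is_deterministic(self, rng):
        net = CompetitiveNet(20, 10, 0.2, rng=rng)
        x = rng.random(20)
        assert np.array_equal(net.infer(x), net.infer(x))

    def test_winner_weight_norm_after_update(self, rng):
        net = CompetitiveNet(30, 15, 0.1, learning_rate=0.5, rng=rng)
        x = rng.random(30)
        y = net.learn(x)
        win = np.flatnonzero(y)
        assert np.allclose(np.linalg.norm(net.weights[win], axis=1), 1.0)

    def test_zero_learning_rate_leaves_weights(self, rng):
        net = CompetitiveNet(30, 15, 0.1, learning_rate=0.0, rng=rng)
        w0 = net.weights.copy()
        net.learn(rng.random(30))
        assert np.array_equal(net.weights, w0)

    def test_repeated_input_aligns_winner(self, rng):
        # cosine between the winner's weights and the input grows to ~1
        net = CompetitiveNet(40, 20, 0.05, learning_rate=0.3, rng=rng)
        x = rng.random(40)
        xu = x / np.linalg.norm(x)
        first = None
        for _ in range(100):
            y = net.learn(x)
        win = np.flatnonzero(y)[0]
        assert net.weights[win] @ xu > 0.999

    def test_orthogonal_inputs_get_disjoint_winners(self, rng):
        net = CompetitiveNet(20, 10, 0.2, learning_rate=0.3, rng=rng)
        x1 = np.r_[np.ones(10), np.zeros(10)]
        x2 = np.r_[np.zeros(10), np.ones(10)]
        for _ in range(50):
            net.learn(x1)
            net.learn(x2)
        w1 = set(np.flatnonzero(net.infer(x1)))
        w2 = set(np.flatnonzero(net.infer(x2)))
        assert not w1 & w2


class TestAutoassocNet:
    def test_store_symmetric_zero_diagonal(self, rng):
        net = AutoassocNet(50, 0.1)
        net.store(gen_sparse_patterns(1, 50, 0.1, rng)[0])
        assert np.allclose(net.weights, net.weights.T)
        assert np.all(np.diag(net.weights) == 0)

    def test_storage_is_linear(self, rng):
        p = gen_sparse_patterns(1, 40, 0.1, rng)[0]
        once = AutoassocNet(40, 0.1).store(p)
        twice = AutoassocNet(40, 0.1).store(p).store(p)
        assert np.allclose(twice.weights, 2 * once.weights)

    def test_stored_patterns_are_fixed_points(self):
        net = AutoassocNet(100, 0.1)
        pats = gen_sparse_patterns(5, 100, 0.1, seed=7)
        for p in pats:
            net.store(p)
        for p in pats:
            state, converged = net.retrieve(p, max_iters=20)
            assert converged
            assert overlap(state, p) == pytest.approx(1.0)

    def test_completion_from_quarter_cue(self, rng):
        net = AutoassocNet(100, 0.1)
        p = gen_sparse_patterns(1, 100, 0.1, seed=3)[0]
        net.store(p)
        act = np.flatnonzero(p)
        cue = np.zeros(100)
        cue[act[:3]] = 1.0  # 25% of 10 active units, rest zero
        state, _ = net.retrieve(cue, max_iters=20)
        assert overlap(state, p) == pytest.approx(1.0)

    def test_full_cue_converges_quickly(self):
        net = AutoassocNet(60, 0.1)
        p = gen_sparse_patterns(1, 60, 0.1, seed=1)[0]
        net.store(p)
        state, converged = net.retrieve(p, max_iters=2)
        assert converged and overlap(state, p) == pytest.approx(1.0)

    def test_overload_collapses_retrieval(self):
        # far over capacity the net lands in mixture states: completion
        # quality collapses well below the under-capacity value, though it
        # remains cue-correlated rather than falling to chance
        net = AutoassocNet(50, 0.1)
        pats = gen_sparse_patterns(200, 50, 0.1, seed=0)
        for p in pats:
            net.store(p)
        ovs = [overlap(net.retrieve(pats[i], 20)[0], pats[i]) for i in range(20)]
        assert np.mean(ovs) < 0.6

    def test_sequence_storage_is_asymmetric(self, rng):
        net = AutoassocNet(200, 0.05)
        views = gen_sparse_patterns(3, 200, 0.05, seed=11)
        net.store_sequence(views)
        # forward drive carries the full m-unit signal; backward drive only
        # accidental overlaps, silenced by the activity floor
        floor = 0.5 * 10
        fwd = net.step(views[0], drive_threshold=floor)
        assert overlap(fwd, views[1]) >= 0.9
        back = net.step(views[2], drive_threshold=floor)
        assert overlap(back, views[1]) < 0.5


class TestHeteroassocNet:
    def test_single_pair_recalled_exactly(self, rng):
        pre, post = gen_sparse_patterns(1, 50, 0.1, rng)[0], \
            gen_sparse_patterns(1, 40, 0.1, rng)[0]
        net = HeteroassocNet(50, 40, 0.1).store(pre, post)
        assert np.array_equal(net.recall(pre), post)

    def test_orthogonal_cues_both_recalled(self):
        net = HeteroassocNet(20, 30, 0.1)
        pre1 = np.r_[np.ones(10), np.zeros(10)]
        pre2 = np.r_[np.zeros(10), np.ones(10)]
        post1 = np.zeros(30); post1[:3] = 1.0
        post2 = np.zeros(30); post2[-3:] = 1.0
        net.store(pre1, post1).store(pre2, post2)
        assert np.array_equal(net.recall(pre1), post1)
        assert np.array_equal(net.recall(pre2), post2)

    def test_zero_cue_gives_empty_output(self, rng):
        net = HeteroassocNet(20, 20, 0.1)
        net.store(gen_sparse_patterns(1, 20, 0.2, rng)[0],
                  gen_sparse_patterns(1, 20, 0.1, rng)[0])
        assert not np.any(net.recall(np.zeros(20)))

    def test_half_cue_recovers_single_pair(self, rng):
        pre = gen_sparse_patterns(1, 60, 0.1, seed=5)[0]
        post = gen_sparse_patterns(1, 60, 0.1, seed=6)[0]
        net = HeteroassocNet(60, 60, 0.1).store(pre, post)
        cue = np.zeros(60)
        cue[np.flatnonzero(pre)[:3]] = 1.0
        assert overlap(net.recall(cue), post) == pytest.approx(1.0)

    def test_unrelated_cue_never_fully_retrieves(self):
        # an unrelated cue drives a mixture state: no stored post pattern is
        # spuriously reconstructed at retrieval quality (mean best-match well
        # below the exact-recall value of 1.0)
        net = HeteroassocNet(100, 100, 0.1, rule="covariance")
        pres = gen_sparse_patterns(20, 100, 0.1, seed=8)
        posts = gen_sparse_patterns(20, 100, 0.1, seed=9)
        for a, b in zip(pres, posts):
            net.store(a, b)
        probes = gen_sparse_patterns(10, 100, 0.1, seed=99)
        best = [max(overlap(net.recall(q), b) for b in posts) for q in probes]
        assert np.mean(best) < 0.75
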