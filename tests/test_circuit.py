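import numpy as np
import pytest

from svcsim.circuit import CircuitConfig, Episode, build_circuit
from svcsim.patterns import overlap
from svcsim.synth import gen_correlated_pattern, gen_sparse_patterns


def make_episodes(cfg, n, seed):
    rng = np.random.default_rng(seed)
    whats = gen_sparse_patterns(n, cfg.neocortex_what, cfg.input_sparseness, rng)
    wheres = gen_sparse_patterns(n, cfg.neocortex_where, cfg.input_sparseness, rng)
    return [Episode(w, wh) for w, wh in zip(whats, wheres)]


class TestConstruction:
    def test_same_seed_gives_identical_circuits(self):
        cfg = CircuitConfig(seed=3)
        c1, c2 = build_circuit(cfg), build_circuit(cfg)
        assert np.array_equal(c1.mossy, c2.mossy)
        assert np.array_equal(c1.dg_net.weights, c2.dg_net.weights)
        assert np.array_equal(c1.ec_where_net.weights, c2.ec_where_net.weights)

    def test_zero_mossy_fanin_rejected(self):
        with pytest.raises(ValueError, match="mossy"):
            CircuitConfig(mossy_fanin=0)

    def test_mossy_nonzero_count(self):
        cfg = CircuitConfig()
        circ = build_circuit(cfg)
        assert np.count_nonzero(circ.mossy) == cfg.ca3 * cfg.mossy_fanin

    def test_dg_smaller_than_ca3_rejected(self):
        with pytest.raises(ValueError, match="expansion"):
            CircuitConfig(dg=100, ca3=500)

    def test_bad_sparseness_rejected(self):
        with pytest.raises(ValueError):
            CircuitConfig(ca3_sparseness=1.5)


class TestStoreRecall:
    def test_single_episode_full_where_cue(self):
        cfg = CircuitConfig(seed=0)
        circ = build_circuit(cfg)
        (ep,) = make_episodes(cfg, 1, seed=42)
        circ.store_episode(ep)
        res = circ.recall_from_partial(ep.where, "where")
        assert res.overlaps["what"] == pytest.approx(1.0)
        assert res.overlaps["where"] == pytest.approx(1.0)

    def test_what_cue_recalls_where(self):
        cfg = CircuitConfig(seed=1)
        circ = build_circuit(cfg)
        eps = make_episodes(cfg, 5, seed=43)
        for ep in eps:
            circ.store_episode(ep)
        res = circ.recall_from_partial(eps[2].what, "what", target=2)
        assert res.overlaps["where"] >= 0.9

    def test_reward_stream_recalled(self):
        cfg = CircuitConfig(seed=2)
        circ = build_circuit(cfg)
        rng = np.random.default_rng(0)
        ep = Episode(
            gen_sparse_patterns(1, cfg.neocortex_what, 0.1, rng)[0],
            gen_sparse_patterns(1, cfg.neocortex_where, 0.1, rng)[0],
            gen_sparse_patterns(1, cfg.neocortex_reward, 0.1, rng)[0])
        circ.store_episode(ep)
        res = circ.recall_from_partial(ep.where, "where")
        assert res.overlaps["reward"] == pytest.approx(1.0)

    def test_mossy_weights_untouched_by_store_and_recall(self):
        cfg = CircuitConfig(seed=4)
        circ = build_circuit(cfg)
        checksum = circ.mossy_checksum()
        for ep in make_episodes(cfg, 5, seed=44):
            circ.store_episode(ep)
        circ.recall_from_partial(circ.episodes[0].where, "where")
        assert circ.mossy_checksum() == checksum

    def test_recall_with_empty_circuit_fails(self):
        circ = build_circuit(CircuitConfig())
        with pytest.raises(RuntimeError):
            circ.recall_from_partial(np.ones(200), "where")

    def test_unknown_cue_kind_rejected(self):
        cfg = CircuitConfig()
        circ = build_circuit(cfg)
        circ.store_episode(make_episodes(cfg, 1, 0)[0])
        with pytest.raises(ValueError, match="cue kind"):
            circ.recall_from_partial(np.ones(cfg.neocortex_where), "colour")

    def test_cue_symmetry_between_streams(self):
        # matched layer sizes: recall quality from what cues and where cues
        # should be comparable
        cfg = CircuitConfig(seed=5)
        circ = build_circuit(cfg)
        eps = make_episodes(cfg, 8, seed=45)
        for ep in eps:
            circ.store_episode(ep)
        from_where = np.mean([
            circ.recall_from_partial(eps[i].where, "where", target=i).overlaps["what"]
            for i in range(8)])
        from_what = np.mean([
            circ.recall_from_partial(eps[i].what, "what", target=i).overlaps["where"]
            for i in range(8)])
        assert abs(from_where - from_what) <= 0.1


class TestPatternSeparation:
    def test_mossy_separation_of_correlated_pairs(self):
        # input pairs sharing 80% of active units; frozen competitive maps so
        # the EC correlation is controlled (~0.5)
        diffs = []
        for pair in range(10):
            cfg = CircuitConfig(seed=pair, competitive_lr=0.0, competitive_reps=0)
            circ = build_circuit(cfg)
            rng = np.random.default_rng(500 + pair)
            w1 = gen_sparse_patterns(1, cfg.neocortex_what, 0.1, rng)[0]
            wh1 = gen_sparse_patterns(1, cfg.neocortex_where, 0.1, rng)[0]
            circ.store_episode(Episode(w1, wh1))
            circ.store_episode(Episode(gen_correlated_pattern(w1, 0.8, rng),
                                       gen_correlated_pattern(wh1, 0.8, rng)))
            diffs.append(circ.pattern_separation_index())
        assert np.mean(diffs) < 0.0
        assert np.sum(np.array(diffs) < 0) >= 9

    def test_identical_episodes_no_separation(self):
        cfg = CircuitConfig(seed=0)
        circ = build_circuit(cfg)
        (ep,) = make_episodes(cfg, 1, seed=9)
        circ.store_episode(ep)
        circ.store_episode(ep)
        assert circ.pattern_separation_index() == pytest.approx(0.0)

    def test_needs_two_episodes(self):
        cfg = CircuitConfig()
        circ = build_circuit(cfg)
        circ.store_episode(make_episodes(cfg, 1, 0)[0])
        with pytest.raises(ValueError):
            circ.pattern_separation_index()

    def test_same_where_different_what_get_distinct_ca3(self):
        # frozen competitive maps, as in the separation experiment
        cfg = CircuitConfig(seed=6, competitive_lr=0.0, competitive_reps=0)
        circ = build_circuit(cfg)
        rng = np.random.default_rng(7)
        wh = gen_sparse_patterns(1, cfg.neocortex_where, 0.1, rng)[0]
        w1, w2 = gen_sparse_patterns(2, cfg.neocortex_what, 0.1, rng)
        circ.store_episode(Episode(w1, wh))
        circ.store_episode(Episode(w2, wh))
        s = circ.episode_states
        ec_ov = overlap(s[0]["ec"], s[1]["ec"])
        ca3_ov = overlap(s[0]["ca3"], s[1]["ca3"])
        assert ca3_ov < ec_ov


class TestSequences:
    def test_three_view_sequence_replays_forward(self):
        cfg = CircuitConfig(ca3=200, dg=1000, ca3_sparseness=0.05, seed=0)
        circ = build_circuit(cfg)
        views = gen_sparse_patterns(3, 200, 0.05, seed=21)
        circ.store_view_sequence(views)
        out = circ.recall_view_sequence(views[0])
        assert len(out) == 2
        assert overlap(out[0], views[1]) >= 0.9
        assert overlap(out[1], views[2]) >= 0.9

    def test_reverse_cue_does_not_replay_backward(self):
        cfg = CircuitConfig(ca3=200, dg=1000, ca3_sparseness=0.05, seed=0)
        circ = build_circuit(cfg)
        views = gen_sparse_patterns(3, 200, 0.05, seed=22)
        circ.store_view_sequence(views)
        back = circ.recall_view_sequence(views[2], n_items=1)
        assert overlap(back[0], views[1]) < 0.5

    def test_single_view_gives_empty_continuation(self):
        cfg = CircuitConfig(ca3=200, dg=1000, seed=0)
        circ = build_circuit(cfg)
        views = gen_sparse_patterns(1, 200, 0.05, seed=23)
        circ.store_view_sequence(views)
        assert circ.recall_view_sequence(views[0]) == []

    def test_long_sequence_rejected(self):
        cfg = CircuitConfig(ca3=200, dg=1000, max_sequence_len=8, seed=0)
        circ = build_circuit(cfg)
        views = gen_sparse_patterns(9, 200, 0.05, seed=24)
        with pytest.raises(ValueError, match="short-sequence"):
            circ.store_view_sequence(views)
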