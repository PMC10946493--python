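"""Episodic memory circuit: neocortex -> EC -> DG -> CA3 -> CA1 -> neocortex.

The circuit binds "what", "where" and (optionally) "reward" neocortical
input streams into a single CA3 attractor state and recalls the whole
episode from a partial cue:

* forward path — each neocortical stream drives its own entorhinal (EC)
  segment through a competitive net; the combined EC pattern drives the
  dentate granule layer (competitive, expansion coding); fixed sparse,
  non-modifiable mossy fibers select the CA3 active set at storage
  (pattern separation); the EC->CA3 perforant path is associatively
  modifiable and seeds CA3 at recall;
* CA3 — recurrent autoassociator storing each episode's active set with a
  covariance rule and completing it from partial drive;
* output path — CA1 (competitive, reading CA3 and the direct EC path with
  equal weight) followed by hetero-associative backprojections CA1 -> EC and
  EC -> neocortex that reinstate the original neocortical patterns.

Short view sequences can additionally be stored in the CA3 recurrent
collaterals with a temporally asymmetric rule and replayed forward.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np

from .nets import AutoassocNet, CompetitiveNet, HeteroassocNet
from .patterns import DimensionError, as_pattern, kwta, overlap

__all__ = ["CircuitConfig", "Episode", "RecallResult", "HippocampalCircuit",
           "build_circuit"]


@dataclass(frozen=True)
class CircuitConfig:
    """Layer sizes, sparseness levels and learning parameters.

    Defaults give a desk-scale circuit with a 500-cell CA3 at 5% sparseness
    and the dentate layer larger than CA3 (expansion before CA3).
    """

    neocortex_what: int = 200
    neocortex_where: int = 200
    neocortex_reward: int = 50
    ec_lateral: int = 200
    ec_medial: int = 200
    ec_reward: int = 50
    dg: int = 1000
    ca3: int = 500
    ca1: int = 500
    input_sparseness: float = 0.1
    ec_sparseness: float = 0.05
    dg_sparseness: float = 0.02
    ca3_sparseness: float = 0.05
    ca1_sparseness: float = 0.05
    mossy_fanin: int = 50
    learn_rate: float = 1.0
    competitive_lr: float = 0.3
    competitive_reps: int = 3
    ca1_lr: float = 0.0
    max_iters: int = 20
    max_sequence_len: int = 8
    seed: int = 0

    def __post_init__(self):
        for name in ("input_sparseness", "ec_sparseness", "dg_sparseness",
                     "ca3_sparseness", "ca1_sparseness"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        for name in ("neocortex_what", "neocortex_where",
                     "ec_lateral", "ec_medial", "dg", "ca3", "ca1"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.neocortex_reward < 0 or self.ec_reward < 0:
            raise ValueError("reward layer sizes cannot be negative")
        if (self.neocortex_reward == 0) != (self.ec_reward == 0):
            raise ValueError("reward layers must be both present or both absent")
        if self.dg < self.ca3:
            raise ValueError("dentate layer must be at least as large as CA3 "
                             "(expansion before CA3)")
        if self.mossy_fanin < 1:
            raise ValueError("mossy_fanin must be >= 1: CA3 cannot be driven "
                             "at storage without mossy fibers")
        if self.mossy_fanin > self.dg:
            raise ValueError("mossy_fanin cannot exceed the dentate size")

    @property
    def ec_total(self) -> int:
        return self.ec_lateral + self.ec_medial + self.ec_reward

    def with_(self, **kw) -> "CircuitConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class Episode:
    """One episodic memory: what + where (+ optional reward) input patterns."""
    what: np.ndarray
    where: np.ndarray
    reward: np.ndarray | None = None


@dataclass
class RecallResult:
    """Outcome of a partial-cue recall, with all intermediate layer states."""
    what: np.ndarray
    where: np.ndarray
    reward: np.ndarray
    states: dict = field(default_factory=dict)
    overlaps: dict = field(default_factory=dict)
    converged: bool = True
    target_index: int | None = None


CUE_KINDS = ("what", "where", "reward", "partial-where")


class HippocampalCircuit:
    """Assembled circuit; use :func:`build_circuit` for validated construction."""

    def __init__(self, config: CircuitConfig):
        self.config = config
        c = config
        rng = np.random.default_rng(c.seed)
        # forward competitive stages (neocortex -> EC segments, EC -> DG, -> CA1)
        self.ec_what_net = CompetitiveNet(c.neocortex_what, c.ec_lateral,
                                          c.ec_sparseness, c.competitive_lr, rng)
        self.ec_where_net = CompetitiveNet(c.neocortex_where, c.ec_medial,
                                           c.ec_sparseness, c.competitive_lr, rng)
        self.ec_reward_net = (
            CompetitiveNet(c.neocortex_reward, c.ec_reward, c.ec_sparseness,
                           c.competitive_lr, rng)
            if c.ec_reward > 0 else None)
        self.dg_net = CompetitiveNet(c.ec_total, c.dg, c.dg_sparseness,
                                     c.competitive_lr, rng)
        self.ca1_net = CompetitiveNet(c.ca3 + c.ec_total, c.ca1,
                                      c.ca1_sparseness, c.ca1_lr, rng)
        # fixed random mossy fibers: mossy_fanin connections per CA3 cell with
        # heterogeneous strengths (so the CA3 winner set is not decided by
        # integer-tie index order), never modified after construction
        mossy = np.zeros((c.ca3, c.dg))
        for i in range(c.ca3):
            cols = rng.choice(c.dg, size=c.mossy_fanin, replace=False)
            mossy[i, cols] = rng.uniform(0.5, 1.5, size=c.mossy_fanin)
        self.mossy = mossy
        # associatively modifiable pathways
        self.pp_net = HeteroassocNet(c.ec_total, c.ca3, c.ca3_sparseness,
                                     c.learn_rate, rule="covariance",
                                     pre_sparseness=None)
        self.ca3_net = AutoassocNet(c.ca3, c.ca3_sparseness, c.learn_rate)
        self.bp_ca1_ec = HeteroassocNet(c.ca1, c.ec_total, c.ec_sparseness,
                                        c.learn_rate, rule="covariance")
        self.bp_ec_what = HeteroassocNet(c.ec_total, c.neocortex_what,
                                         c.input_sparseness, c.learn_rate,
                                         rule="covariance")
        self.bp_ec_where = HeteroassocNet(c.ec_total, c.neocortex_where,
                                          c.input_sparseness, c.learn_rate,
                                          rule="covariance")
        self.bp_ec_reward = (
            HeteroassocNet(c.ec_total, c.neocortex_reward, c.input_sparseness,
                           c.learn_rate, rule="covariance")
            if c.neocortex_reward > 0 else None)
        self.episodes: list[Episode] = []
        self.episode_states: list[dict] = []
        self._last_seq_len = 0

    # -- helpers ---------------------------------------------------------

    def mossy_checksum(self) -> str:
        """SHA-256 of the mossy-fiber weight bytes (immutability witness)."""
        return hashlib.sha256(np.ascontiguousarray(self.mossy).tobytes()).hexdigest()

    def _ec_state(self, what=None, where=None, reward=None) -> np.ndarray:
        """Combined EC pattern; absent streams contribute silent segments."""
        c = self.config
        lat = self.ec_what_net.infer(what) if what is not None else np.zeros(c.ec_lateral)
        med = self.ec_where_net.infer(where) if where is not None else np.zeros(c.ec_medial)
        if reward is not None:
            if self.ec_reward_net is None:
                raise ValueError("circuit was built without a reward stream")
            rew = self.ec_reward_net.infer(reward)
        else:
            rew = np.zeros(c.ec_reward)
        return np.concatenate([lat, med, rew])

    def _check_episode(self, ep: Episode) -> Episode:
        c = self.config
        what = as_pattern(ep.what)
        where = as_pattern(ep.where)
        if what.size != c.neocortex_what:
            raise DimensionError("what pattern size mismatch")
        if where.size != c.neocortex_where:
            raise DimensionError("where pattern size mismatch")
        reward = None
        if ep.reward is not None:
            reward = as_pattern(ep.reward)
            if reward.size != c.neocortex_reward:
                raise DimensionError("reward pattern size mismatch")
        return Episode(what, where, reward)

    # -- storage ---------------------------------------------------------

    def store_episode(self, episode: Episode) -> "HippocampalCircuit":
        """One-shot storage of an episode.

        The full forward sweep is computed with the current weights first;
        all weight updates are then applied, so the stored associations refer
        to a single consistent set of layer states.
        """
        c = self.config
        ep = self._check_episode(episode)
        # forward sweep
        ec = self._ec_state(ep.what, ep.where, ep.reward)
        dg = self.dg_net.infer(ec)
        ca3 = kwta(self.mossy @ dg, c.ca3_sparseness)  # mossy drive selects CA3
        ca1 = self.ca1_net.infer(np.concatenate([ca3, ec]))
        # associative updates
        self.ca3_net.store(ca3)
        self.pp_net.store(ec, ca3)
        self.bp_ca1_ec.store(ca1, ec)
        self.bp_ec_what.store(ec, ep.what)
        self.bp_ec_where.store(ec, ep.where)
        if ep.reward is not None:
            self.bp_ec_reward.store(ec, ep.reward)
        # competitive refinement (winners unchanged by their own update)
        for _ in range(c.competitive_reps):
            self.ec_what_net.learn(ep.what)
            self.ec_where_net.learn(ep.where)
            if ep.reward is not None and self.ec_reward_net is not None:
                self.ec_reward_net.learn(ep.reward)
            self.dg_net.learn(ec)
            self.ca1_net.learn(np.concatenate([ca3, ec]))
        self.episodes.append(ep)
        self.episode_states.append(
            {"ec": ec, "dg": dg, "ca3": ca3, "ca1": ca1})
        return self

    # -- recall ----------------------------------------------------------

    def recall_from_partial(self, cue, cue_kind: str,
                            target: int | None = None) -> RecallResult:
        """Recall a whole episode from a cue on one input stream.

        cue_kind is one of ``what``, ``where``, ``reward`` or
        ``partial-where`` (a where cue with only a subset of active units).
        Returns the recalled neocortical patterns, the intermediate layer
        states, and overlaps with the target episode (by default the stored
        episode whose cue-stream pattern best matches the cue).
        """
        if not self.episodes:
            raise RuntimeError("no episodes stored")
        if cue_kind not in CUE_KINDS:
            raise ValueError(f"unknown cue kind {cue_kind!r}")
        stream = "where" if cue_kind == "partial-where" else cue_kind
        cue = as_pattern(cue)
        ec_cue = self._ec_state(**{stream: cue})
        ca3_seed = self.pp_net.recall(ec_cue)
        ca3, converged = self.ca3_net.retrieve(ca3_seed, self.config.max_iters)
        ca1 = self.ca1_net.infer(np.concatenate([ca3, ec_cue]))
        ec_rec = self.bp_ca1_ec.recall(ca1)
        what = self.bp_ec_what.recall(ec_rec)
        where = self.bp_ec_where.recall(ec_rec)
        reward = (self.bp_ec_reward.recall(ec_rec)
                  if self.bp_ec_reward is not None and self.bp_ec_reward.stored_count
                  else np.zeros(self.config.neocortex_reward))
        if target is None:
            target = int(np.argmax([
                overlap(cue, getattr(e, stream)) if getattr(e, stream) is not None
                else -1.0 for e in self.episodes]))
        tgt = self.episodes[target]
        overlaps = {
            "what": overlap(what, tgt.what),
            "where": overlap(where, tgt.where),
            "ca3": overlap(ca3, self.episode_states[target]["ca3"]),
            "ec": overlap(ec_rec, self.episode_states[target]["ec"]),
        }
        if tgt.reward is not None:
            overlaps["reward"] = overlap(reward, tgt.reward)
        states = {"ec_cue": ec_cue, "ca3_seed": ca3_seed, "ca3": ca3,
                  "ca1": ca1, "ec": ec_rec}
        return RecallResult(what, where, reward, states, overlaps,
                            converged, target)

    # -- analysis --------------------------------------------------------

    def pattern_separation_index(self) -> float:
        """Mean pairwise CA3 overlap minus mean pairwise EC overlap over the
        stored episodes (negative = CA3 separates its EC inputs)."""
        if len(self.episode_states) < 2:
            raise ValueError("need at least 2 stored episodes")
        ca3s = [s["ca3"] for s in self.episode_states]
        ecs = [s["ec"] for s in self.episode_states]
        n = len(ca3s)
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        ca3_ov = np.mean([overlap(ca3s[i], ca3s[j]) for i, j in pairs])
        ec_ov = np.mean([overlap(ecs[i], ecs[j]) for i, j in pairs])
        return float(ca3_ov - ec_ov)

    # -- sequences -------------------------------------------------------

    def store_view_sequence(self, views) -> "HippocampalCircuit":
        """Store a short ordered sequence of CA3-sized view patterns with the
        temporally asymmetric rule (item t drives item t+1)."""
        views = [as_pattern(v) for v in views]
        if len(views) > self.config.max_sequence_len:
            raise ValueError(
                f"sequence of {len(views)} items exceeds the short-sequence "
                f"limit ({self.config.max_sequence_len})")
        self.ca3_net.store_sequence(views)
        self._last_seq_len = len(views)
        return self

    def recall_view_sequence(self, first_view, n_items: int | None = None) -> list:
        """Replay a stored sequence forward from its first item.

        Each step is one asymmetric recurrent pass, k-WTA re-thresholded
        with an activity floor at half the full-cue drive so that a cue
        carrying no forward association (e.g. the last item, or a reversed
        cue) yields silence rather than a pattern reconstructed from
        accidental overlaps.  Returns the continuation (excludes the cue);
        empty for a single-item sequence.
        """
        if n_items is None:
            n_items = max(self._last_seq_len - 1, 0)
        c = self.config
        m = int(np.ceil(c.ca3_sparseness * c.ca3))
        floor = 0.5 * self.ca3_net.learn_rate * m
        r = as_pattern(first_view)
        out = []
        for _ in range(n_items):
            r = self.ca3_net.step(r, drive_threshold=floor)
            out.append(r)
        return out


def build_circuit(config: CircuitConfig) -> HippocampalCircuit:
    """Deterministic construction from ``config.seed``."""
    return HippocampalCircuit(config)
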