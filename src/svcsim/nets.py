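"""The three elementary network types the hippocampal circuit is built from.

* :class:`CompetitiveNet` — unsupervised categoriser: k-winners-take-all on a
  feedforward drive, Hebbian learning on the winners with weight-vector
  renormalisation (entorhinal cortex, dentate granule cells, CA1).
* :class:`AutoassocNet` — recurrent attractor memory storing binary patterns
  with a covariance rule and completing them from partial cues by synchronous
  iteration (CA3).  Also supports temporally asymmetric storage for short
  sequences.
* :class:`HeteroassocNet` — one-shot pattern associator mapping a cue layer to
  a target layer (perforant path, Schaffer collaterals, backprojections).

All dynamics use fixed-sparseness k-WTA thresholding in place of explicit
inhibitory feedback; ties are broken by lowest unit index so every operation
is deterministic.  Weights are unbounded reals.
"""

from __future__ import annotations

import numpy as np

from .patterns import DimensionError, as_pattern, kwta

__all__ = ["CompetitiveNet", "AutoassocNet", "HeteroassocNet"]


def _unit_rows(w: np.ndarray, rows=None) -> None:
    """Renormalise (in place) the given rows of w to unit Euclidean norm."""
    if rows is None:
        rows = slice(None)
    norms = np.linalg.norm(w[rows], axis=1, keepdims=True)
    norms[norms == 0.0] = 1.0
    w[rows] = w[rows] / norms


class CompetitiveNet:
    """Competitive network: k-WTA inference, normalised Hebbian learning.

    Every output unit's incoming weight vector is kept at unit Euclidean
    norm, so learning rotates weight vectors toward the inputs a unit wins.

    Parameters
    ----------
    n_in, n_out : layer sizes.
    output_sparseness : fraction of output units active after k-WTA,
        k = ceil(output_sparseness * n_out).
    learning_rate : Hebbian step size.
    rng : seeded generator for the random non-negative initial weights.
    """

    def __init__(self, n_in: int, n_out: int, output_sparseness: float,
                 learning_rate: float = 0.5, rng: np.random.Generator | None = None):
        if not 0.0 < output_sparseness < 1.0:
            raise ValueError("output_sparseness must be in (0,1)")
        if learning_rate < 0.0:
            raise ValueError("learning_rate must be >= 0")
        if rng is None:
            rng = np.random.default_rng()
        self.n_in = int(n_in)
        self.n_out = int(n_out)
        self.output_sparseness = float(output_sparseness)
        self.learning_rate = float(learning_rate)
        self.weights = rng.uniform(0.0, 1.0, size=(self.n_out, self.n_in))
        _unit_rows(self.weights)

    def _check(self, x: np.ndarray) -> np.ndarray:
        x = as_pattern(x)
        if x.size != self.n_in:
            raise DimensionError(f"input length {x.size} != n_in {self.n_in}")
        return x

    def infer(self, x) -> np.ndarray:
        """Binary output: exactly ceil(a*n_out) winners of the drive W·x."""
        x = self._check(x)
        return kwta(self.weights @ x, self.output_sparseness)

    def learn(self, x) -> np.ndarray:
        """One inference + Hebbian update on the winners; returns the output.

        Δw = learning_rate * post * pre on winning rows, then those rows are
        renormalised to unit norm.
        """
        x = self._check(x)
        y = kwta(self.weights @ x, self.output_sparseness)
        if self.learning_rate > 0.0:
            win = np.flatnonzero(y > 0)
            self.weights[win] += self.learning_rate * x[None, :]
            _unit_rows(self.weights, win)
        return y


class AutoassocNet:
    """Autoassociative attractor network with covariance-rule storage.

    Storage of a binary pattern r increments w_ij by
    learn_rate * (r_i - a)(r_j - a) for i != j, which keeps the matrix
    symmetric with a zero diagonal.  Retrieval iterates h = W·r followed by
    k-WTA at the configured sparseness until a fixed point (or max_iters).

    ``rule="hebb"`` (plain r_i r_j) is available as a configuration option;
    the covariance form is the default because the sparse-coding capacity
    scaling assumed throughout holds for it.
    """

    def __init__(self, n: int, sparseness: float, learn_rate: float = 1.0,
                 rule: str = "covariance"):
        if not 0.0 < sparseness < 1.0:
            raise ValueError("sparseness must be in (0,1)")
        if rule not in ("covariance", "hebb"):
            raise ValueError(f"unknown rule {rule!r}")
        self.n = int(n)
        self.sparseness = float(sparseness)
        self.learn_rate = float(learn_rate)
        self.rule = rule
        self.weights = np.zeros((self.n, self.n))
        self.stored_count = 0

    def _check(self, r: np.ndarray) -> np.ndarray:
        r = as_pattern(r)
        if r.size != self.n:
            raise DimensionError(f"pattern length {r.size} != N {self.n}")
        return r

    def store(self, r) -> "AutoassocNet":
        """Store one pattern with the covariance (or Hebb) rule; zero diagonal."""
        r = self._check(r)
        v = r - self.sparseness if self.rule == "covariance" else r
        self.weights += self.learn_rate * np.outer(v, v)
        np.fill_diagonal(self.weights, 0.0)
        self.stored_count += 1
        return self

    def store_sequence(self, patterns) -> "AutoassocNet":
        """Temporally asymmetric storage: Δw_ij = learn_rate · r_i(t+1)·r_j(t).

        Associates each item with its successor so that one recurrent step
        from item t retrieves item t+1 (and not the reverse).  Plain Hebbian
        products are used for the asymmetric rule regardless of the episodic
        storage rule.
        """
        pats = [self._check(p) for p in patterns]
        for prev, nxt in zip(pats[:-1], pats[1:]):
            self.weights += self.learn_rate * np.outer(nxt, prev)
            np.fill_diagonal(self.weights, 0.0)
        self.stored_count += max(len(pats) - 1, 0)
        return self

    def step(self, r, drive_threshold: float | None = None) -> np.ndarray:
        """One synchronous update: k-WTA of the recurrent drive W·r.

        With *drive_threshold*, winners whose drive falls at or below the
        threshold are silenced — an activity floor that stops retrieval when
        the cue carries no real signal (e.g. stepping a stored sequence
        backward, where only accidental pattern overlaps drive the net).
        """
        r = self._check(r)
        h = self.weights @ r
        y = kwta(h, self.sparseness)
        if drive_threshold is not None:
            y = y * (h > drive_threshold)
        return y

    def retrieve(self, cue, max_iters: int = 20) -> tuple[np.ndarray, bool]:
        """Iterate to a fixed point from *cue*; returns (state, converged)."""
        if max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        r = self._check(cue)
        for _ in range(max_iters):
            nxt = kwta(self.weights @ r, self.sparseness)
            if np.array_equal(nxt, r):
                return nxt, True
            r = nxt
        return r, False


class HeteroassocNet:
    """Hetero-associative pattern associator (cue layer -> target layer).

    The default learning rule is the plain Hebbian outer product
    Δw = learn_rate * post ⊗ pre.  ``rule="covariance"`` subtracts the
    expected sparseness from both factors, which removes the crosstalk mean
    and realises the high-capacity regime of sparse pattern association; the
    circuit uses that form for its perforant-path, Schaffer and
    backprojection synapses.
    """

    def __init__(self, n_pre: int, n_post: int, post_sparseness: float,
                 learn_rate: float = 1.0, rule: str = "hebb",
                 pre_sparseness: float | None = None):
        if not 0.0 < post_sparseness < 1.0:
            raise ValueError("post_sparseness must be in (0,1)")
        if rule not in ("hebb", "covariance"):
            raise ValueError(f"unknown rule {rule!r}")
        self.n_pre = int(n_pre)
        self.n_post = int(n_post)
        self.post_sparseness = float(post_sparseness)
        self.pre_sparseness = float(pre_sparseness) if pre_sparseness is not None else None
        self.learn_rate = float(learn_rate)
        self.rule = rule
        self.weights = np.zeros((self.n_post, self.n_pre))
        self.stored_count = 0

    def _check(self, x, n, what) -> np.ndarray:
        x = as_pattern(x)
        if x.size != n:
            raise DimensionError(f"{what} length {x.size} != {n}")
        return x

    def store(self, pre_p, post_p) -> "HeteroassocNet":
        pre = self._check(pre_p, self.n_pre, "pre")
        post = self._check(post_p, self.n_post, "post")
        if self.rule == "covariance":
            a_pre = self.pre_sparseness
            if a_pre is None:
                a_pre = float(np.count_nonzero(pre > 0)) / self.n_pre
            pre = pre - a_pre
            post = post - self.post_sparseness
        self.weights += self.learn_rate * np.outer(post, pre)
        self.stored_count += 1
        return self

    def recall(self, cue) -> np.ndarray:
        """k-WTA of the drive W·cue; an all-zero cue yields an empty output."""
        cue = self._check(cue, self.n_pre, "cue")
        if not np.any(cue):
            return np.zeros(self.n_post)
        return kwta(self.weights @ cue, self.post_sparseness)
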