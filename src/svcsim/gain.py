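"""Gain-modulated coordinate transforms with trace learning.

Three stacked stages turn a retinal signal into an allocentric spatial view
location, each by multiplying a tuned driving input with a tuned modulator
(a gain field) and learning invariant output units with a trace rule:

1. retinal position x eye position      -> head-centred direction
2. head-centred direction x head direction -> allocentric bearing
3. allocentric bearing x place          -> allocentric view location (wall)

The driving and modulating variables are represented by Gaussian population
codes (rings for angles, a grid for place); the pre-synaptic layer is their
outer product; output units are selected by k-winners-take-all and learn
with a Hebbian rule whose post-synaptic term is an exponential trace of
recent activity,

    rbar(t) = (1 - eta) * r(t) + eta * rbar(t-1),

reset between training groups.  Because the invariant quantity (head-centred
direction, bearing, or viewed location) is constant within a group while the
inputs vary, the trace binds the group's input combinations onto a shared
set of output units, producing a code that is invariant to the nuisance
variables — the same slow-learning principle used for transform invariance
in the ventral visual stream.

The module also provides the exact geometric oracle (bearing = head
direction + egocentric direction; wall intersection of the bearing ray) used
to generate training groups and to evaluate decoding, and an idiothetic
update mode that runs the chain along the fovea ray (retinal position 0)
with no visual cue input, emulating spatial-view firing in darkness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arena import Arena, gaze_wall_point, wrap_deg
from .patterns import kwta

__all__ = ["PoseSignals", "GainStage", "TransformChain", "geometric_oracle",
           "invariance_index", "ring_code", "grid_code"]


@dataclass(frozen=True)
class PoseSignals:
    """Input signals for one gaze sample.

    rp: retinal angle of the target from the fovea (deg, signed, clockwise
    positive); ep: eye position in the head (deg, signed); hd: head direction
    (deg from north, clockwise); place: (x, y) in the arena.
    """
    rp: float
    ep: float
    hd: float
    place: tuple


def geometric_oracle(signals: PoseSignals, arena: Arena) -> tuple:
    """Exact transform: (head-centred angle, allocentric bearing, wall coord).

    head_centred = ep + rp; bearing = (hd + head_centred) mod 360;
    view location = perimeter coordinate where the bearing ray from the place
    meets the arena wall.
    """
    x, y = signals.place
    if not arena.contains(x, y):
        raise ValueError("place outside arena")
    head_centred = signals.ep + signals.rp
    bearing = (signals.hd + head_centred) % 360.0
    s = gaze_wall_point(arena, x, y, bearing)
    return float(wrap_deg(head_centred)), float(bearing), float(s)


# -- population codes --------------------------------------------------------

def ring_code(angle_deg, n_centers: int = 36, sigma: float | None = None) -> np.ndarray:
    """Gaussian population code of an angle on a ring of evenly spaced
    centers; sigma defaults to the center spacing."""
    spacing = 360.0 / n_centers
    if sigma is None:
        sigma = spacing
    centers = np.arange(n_centers) * spacing
    d = np.abs((np.asarray(angle_deg, dtype=float) - centers + 180.0) % 360.0 - 180.0)
    code = np.exp(-0.5 * (d / sigma) ** 2)
    return code / np.linalg.norm(code)


def grid_code(xy, side: float, n_per_axis: int = 6,
              sigma: float | None = None) -> np.ndarray:
    """Gaussian population code of a place on an n x n grid of centers;
    sigma defaults to the center spacing."""
    spacing = side / n_per_axis
    if sigma is None:
        sigma = spacing
    c = (np.arange(n_per_axis) + 0.5) * spacing
    cx, cy = np.meshgrid(c, c, indexing="ij")
    d2 = (cx.ravel() - xy[0]) ** 2 + (cy.ravel() - xy[1]) ** 2
    code = np.exp(-0.5 * d2 / sigma ** 2)
    return code / np.linalg.norm(code)


# -- a single gain-modulated stage -------------------------------------------

class GainStage:
    """One gain-field layer: outer product of driving and modulator codes,
    k-WTA output, trace-rule Hebbian learning with renormalisation."""

    def __init__(self, n_drive: int, n_mod: int, n_out: int = 240,
                 sparseness: float = 0.05, eta: float = 0.8,
                 learn_rate: float = 0.2, rng: np.random.Generator | None = None):
        if not 0.0 <= eta < 1.0:
            raise ValueError("trace parameter eta must be in [0,1)")
        if rng is None:
            rng = np.random.default_rng()
        self.n_drive = int(n_drive)
        self.n_mod = int(n_mod)
        self.n_out = int(n_out)
        self.sparseness = float(sparseness)
        self.eta = float(eta)
        self.learn_rate = float(learn_rate)
        self.weights = rng.uniform(0.0, 1.0, size=(self.n_out, self.n_drive * self.n_mod))
        self.weights /= np.linalg.norm(self.weights, axis=1, keepdims=True)
        self.trace = np.zeros(self.n_out)
        self.trained = False

    @staticmethod
    def _pre(drive: np.ndarray, mod: np.ndarray) -> np.ndarray:
        pre = np.outer(drive, mod).ravel()
        n = np.linalg.norm(pre)
        return pre / n if n > 0 else pre

    def infer(self, drive: np.ndarray, mod: np.ndarray) -> np.ndarray:
        """Graded k-WTA output: the k most-driven units keep their drive
        (rectified), all other units are silenced."""
        h = self.weights @ self._pre(drive, mod)
        mask = kwta(h, self.sparseness)
        return np.maximum(h, 0.0) * mask

    def reset_trace(self) -> None:
        self.trace[:] = 0.0

    def present(self, drive: np.ndarray, mod: np.ndarray) -> np.ndarray:
        """One learning presentation: k-WTA output, trace update, Hebbian
        increment with the trace as the post-synaptic term."""
        pre = self._pre(drive, mod)
        h = self.weights @ pre
        y = np.maximum(h, 0.0) * kwta(h, self.sparseness)
        self.trace = (1.0 - self.eta) * y + self.eta * self.trace
        rows = np.flatnonzero(self.trace > 1e-12)
        if rows.size and self.learn_rate > 0.0:
            self.weights[rows] += self.learn_rate * self.trace[rows, None] * pre[None, :]
            norms = np.linalg.norm(self.weights[rows], axis=1, keepdims=True)
            norms[norms == 0.0] = 1.0
            self.weights[rows] /= norms
        self.trained = True
        return y


# -- the full three-stage chain ----------------------------------------------

class TransformChain:
    """Retinal -> head-centred -> bearing -> spatial-view transform chain.

    Training presents each stage with groups in which the stage's invariant
    quantity is held constant while its inputs vary; the trace is reset at
    group boundaries.  After training, an exemplar codebook (sampled output
    codes per invariant-value bin) is built for every stage; decoding is
    k-nearest-exemplar with a similarity-weighted circular mean over bins.
    """

    # signal ranges the chain is trained over
    EP_MAX = 40.0    # |eye position| deg
    RP_MAX = 60.0    # |retinal angle| deg
    HC_MAX = 100.0   # |head-centred gaze angle| deg (= EP_MAX + RP_MAX)

    def __init__(self, arena: Arena, n_ring: int = 36, n_place: int = 8,
                 n_out: int = 320, sparseness: float = 0.06, eta: float = 0.8,
                 n_view_bins: int = 16, seed: int = 0):
        self.arena = arena
        self.n_ring = n_ring
        self.n_place = n_place
        self.n_view_bins = n_view_bins
        self.eta = eta
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.stage1 = GainStage(n_ring, n_ring, n_out, sparseness, eta, rng=rng)
        self.stage2 = GainStage(n_out, n_ring, n_out, sparseness, eta, rng=rng)
        self.stage3 = GainStage(n_out, n_place * n_place, n_out, sparseness,
                                eta, rng=rng)
        self.codebooks: dict = {}
        self.trained = False

    # ..codes..
    def _rp_code(self, rp):
        return ring_code(rp, self.n_ring)

    def _ep_code(self, ep):
        return ring_code(ep, self.n_ring)

    def _hd_code(self, hd):
        return ring_code(hd, self.n_ring)

    def _place_code(self, xy):
        return grid_code(xy, self.arena.side, self.n_place)

    def _s1(self, rp, ep):
        return self.stage1.infer(self._rp_code(rp), self._ep_code(ep))

    def _s2(self, rp, ep, hd):
        return self.stage2.infer(self._s1(rp, ep), self._hd_code(hd))

    def chain_transform(self, signals: PoseSignals) -> np.ndarray:
        """Stage-3 population code for one set of input signals."""
        if not self.trained:
            raise RuntimeError("chain is untrained; call train() first")
        y2 = self._s2(signals.rp, signals.ep, signals.hd)
        return self.stage3.infer(y2, self._place_code(signals.place))

    # ..training..
    def _hc_pairs(self, hc: float, n: int, rng) -> list:
        """(rp, ep) combinations with ep + rp = hc, inside the signal range."""
        lo = max(-self.EP_MAX, hc - self.RP_MAX)
        hi = min(self.EP_MAX, hc + self.RP_MAX)
        eps = rng.uniform(lo, hi, size=n)
        return [(hc - ep, ep) for ep in eps]

    def train(self, n_epochs: int = 8, exemplars: int = 24,
              group_step: float = 5.0, lr_decay: float = 0.7,
              seed: int | None = None) -> "TransformChain":
        """Train the three stages bottom-up on oracle-grouped input streams.

        The learning rate of every stage is multiplied by *lr_decay* after
        each epoch, so early epochs allocate output units to groups and late
        epochs consolidate them.
        """
        rng = np.random.default_rng(self.seed if seed is None else seed)
        hc_max = self.HC_MAX
        hc_values = np.arange(-hc_max, hc_max + 1e-9, group_step)
        bearing_values = np.arange(0.0, 360.0, group_step)
        s_values = (np.arange(self.n_view_bins) + 0.5) * (
            self.arena.perimeter / self.n_view_bins)

        base_lr = {st: st.learn_rate for st in (self.stage1, self.stage2, self.stage3)}

        def set_lr(stage, epoch):
            stage.learn_rate = base_lr[stage] * lr_decay ** epoch

        # stage 1: head-centred direction invariant over (rp, ep)
        for epoch in range(n_epochs):
            set_lr(self.stage1, epoch)
            for hc in rng.permutation(hc_values):
                self.stage1.reset_trace()
                for rp, ep in self._hc_pairs(float(hc), exemplars, rng):
                    self.stage1.present(self._rp_code(rp), self._ep_code(ep))
        # stage 2: bearing invariant over (head direction, head-centred)
        for epoch in range(n_epochs):
            set_lr(self.stage2, epoch)
            for b in rng.permutation(bearing_values):
                self.stage2.reset_trace()
                for _ in range(exemplars):
                    hc = rng.uniform(-hc_max, hc_max)
                    hd = (b - hc) % 360.0
                    rp, ep = self._hc_pairs(hc, 1, rng)[0]
                    self.stage2.present(self._s1(rp, ep), self._hd_code(hd))
        # stage 3: viewed wall location invariant over (place, bearing)
        L = self.arena.side
        s_xy = {}
        for s in s_values:
            wall, t = int(s // L) % 4, s % L
            s_xy[float(s)] = {0: (t, 0.0), 1: (L, t), 2: (L - t, L), 3: (0.0, L - t)}[wall]
        for epoch in range(n_epochs):
            set_lr(self.stage3, epoch)
            for s in rng.permutation(s_values):
                self.stage3.reset_trace()
                tx, ty = s_xy[float(s)]
                for _ in range(exemplars):
                    x = rng.uniform(0.1 * L, 0.9 * L)
                    y = rng.uniform(0.1 * L, 0.9 * L)
                    from .arena import bearing_deg
                    b = bearing_deg(tx - x, ty - y)
                    hc = rng.uniform(-hc_max, hc_max)
                    hd = (b - hc) % 360.0
                    rp, ep = self._hc_pairs(hc, 1, rng)[0]
                    y2 = self.stage2.infer(self._s1(rp, ep), self._hd_code(hd))
                    self.stage3.present(y2, self._place_code((x, y)))
        for st, lr in base_lr.items():
            st.learn_rate = lr
        self.trained = True
        self._build_codebooks(rng, hc_values, bearing_values, s_values,
                              s_xy, exemplars=64)
        return self

    def _build_codebooks(self, rng, hc_values, bearing_values, s_values,
                         s_xy, exemplars: int = 24) -> None:
        """Exemplar codebooks: for each bin of an invariant quantity, a set
        of output codes sampled across the nuisance variables.

        Decoding is nearest-exemplar rather than nearest-mean because the
        code manifold of one bin is multimodal (one mode per region of the
        nuisance space); averaging the modes blurs neighbouring bins
        together.
        """
        hc_max = self.HC_MAX
        from .arena import bearing_deg

        def pack(values, codes, labels):
            codes = np.asarray(codes)
            norms = np.linalg.norm(codes, axis=1, keepdims=True)
            norms[norms == 0.0] = 1.0
            return {"values": np.asarray(values), "codes": codes / norms,
                    "labels": np.asarray(labels, dtype=int)}

        c1, l1 = [], []
        for i, hc in enumerate(hc_values):
            for rp, ep in self._hc_pairs(float(hc), exemplars, rng):
                c1.append(self._s1(rp, ep))
                l1.append(i)
        c2, l2 = [], []
        for i, b in enumerate(bearing_values):
            for _ in range(exemplars):
                hc = rng.uniform(-hc_max, hc_max)
                rp, ep = self._hc_pairs(hc, 1, rng)[0]
                c2.append(self._s2(rp, ep, (b - hc) % 360.0))
                l2.append(i)
        c3, l3 = [], []
        L = self.arena.side
        for i, s in enumerate(s_values):
            tx, ty = s_xy[float(s)]
            for _ in range(exemplars):
                x = rng.uniform(0.1 * L, 0.9 * L)
                y = rng.uniform(0.1 * L, 0.9 * L)
                b = bearing_deg(tx - x, ty - y)
                hc = rng.uniform(-hc_max, hc_max)
                rp, ep = self._hc_pairs(hc, 1, rng)[0]
                y2 = self._s2(rp, ep, (b - hc) % 360.0)
                c3.append(self.stage3.infer(y2, self._place_code((x, y))))
                l3.append(i)
        self.codebooks = {
            "head_centred": pack(hc_values, c1, l1),
            "bearing": pack(bearing_values, c2, l2),
            "view": pack(s_values, c3, l3),
        }

    # ..decoding..
    @staticmethod
    def _decode_bin(code: np.ndarray, book: dict, knn: int = 5) -> int:
        """Decoded bin: similarity-weighted circular mean of the bins of the
        *knn* codebook exemplars most similar (cosine) to *code*; knn=1 is
        plain nearest-exemplar."""
        c = np.asarray(code, dtype=float)
        nc = np.linalg.norm(c)
        if nc > 0:
            c = c / nc
        sims = book["codes"] @ c
        n_bins = len(book["values"])
        if knn <= 1:
            return int(book["labels"][np.argmax(sims)])
        top = np.argsort(-sims)[:knn]
        w = np.maximum(sims[top], 0.0)
        ang = book["labels"][top] * 2.0 * np.pi / n_bins
        mean = np.angle(np.sum(w * np.exp(1j * ang)))
        return int(np.round(mean * n_bins / (2.0 * np.pi))) % n_bins

    def decode_view(self, code: np.ndarray, knn: int = 5) -> float:
        """Decoded wall location (perimeter coordinate) of a stage-3 code."""
        book = self.codebooks["view"]
        return float(book["values"][self._decode_bin(code, book, knn)])

    def view_bin_error(self, code: np.ndarray, s_true: float, knn: int = 5) -> int:
        """Circular distance, in codebook bins, between the decoded and true
        wall locations."""
        book = self.codebooks["view"]
        i = self._decode_bin(code, book, knn)
        values = book["values"]
        j = int(np.argmin(np.abs([
            self.arena.perimeter_distance(v, s_true) for v in values])))
        n = len(values)
        d = abs(i - j) % n
        return min(d, n - d)

    def idiothetic_predict(self, ep: float, hd: float, place) -> float:
        """Run the chain along the fovea ray (rp = 0) with no visual cue
        input and decode the allocentric location the gaze points at —
        spatial-view firing updated purely by the pose signals ("darkness")."""
        code = self.chain_transform(PoseSignals(0.0, ep, hd, tuple(place)))
        return self.decode_view(code)


def invariance_index(codes: np.ndarray, groups: np.ndarray) -> float:
    """1 - (mean within-group variance / between-group variance of the group
    means), clipped to [0, 1].  1 = perfectly invariant code; ~0 when group
    structure explains nothing."""
    codes = np.asarray(codes, dtype=float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if uniq.size < 2:
        raise ValueError("need at least 2 groups")
    grand = codes.mean(axis=0)
    within, between = [], []
    for g in uniq:
        sub = codes[groups == g]
        mu = sub.mean(axis=0)
        within.append(np.mean(np.sum((sub - mu) ** 2, axis=1)))
        between.append(np.sum((mu - grand) ** 2))
    w = float(np.mean(within))
    b = float(np.mean(between))
    if b <= 0:
        return 0.0
    return float(np.clip(1.0 - w / b, 0.0, 1.0))
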