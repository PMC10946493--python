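"""Recall-capacity theory and empirical capacity measurements.

The quantitative theory of recall from the hippocampus to the neocortex says
the number of memories p that can be recalled through the backprojection
pattern associators is

    p = k * C / (a * ln(1/a))

where C is the number of associatively modifiable backprojection synapses
onto each neocortical cell, a is the population sparseness of the
backprojection representation, and k is a prefactor of order 0.2-0.3.  The
same scaling (with C the recurrent synapses per neuron) governs the CA3
attractor itself.

This module evaluates the closed form and measures the matching empirical
quantities in simulation: end-to-end neocortical recall capacity of the full
circuit as a function of backprojection synapse count, and completion
capacity of a stand-alone CA3 autoassociator from half cues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circuit import CircuitConfig, Episode, build_circuit
from .nets import AutoassocNet
from .patterns import overlap
from .synth import gen_sparse_patterns

__all__ = ["CapacityParams", "CapacityCurve", "eq1_recall_capacity",
           "empirical_recall_capacity", "empirical_ca3_capacity"]


@dataclass(frozen=True)
class CapacityParams:
    """Parameters of the backprojection recall-capacity formula."""
    C: int          # associatively modifiable backprojection synapses per cell
    a: float        # population sparseness of the backprojection representation
    k: float = 0.25  # prefactor, order 0.2-0.3

    def __post_init__(self):
        if not 0.0 < self.a < 1.0:
            raise ValueError("sparseness a must be in (0,1)")
        if self.C < 1:
            raise ValueError("C must be >= 1")
        if not 0.0 <= self.k <= 1.0:
            raise ValueError("k must be in [0,1]")


@dataclass
class CapacityCurve:
    """Mean recall overlap (with sd over seeds) as a function of stored count."""
    p_values: np.ndarray
    mean_overlap: np.ndarray
    sd_overlap: np.ndarray
    p_hat: int


def eq1_recall_capacity(params: CapacityParams) -> float:
    """Closed-form recall capacity p = k*C / (a * ln(1/a))."""
    return params.k * params.C / (params.a * np.log(1.0 / params.a))


def _recall_overlap_at_p(config: CircuitConfig, p: int, seed: int,
                         n_probe: int) -> float:
    """Store p what-where episodes, recall a probe sample from full where
    cues, return the mean recalled-what overlap."""
    rng = np.random.default_rng(seed)
    circ = build_circuit(config.with_(seed=seed))
    whats = gen_sparse_patterns(p, config.neocortex_what,
                                config.input_sparseness, rng)
    wheres = gen_sparse_patterns(p, config.neocortex_where,
                                 config.input_sparseness, rng)
    for w, wh in zip(whats, wheres):
        circ.store_episode(Episode(what=w, where=wh))
    probes = rng.choice(p, size=min(n_probe, p), replace=False)
    ovs = [circ.recall_from_partial(wheres[i], "where", target=int(i)).overlaps["what"]
           for i in probes]
    return float(np.mean(ovs))


def empirical_recall_capacity(config: CircuitConfig, criterion: float = 0.75,
                              p_grid=None, seeds=(0, 1, 2), n_probe: int = 20
                              ) -> CapacityCurve:
    """Measure how many episodes survive end-to-end neocortical recall.

    For each p in *p_grid*, p random episodes are stored in a fresh circuit
    and the mean recalled-what overlap from full where cues is measured;
    p_hat is the largest grid value whose mean overlap meets *criterion*.

    The competitive stages are frozen (learning rate 0) for this measurement
    so that the capacity probed is that of the associatively modifiable
    pathways the theory describes, not drift of the competitive maps under
    hundreds of one-shot stores.
    """
    if not 0.0 < criterion < 1.0:
        raise ValueError("criterion must be in (0,1)")
    if p_grid is None:
        theory = eq1_recall_capacity(
            CapacityParams(config.ec_total, config.ec_sparseness))
        p_grid = np.unique(np.maximum(
            np.round(theory * np.array([0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0])), 1
        ).astype(int))
    p_grid = np.asarray(sorted(p_grid), dtype=int)
    if p_grid.size == 0:
        raise ValueError("empty p grid")
    cfg = config.with_(competitive_lr=0.0, competitive_reps=0)
    means = np.empty((p_grid.size, len(seeds)))
    for j, s in enumerate(seeds):
        for i, p in enumerate(p_grid):
            means[i, j] = _recall_overlap_at_p(cfg, int(p), int(s), n_probe)
    mean = means.mean(axis=1)
    sd = means.std(axis=1)
    ok = np.flatnonzero(mean >= criterion)
    p_hat = int(p_grid[ok[-1]]) if ok.size else 0
    return CapacityCurve(p_grid, mean, sd, p_hat)


def empirical_ca3_capacity(config: CircuitConfig, criterion: float = 0.75,
                           p_grid=None, seeds=(0, 1, 2), n_probe: int = 20,
                           cue_fraction: float = 0.5) -> CapacityCurve:
    """Completion capacity of the CA3 autoassociator from partial cues.

    Stores p random binary patterns (CA3 size and sparseness from *config*)
    directly in a fully connected autoassociative net and measures the mean
    completion overlap from cues retaining *cue_fraction* of each target's
    active units.
    """
    if not 0.0 < criterion < 1.0:
        raise ValueError("criterion must be in (0,1)")
    N, a = config.ca3, config.ca3_sparseness
    if p_grid is None:
        theory = eq1_recall_capacity(CapacityParams(N, a))
        p_grid = np.unique(np.maximum(
            np.round(theory * np.array([0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0])), 1
        ).astype(int))
    p_grid = np.asarray(sorted(p_grid), dtype=int)
    if p_grid.size == 0:
        raise ValueError("empty p grid")
    means = np.empty((p_grid.size, len(seeds)))
    for j, s in enumerate(seeds):
        rng = np.random.default_rng(int(s))
        for i, p in enumerate(p_grid):
            net = AutoassocNet(N, a)
            pats = gen_sparse_patterns(int(p), N, a, rng)
            for q in pats:
                net.store(q)
            probes = rng.choice(int(p), size=min(n_probe, int(p)), replace=False)
            ovs = []
            for t in probes:
                act = np.flatnonzero(pats[t] > 0)
                keep = rng.choice(act, size=max(int(round(cue_fraction * act.size)), 1),
                                  replace=False)
                cue = np.zeros(N)
                cue[keep] = 1.0
                state, _ = net.retrieve(cue, config.max_iters)
                ovs.append(overlap(state, pats[t]))
            means[i, j] = float(np.mean(ovs))
    mean = means.mean(axis=1)
    sd = means.std(axis=1)
    ok = np.flatnonzero(mean >= criterion)
    p_hat = int(p_grid[ok[-1]]) if ok.size else 0
    return CapacityCurve(p_grid, mean, sd, p_hat)
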