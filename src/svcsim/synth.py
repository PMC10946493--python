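"""Synthetic input generators.

Everything the simulator consumes is generated here from a seed: random
sparse binary activity patterns (the what/where/reward inputs to the
circuit), wall-landmark arenas, and simulated populations of view-tuned
neurons with trial noise for the information-analysis pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arena import Arena

__all__ = [
    "gen_sparse_patterns",
    "gen_correlated_pattern",
    "gen_arena",
    "SimulatedViewPopulation",
    "gen_view_population",
]


def gen_sparse_patterns(n: int, N: int, a: float, seed=None) -> list[np.ndarray]:
    """*n* random binary patterns of length *N*, each with exactly round(a*N)
    active units placed uniformly at random.

    The active-unit count is deterministic, so population sparseness is
    exactly round(a*N)/N for every pattern.
    """
    if not 0.0 < a <= 1.0:
        raise ValueError("sparseness a must be in (0,1]")
    m = int(round(a * N))
    if m < 1:
        raise ValueError(f"a*N = {a * N:.3g} rounds below one active unit")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pats = []
    for _ in range(n):
        p = np.zeros(N)
        p[rng.choice(N, size=m, replace=False)] = 1.0
        pats.append(p)
    return pats


def gen_correlated_pattern(base: np.ndarray, shared_frac: float,
                           rng: np.random.Generator) -> np.ndarray:
    """A binary pattern sharing *shared_frac* of the base pattern's active
    units, with the remainder redrawn from the inactive units (same count)."""
    base = np.asarray(base, dtype=float)
    act = np.flatnonzero(base > 0)
    inact = np.flatnonzero(base == 0)
    n_keep = int(round(shared_frac * act.size))
    keep = rng.choice(act, size=n_keep, replace=False)
    fresh = rng.choice(inact, size=act.size - n_keep, replace=False)
    p = np.zeros_like(base)
    p[keep] = 1.0
    p[fresh] = 1.0
    return p


def gen_arena(preset: str = "four-wall-12", side: float = 1.0,
              landmarks=None) -> Arena:
    """Build a square arena with wall landmarks.

    Presets mirror an open laboratory lined with discrete visual cues:
    ``four-wall-12`` places 3 evenly spaced cues on each of the 4 walls;
    ``minimal-3`` places a single cue on each of 3 walls.  A custom
    ``landmarks`` list of (wall, position-along-wall) pairs overrides the
    preset; at least 3 landmarks are required.
    """
    if landmarks is None:
        if preset == "four-wall-12":
            # three cues per wall, clustered mid-wall: a cue triple then spans
            # ~0.3 side and is co-visible within a narrow (30 deg) field of
            # view from most of the arena, like discrete cue cards in an
            # open laboratory
            landmarks = [(w, side * f) for w in range(4) for f in (0.35, 0.5, 0.65)]
        elif preset == "minimal-3":
            landmarks = [(0, side * 0.5), (1, side * 0.5), (2, side * 0.5)]
        else:
            raise ValueError(f"unknown preset {preset!r}")
    return Arena(side=side, landmarks=list(landmarks))


@dataclass
class SimulatedViewPopulation:
    """Population of simulated view-tuned cells over S wall locations.

    Each cell has a Gaussian view field (circular over the S locations)
    around its own preferred location, emulating the partly overlapping view
    fields of recorded populations; trial-to-trial variability is Gaussian
    (rectified at zero) or Poisson.
    """

    n_stimuli: int
    n_cells: int
    preferred: np.ndarray      # preferred location index per cell
    tuning_width: float        # sd of the Gaussian tuning, in location units
    peak_rate: float
    noise: str                 # "gaussian" or "poisson"
    noise_sd: float            # sd for gaussian noise (rate units)

    def mean_rates(self) -> np.ndarray:
        """(S, n_cells) noiseless mean response matrix."""
        s = np.arange(self.n_stimuli)[:, None]
        d = np.abs(s - self.preferred[None, :])
        d = np.minimum(d, self.n_stimuli - d)  # circular location distance
        return self.peak_rate * np.exp(-0.5 * (d / self.tuning_width) ** 2)


def gen_view_population(S: int = 16, n_cells: int = 20, trials_per_stimulus: int = 50,
                        tuning_width: float = 1.0, peak_rate: float = 20.0,
                        noise: str = "gaussian", noise_sd: float = 5.0,
                        seed=None):
    """Simulated view-cell population plus a trials x cells response dataset.

    Returns ``(population, responses, labels)`` where *responses* has one row
    per trial and *labels* gives the stimulus (viewed location) index of each
    trial.  Preferred locations are drawn without replacement when the
    population is no larger than the stimulus set, so cells tile the
    locations; with more cells than locations the extras are drawn uniformly.
    """
    if S < 2:
        raise ValueError("need at least 2 stimuli")
    if noise not in ("gaussian", "poisson"):
        raise ValueError(f"unknown noise model {noise!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_cells <= S:
        preferred = rng.choice(S, size=n_cells, replace=False)
    else:
        preferred = np.concatenate([
            rng.permutation(S), rng.integers(0, S, size=n_cells - S)])
    pop = SimulatedViewPopulation(S, n_cells, preferred, tuning_width,
                                  peak_rate, noise, noise_sd)
    means = pop.mean_rates()
    labels = np.repeat(np.arange(S), trials_per_stimulus)
    mu = means[labels]
    if noise == "gaussian":
        responses = np.maximum(mu + rng.normal(0.0, noise_sd, size=mu.shape), 0.0)
    else:
        responses = rng.poisson(mu).astype(float)
    return pop, responses, labels
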