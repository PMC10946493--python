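"""Pattern algebra for sparse firing-rate vectors.

Activity patterns are plain 1-D numpy arrays of non-negative firing rates
(typically binary {0,1}).  The two quantities everything downstream relies on
are the population sparseness

    a = (sum_i r_i)^2 / (N * sum_i r_i^2)

which reduces to (active count)/N for a binary pattern, and cosine overlap,
used throughout as the retrieval-quality metric.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "as_pattern",
    "population_sparseness",
    "overlap",
    "k_winners",
    "kwta",
    "active_count",
]


class SparsenessError(ValueError):
    """Raised when sparseness is undefined (all-zero pattern)."""


class DimensionError(ValueError):
    """Raised on mismatched pattern lengths."""


def as_pattern(rates) -> np.ndarray:
    """Validate and convert *rates* to a float firing-rate vector (all >= 0)."""
    r = np.asarray(rates, dtype=float)
    if r.ndim != 1:
        raise DimensionError(f"pattern must be 1-D, got shape {r.shape}")
    if np.any(r < 0) or not np.all(np.isfinite(r)):
        raise ValueError("firing rates must be finite and non-negative")
    return r


def population_sparseness(rates) -> float:
    """Population sparseness a = (Σr)² / (N·Σr²), in (0, 1].

    For a binary pattern with m active units out of N this is exactly m/N.
    Raises :class:`SparsenessError` for an all-zero pattern.
    """
    r = as_pattern(rates)
    ssq = float(np.dot(r, r))
    if ssq == 0.0:
        raise SparsenessError("sparseness undefined for an all-zero pattern")
    return float(r.sum()) ** 2 / (r.size * ssq)


def overlap(p, q) -> float:
    """Cosine similarity between two rate vectors; 0 if either is all-zero."""
    a = as_pattern(p)
    b = as_pattern(q)
    if a.size != b.size:
        raise DimensionError(f"length mismatch: {a.size} vs {b.size}")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def k_winners(drive: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k most-driven units; ties broken by lowest unit index.

    Deterministic: sorts on (-drive, index) so that among equal drives the
    lower-indexed unit wins.
    """
    h = np.asarray(drive, dtype=float)
    if k <= 0:
        return np.empty(0, dtype=int)
    k = min(k, h.size)
    order = np.lexsort((np.arange(h.size), -h))
    return np.sort(order[:k])


def kwta(drive: np.ndarray, sparseness: float) -> np.ndarray:
    """Binary k-winners-take-all output with k = ceil(sparseness * N)."""
    h = np.asarray(drive, dtype=float)
    k = int(np.ceil(sparseness * h.size))
    out = np.zeros(h.size, dtype=float)
    out[k_winners(h, k)] = 1.0
    return out


def active_count(rates) -> int:
    """Number of strictly positive rates."""
    return int(np.count_nonzero(np.asarray(rates, dtype=float) > 0))
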