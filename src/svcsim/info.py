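"""Population information from biologically plausible decoding.

Pipeline: simulated (or any) trials x cells response matrix with stimulus
labels -> leave-one-out dot-product decoding (each held-out trial is assigned
the stimulus whose mean training response vector is most similar) ->
confusion matrix of (true, decoded) counts -> plug-in Shannon mutual
information in bits.  Information-versus-ensemble-size curves average the
information over random cell subsets of each size.

Cosine similarity is the default "dot product" to remove overall rate-scale
confounds; the raw dot product is available by flag.  The plug-in information
estimator is used without bias correction; an optional jackknife correction
(Miller-Madow-style leave-one-out) is available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ResponseDataset", "dot_product_decode", "confusion_from_dataset",
           "info_from_confusion", "info_vs_ensemble", "single_cell_info"]


@dataclass
class ResponseDataset:
    """Trials x cells firing rates with a stimulus label per trial."""
    responses: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.responses = np.asarray(self.responses, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.responses.ndim != 2:
            raise ValueError("responses must be trials x cells")
        if self.labels.size != self.responses.shape[0]:
            raise ValueError("one label per trial required")
        if np.any(self.responses < 0):
            raise ValueError("rates must be non-negative")
        _, counts = np.unique(self.labels, return_counts=True)
        if np.any(counts < 2):
            raise ValueError("need at least 2 trials per stimulus")

    @property
    def n_stimuli(self) -> int:
        return int(np.unique(self.labels).size)

    @property
    def n_cells(self) -> int:
        return int(self.responses.shape[1])

    def subset(self, cells) -> "ResponseDataset":
        return ResponseDataset(self.responses[:, np.asarray(cells)], self.labels)


def dot_product_decode(train_responses: np.ndarray, train_labels: np.ndarray,
                       test_vector: np.ndarray, metric: str = "cosine") -> int:
    """Predict the stimulus of *test_vector* from per-stimulus mean training
    vectors by maximum similarity; ties go to the lowest stimulus index."""
    train_responses = np.asarray(train_responses, dtype=float)
    train_labels = np.asarray(train_labels, dtype=int)
    stimuli = np.unique(train_labels)
    means = np.stack([train_responses[train_labels == s].mean(axis=0)
                      for s in stimuli])
    test_vector = np.asarray(test_vector, dtype=float)
    if metric not in ("cosine", "dot"):
        raise ValueError(f"unknown metric {metric!r}")
    if means.shape[1] == 1:
        # angular similarity is undefined in one dimension: decode a single
        # cell by nearest mean rate
        sims = -np.abs(means[:, 0] - test_vector[0])
    else:
        sims = means @ test_vector
        if metric == "cosine":
            norms = np.linalg.norm(means, axis=1) * (np.linalg.norm(test_vector) + 1e-300)
            sims = np.divide(sims, norms, out=np.zeros_like(sims), where=norms > 0)
        # among (near-)tied similarities — e.g. all mean vectors pointing the
        # same way, as with duplicated cells — prefer the nearest mean by
        # Euclidean distance, so amplitude information is not discarded
        tied = sims >= sims.max() - 1e-9
        if tied.sum() > 1:
            d2 = np.sum((means - test_vector) ** 2, axis=1)
            sims = np.where(tied, -d2, -np.inf)
    # argmax returns the first (lowest-index) maximum, which is the tie rule
    return int(stimuli[np.argmax(sims)])


def _loo_confusion(responses: np.ndarray, labels: np.ndarray,
                   metric: str = "cosine") -> np.ndarray:
    """Vectorised leave-one-out confusion matrix (S x S counts)."""
    stimuli, inv = np.unique(labels, return_inverse=True)
    S = stimuli.size
    n_per = np.bincount(inv)
    sums = np.zeros((S, responses.shape[1]))
    np.add.at(sums, inv, responses)
    # per-trial class means with the trial itself removed from its own class
    means = sums[None, :, :] / n_per[None, :, None]          # (1, S, cells)
    means = np.broadcast_to(means, (responses.shape[0], S, responses.shape[1])).copy()
    own = (sums[inv] - responses) / (n_per[inv] - 1)[:, None]
    means[np.arange(responses.shape[0]), inv] = own
    if responses.shape[1] == 1:
        # single cell: nearest mean rate (see dot_product_decode)
        sims = -np.abs(means[:, :, 0] - responses[:, 0:1])
    else:
        sims = np.einsum("tsc,tc->ts", means, responses)
        if metric == "cosine":
            norms = (np.linalg.norm(means, axis=2)
                     * (np.linalg.norm(responses, axis=1)[:, None] + 1e-300))
            sims = np.divide(sims, norms, out=np.zeros_like(sims), where=norms > 0)
        # Euclidean tie-break among (near-)equal similarities, as in
        # dot_product_decode
        tied = sims >= sims.max(axis=1, keepdims=True) - 1e-9
        if np.any(tied.sum(axis=1) > 1):
            d2 = np.sum((means - responses[:, None, :]) ** 2, axis=2)
            sims = np.where(tied, -d2, -np.inf)
    decoded = np.argmax(sims, axis=1)
    cm = np.zeros((S, S), dtype=int)
    np.add.at(cm, (inv, decoded), 1)
    return cm


def confusion_from_dataset(ds: ResponseDataset, metric: str = "cosine") -> np.ndarray:
    """Leave-one-out cross-validated confusion matrix: rows = true stimulus,
    columns = decoded stimulus, entries = held-out trial counts."""
    return _loo_confusion(ds.responses, ds.labels, metric)


def info_from_confusion(cm: np.ndarray, jackknife: bool = False) -> float:
    """Plug-in Shannon mutual information (bits) of a confusion matrix:
    I = sum P(s,s') log2[P(s,s') / (P(s)P(s'))], with 0 log 0 = 0.

    With ``jackknife=True`` a leave-one-trial-out jackknife bias correction
    is applied to the plug-in estimate.
    """
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")

    def plugin(counts):
        n = counts.sum()
        pj = counts / n
        ps = pj.sum(axis=1, keepdims=True)
        pd = pj.sum(axis=0, keepdims=True)
        denom = ps @ pd
        nz = pj > 0
        return float(np.sum(pj[nz] * np.log2(pj[nz] / denom[nz])))

    est = plugin(cm)
    if not jackknife:
        return est
    n = int(total)
    loo = []
    rows, cols = np.nonzero(cm)
    for r, c in zip(rows, cols):
        cm2 = cm.copy()
        cm2[r, c] -= 1
        loo.append(plugin(cm2) * cm[r, c])
    mean_loo = float(np.sum(loo)) / n
    return n * est - (n - 1) * mean_loo


def info_vs_ensemble(ds: ResponseDataset, sizes, n_resamples: int = 5,
                     seed=None, metric: str = "cosine"):
    """Mean information (bits) as a function of ensemble size.

    For each size, *n_resamples* random cell subsets are drawn (seeded) and
    the leave-one-out decoded information is averaged.  Returns
    ``(sizes, mean_bits)`` arrays.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sizes = np.asarray(sizes, dtype=int)
    if np.any(sizes < 1) or np.any(sizes > ds.n_cells):
        raise ValueError("ensemble sizes must be in [1, n_cells]")
    means = []
    for size in sizes:
        vals = []
        for _ in range(n_resamples):
            cells = rng.choice(ds.n_cells, size=int(size), replace=False)
            vals.append(info_from_confusion(
                confusion_from_dataset(ds.subset(cells), metric)))
        means.append(float(np.mean(vals)))
    return sizes, np.asarray(means)


def single_cell_info(ds: ResponseDataset, cell: int,
                     metric: str = "cosine") -> float:
    """Information carried by one cell's responses alone (0 for a constant
    cell, which decodes every trial to the same stimulus)."""
    return info_from_confusion(confusion_from_dataset(ds.subset([cell]), metric))
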