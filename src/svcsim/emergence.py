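"""Emergence of place cells versus spatial view cells from the field of view.

An agent visits every place on a grid and every head direction in a
landmark-lined arena.  Model hippocampal cells are driven by conjunctions of
three or more landmark cues that fall inside the field of view alpha, with
Gaussian tuning to the angles subtended between the cues as seen from the
agent; templates are acquired by competitive learning over the pose stream.

Because the subtended angle between two landmarks depends only on the
agent's place (not its head direction), a wide field of view (270 deg, the
rodent condition) keeps a cell's cue conjunction visible across most head
directions and yields place fields, whereas a narrow field of view (30 deg,
the primate foveate condition) ties firing to gazing at a particular wall
region and yields spatial view fields.  Cells are classified by comparing
the spatial information of their place map against that of their
wall-unrolled view map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .arena import Arena, AgentPose, CueView, gaze_wall_points, landmark_bearings

__all__ = ["AngleTemplate", "FieldMaps", "cell_response", "train_population",
           "compute_field_maps", "classify_cell", "spatial_information",
           "fov_experiment", "pose_geometry"]


@dataclass
class AngleTemplate:
    """Cell model: a conjunction of >=3 landmark cues with reference
    subtended angles between each pair, Gaussian tuning width sigma_phi."""

    cue_ids: tuple            # >=3 landmark ids, ascending
    pair_angles: np.ndarray   # reference angle (deg, [0,180]) per cue pair
    sigma_phi: float = 10.0
    gain: float = 1.0

    def __post_init__(self):
        self.cue_ids = tuple(sorted(int(i) for i in self.cue_ids))
        if len(self.cue_ids) < 3:
            raise ValueError("a cell conjunction needs at least 3 cues")
        if self.sigma_phi <= 0:
            raise ValueError("sigma_phi must be positive")
        self.pair_angles = np.asarray(self.pair_angles, dtype=float)
        n_pairs = len(self.cue_ids) * (len(self.cue_ids) - 1) // 2
        if self.pair_angles.size != n_pairs:
            raise ValueError("need one reference angle per cue pair")

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return list(combinations(self.cue_ids, 2))


def _pair_separation(b1, b2):
    """Angular separation of two bearings, in [0, 180]."""
    d = np.abs(np.asarray(b1) - np.asarray(b2)) % 360.0
    return np.minimum(d, 360.0 - d)


def cell_response(cell: AngleTemplate, cues: list[CueView]) -> float:
    """Firing rate of *cell* given the currently visible cues.

    Zero unless at least 3 of the cell's cue ids are visible; otherwise
    gain times the product of Gaussian matches between the observed and
    reference subtended angles over all co-visible cue pairs.
    """
    bear = {c.landmark_id: c.allocentric for c in cues}
    visible = [i for i in cell.cue_ids if i in bear]
    if len(visible) < 3:
        return 0.0
    rate = cell.gain
    for k, (i, j) in enumerate(cell.pairs):
        if i in bear and j in bear:
            d = _pair_separation(bear[i], bear[j]) - cell.pair_angles[k]
            rate *= float(np.exp(-0.5 * (d / cell.sigma_phi) ** 2))
    return rate


# -- vectorised geometry ---------------------------------------------------

def pose_geometry(arena: Arena, poses: np.ndarray, fov: float) -> dict:
    """Precompute, for every pose: bearings to all landmarks, the visibility
    mask for the given field of view, and the gaze ray's wall point."""
    poses = np.asarray(poses, dtype=float)
    xy = poses[:, :2]
    theta = poses[:, 2]
    bearings = landmark_bearings(arena, xy)
    ego = (bearings - theta[:, None] + 180.0) % 360.0 - 180.0
    visible = np.abs(ego) <= fov / 2.0
    gaze_s = gaze_wall_points(arena, xy, theta)
    return {"poses": poses, "bearings": bearings, "visible": visible,
            "gaze_s": gaze_s, "fov": fov}


def _population_arrays(cells: list[AngleTemplate]):
    ids = np.array([c.cue_ids for c in cells])             # (n_cells, ncue)
    n = ids.shape[1]
    pidx = np.array(list(combinations(range(n), 2)))       # (n_pairs, 2)
    refs = np.array([c.pair_angles for c in cells])        # (n_cells, n_pairs)
    sigma = np.array([c.sigma_phi for c in cells])
    gain = np.array([c.gain for c in cells])
    return ids, pidx, refs, sigma, gain


def response_matrix(cells: list[AngleTemplate], geom: dict,
                    chunk: int = 4096) -> np.ndarray:
    """(n_poses, n_cells) firing rates, computed in pose chunks."""
    ids, pidx, refs, sigma, gain = _population_arrays(cells)
    M = geom["poses"].shape[0]
    out = np.empty((M, len(cells)))
    for lo in range(0, M, chunk):
        hi = min(lo + chunk, M)
        b = geom["bearings"][lo:hi][:, ids]                # (m, n_cells, ncue)
        vis = geom["visible"][lo:hi][:, ids].all(axis=2)   # (m, n_cells)
        sep = _pair_separation(b[:, :, pidx[:, 0]], b[:, :, pidx[:, 1]])
        z = (sep - refs[None]) / sigma[None, :, None]
        out[lo:hi] = gain[None] * np.exp(-0.5 * (z ** 2).sum(axis=2)) * vis
    return out


# -- learning --------------------------------------------------------------

def train_population(arena: Arena, poses: np.ndarray, fov: float,
                     n_cells: int, learn_rate: float = 0.1,
                     sigma_phi: float = 10.0, n_train: int | None = None,
                     seed=None) -> list[AngleTemplate]:
    """Acquire a population of cue-conjunction templates by competitive
    learning over the pose stream.

    Templates are initialised from randomly sampled poses (a random visible
    cue triple and its observed subtended angles), then refined over a
    shuffled pass through the poses: at each pose the most active cell wins
    and its reference angles move toward the observed configuration.
    Deterministic given the seed.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if arena.n_landmarks < 3:
        raise ValueError("arena needs at least 3 landmarks")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    geom = pose_geometry(arena, poses, fov)
    M = geom["poses"].shape[0]
    usable = np.flatnonzero(geom["visible"].sum(axis=1) >= 3)
    if usable.size == 0:
        raise ValueError("no pose has 3 visible cues at this field of view")

    # data-driven initialisation
    cells: list[AngleTemplate] = []
    init_poses = rng.choice(usable, size=n_cells, replace=usable.size < n_cells)
    for p in init_poses:
        vis_ids = np.flatnonzero(geom["visible"][p])
        trio = np.sort(rng.choice(vis_ids, size=3, replace=False))
        b = geom["bearings"][p, trio]
        angles = [_pair_separation(b[i], b[j]) for i, j in combinations(range(3), 2)]
        cells.append(AngleTemplate(tuple(trio), np.array(angles), sigma_phi))

    # competitive refinement
    ids, pidx, refs, sigma, gain = _population_arrays(cells)
    order = rng.permutation(usable)
    if n_train is not None:
        order = order[:n_train]
    for p in order:
        b = geom["bearings"][p][ids]                        # (n_cells, 3)
        vis = geom["visible"][p][ids].all(axis=1)
        if not vis.any():
            continue
        sep = _pair_separation(b[:, pidx[:, 0]], b[:, pidx[:, 1]])
        z = (sep - refs) / sigma[:, None]
        rates = gain * np.exp(-0.5 * (z ** 2).sum(axis=1)) * vis
        w = int(np.argmax(rates))
        if rates[w] <= 0.0:
            continue
        refs[w] += learn_rate * (sep[w] - refs[w])
    for c, r in zip(cells, refs):
        c.pair_angles = r
    return cells


# -- rate maps and classification ------------------------------------------

@dataclass
class FieldMaps:
    """Place map, wall-unrolled view map and summary statistics for one cell."""
    place_map: np.ndarray          # (grid_n, grid_n) mean rate over theta
    view_map: np.ndarray           # (n_view_bins,) mean rate per wall bin
    view_occupancy: np.ndarray     # gaze samples per wall bin
    place_info: float              # bits
    view_info: float               # bits
    directionality: float          # 1 - mean/max of the head-direction tuning
    label: str = "unclassified"
    extras: dict = field(default_factory=dict)


def spatial_information(rates: np.ndarray, occupancy: np.ndarray) -> float:
    """Skaggs-style spatial information (bits) of a rate map:
    sum_i p_i (lambda_i/lambda) log2(lambda_i/lambda), 0*log0 = 0."""
    lam = np.asarray(rates, dtype=float).ravel()
    occ = np.asarray(occupancy, dtype=float).ravel()
    tot = occ.sum()
    if tot <= 0:
        return 0.0
    p = occ / tot
    mean = float(np.dot(p, lam))
    if mean <= 0:
        return 0.0
    ratio = lam / mean
    nz = (ratio > 0) & (p > 0)
    return float(np.sum(p[nz] * ratio[nz] * np.log2(ratio[nz])))


def compute_field_maps(rates: np.ndarray, geom: dict, arena: Arena,
                       grid_n: int, n_view_bins: int = 36,
                       info_grid: int = 6) -> FieldMaps:
    """Build place and view maps for one cell from its per-pose rates.

    The place map averages rate over head direction at each grid place;
    the view map accumulates rate at the wall bin hit by the gaze ray
    (head-direction ray), normalised by how often each bin is gazed at.

    The spatial information used for classification is computed on
    matched-capacity maps — an ``info_grid`` x ``info_grid`` place binning
    against ``n_view_bins`` wall bins (36 bins each by default) — because
    Skaggs information grows with bin count and the native place map has far
    more bins than the wall map.
    """
    poses = geom["poses"]
    M = poses.shape[0]
    if M == 0:
        raise ValueError("empty pose stream")
    rates = np.asarray(rates, dtype=float)
    n_dir = M // (grid_n * grid_n)
    place_map = rates.reshape(grid_n, grid_n, n_dir).mean(axis=2)

    bins = np.minimum((geom["gaze_s"] / arena.perimeter * n_view_bins).astype(int),
                      n_view_bins - 1)
    occ = np.bincount(bins, minlength=n_view_bins).astype(float)
    tot = np.bincount(bins, weights=rates, minlength=n_view_bins)
    view_map = np.divide(tot, occ, out=np.zeros(n_view_bins), where=occ > 0)

    tuning = rates.reshape(-1, n_dir).mean(axis=0)
    peak = tuning.max()
    directionality = float(1.0 - tuning.mean() / peak) if peak > 0 else 0.0

    # matched-capacity information: coarse place bins vs wall bins
    ix = np.minimum((poses[:, 0] / arena.side * info_grid).astype(int), info_grid - 1)
    iy = np.minimum((poses[:, 1] / arena.side * info_grid).astype(int), info_grid - 1)
    pbin = ix * info_grid + iy
    pocc = np.bincount(pbin, minlength=info_grid ** 2).astype(float)
    ptot = np.bincount(pbin, weights=rates, minlength=info_grid ** 2)
    coarse = np.divide(ptot, pocc, out=np.zeros(info_grid ** 2), where=pocc > 0)

    p_info = spatial_information(coarse, pocc)
    v_info = spatial_information(view_map, occ)
    return FieldMaps(place_map, view_map, occ, p_info, v_info, directionality,
                     extras={"coarse_place_map": coarse.reshape(info_grid, info_grid)})


def classify_cell(maps: FieldMaps, ratio_threshold: float = 2.0,
                  min_mean_rate: float = 1e-6) -> str:
    """Label a cell place/view/mixed/unresponsive by comparing the spatial
    information of its place map and its view map (default 2x ratio)."""
    if maps.place_map.mean() < min_mean_rate and maps.view_map.mean() < min_mean_rate:
        maps.label = "unresponsive"
    elif maps.view_info >= ratio_threshold * maps.place_info:
        maps.label = "view"
    elif maps.place_info >= ratio_threshold * maps.view_info:
        maps.label = "place"
    else:
        maps.label = "mixed"
    return maps.label


def fov_experiment(arena: Arena, fov: float, grid_n: int = 40,
                   dtheta: float = 15.0, n_cells: int = 100, seed=0,
                   n_view_bins: int = 40, ratio_threshold: float = 2.0,
                   n_train: int | None = None) -> dict:
    """Train a population at the given field of view and classify every cell.

    Returns a summary dict with the label counts, per-cell information
    values, and the trained population.
    """
    from .arena import enumerate_poses
    poses = enumerate_poses(arena, grid_n, dtheta)
    cells = train_population(arena, poses, fov, n_cells, seed=seed,
                             n_train=n_train)
    geom = pose_geometry(arena, poses, fov)
    R = response_matrix(cells, geom)
    labels, p_infos, v_infos = [], [], []
    for j in range(len(cells)):
        maps = compute_field_maps(R[:, j], geom, arena, grid_n, n_view_bins)
        labels.append(classify_cell(maps, ratio_threshold))
        p_infos.append(maps.place_info)
        v_infos.append(maps.view_info)
    labels = np.array(labels)
    counts = {lab: int((labels == lab).sum())
              for lab in ("place", "view", "mixed", "unresponsive")}
    responsive = len(cells) - counts["unresponsive"]
    return {
        "fov": fov,
        "counts": counts,
        "n_cells": len(cells),
        "n_responsive": responsive,
        "frac_place": counts["place"] / responsive if responsive else 0.0,
        "frac_view": counts["view"] / responsive if responsive else 0.0,
        "place_info": np.array(p_infos),
        "view_info": np.array(v_infos),
        "labels": labels,
        "cells": cells,
    }
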