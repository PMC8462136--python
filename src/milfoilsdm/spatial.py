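"""Spatial statistics shared by modelling and evaluation.

Distance-band inverse-distance neighbor weights, the spatial
autocovariate (distance-weighted mean of neighboring responses), global
Moran's I with a permutation test, the pair correlation function g(r)
for point patterns, and spatial block fold assignment for blocked
cross-validation. Coordinates are planar (km); no geodesy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree

log = logging.getLogger(__name__)

__all__ = [
    "SpatialWeights",
    "BlockAssignment",
    "MoranResult",
    "build_weights",
    "autocovariate",
    "cross_autocovariate",
    "attach_autocovariate",
    "morans_i",
    "pair_correlation",
    "assign_blocks",
]


@dataclass
class SpatialWeights:
    """Distance-band neighborhood with inverse-distance weights.

    ``W`` holds the raw weights w_ij = 1/d_ij for pairs within the
    radius (symmetric, zero diagonal); ``row_standardized`` divides each
    row by its sum so the autocovariate is a weighted mean.
    """

    coords: np.ndarray
    W: sparse.csr_matrix
    radius: float
    ids: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.W.shape[0]

    @property
    def row_standardized(self) -> sparse.csr_matrix:
        rowsum = np.asarray(self.W.sum(axis=1)).ravel()
        inv = sparse.diags(1.0 / rowsum)
        return (inv @ self.W).tocsr()

    def to_triplet_csv(self, path) -> None:
        coo = self.W.tocoo()
        pd.DataFrame({"i": coo.row, "j": coo.col, "w": coo.data}).to_csv(path, index=False)


@dataclass
class MoranResult:
    I: float
    p: float
    n_perm: int


@dataclass
class BlockAssignment:
    """Square-grid spatial blocks mapped to cross-validation folds."""

    block_side: float
    df: pd.DataFrame  # columns: block, fold (indexed like the input coords)

    @property
    def folds(self) -> np.ndarray:
        return self.df["fold"].to_numpy()

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def build_weights(coords, radius="auto", ids=None) -> SpatialWeights:
    """Inverse-distance weights over a distance-band neighborhood.

    radius="auto" uses the maximum nearest-neighbor distance — the
    smallest band giving every point at least one neighbor. Duplicate
    coordinates make 1/d undefined and are rejected.
    """
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 2:
        raise ValueError("need at least 2 points")
    tree = cKDTree(coords)
    nn_d, _ = tree.query(coords, k=2)
    if np.any(nn_d[:, 1] == 0):
        raise ValueError(
            "duplicate coordinates found (zero distance); jitter the points "
            "before building inverse-distance weights"
        )
    if radius == "auto":
        # tiny inflation so the defining max-NN pair survives fp rounding
        radius = float(nn_d[:, 1].max()) * (1 + 1e-9)
    radius = float(radius)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    if len(pairs) == 0:
        raise ValueError("radius too small: no neighbor pairs")
    d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    i = np.concatenate([pairs[:, 0], pairs[:, 1]])
    j = np.concatenate([pairs[:, 1], pairs[:, 0]])
    w = np.concatenate([1.0 / d, 1.0 / d])
    W = sparse.coo_matrix((w, (i, j)), shape=(len(coords), len(coords))).tocsr()
    deg = np.asarray((W != 0).sum(axis=1)).ravel()
    if np.any(deg == 0):
        raise ValueError(
            f"{int((deg == 0).sum())} point(s) have no neighbor within radius "
            f"{radius}; enlarge the radius or use radius='auto'"
        )
    return SpatialWeights(coords=coords, W=W, radius=radius,
                          ids=None if ids is None else np.asarray(ids))


def autocovariate(weights: SpatialWeights, response) -> np.ndarray:
    """Row-standardized distance-weighted mean of neighbors' responses.

    ac_i = sum_j w_ij y_j / sum_j w_ij; bounded by the range of the
    neighbors' response values.
    """
    y = np.asarray(response, dtype=float)
    if len(y) != weights.n:
        raise ValueError("response length does not match weights")
    return np.asarray(weights.row_standardized @ y)


def cross_autocovariate(target_coords, source_coords, source_response, radius="auto"):
    """Autocovariate of target points from responses observed at source points.

    Inverse-distance weighted mean of source responses within the radius
    of each target; zero-distance source points (the target itself, when
    present among the sources) are excluded. radius="auto" takes the
    largest target-to-nearest-source distance, so every target has at
    least one neighbor.
    """
    tc = np.asarray(target_coords, dtype=float)
    sc = np.asarray(source_coords, dtype=float)
    y = np.asarray(source_response, dtype=float)
    d = np.sqrt(((tc[:, None, :] - sc[None, :, :]) ** 2).sum(axis=2))
    self_mask = d < 1e-12
    d_masked = np.where(self_mask, np.inf, d)
    if radius == "auto":
        radius = float(d_masked.min(axis=1).max())
    radius = float(radius)
    w = np.where(d_masked <= radius, 1.0 / d_masked, 0.0)
    rowsum = w.sum(axis=1)
    # fallback: targets with no source in the band use their nearest source
    empty = rowsum == 0
    if empty.any():
        nearest = d_masked[empty].argmin(axis=1)
        w[np.flatnonzero(empty), nearest] = 1.0
        rowsum = w.sum(axis=1)
    return (w @ y) / rowsum


def attach_autocovariate(dataset, radius="auto"):
    """Attach the spatial-lag predictor to a response dataset, in place.

    The autocovariate is computed once from the full dataset's labels
    before any train/test split; neighboring responses therefore leak
    between training and evaluation rows, which is logged.
    """
    weights = build_weights(dataset.coords, radius=radius)
    dataset.df["autocov"] = autocovariate(weights, dataset.labels)
    if "autocov" not in dataset.feature_names:
        dataset.feature_names = dataset.feature_names + ["autocov"]
    log.info(
        "autocovariate for %s computed on the full dataset (pre-split): "
        "spatial information is shared across any later train/test split",
        dataset.kind,
    )
    return dataset


def morans_i(
    weights: SpatialWeights,
    values,
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
) -> MoranResult:
    """Global Moran's I with a one-sided permutation test.

    I = (n/S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2,
    using the row-standardized weights. p = (1 + #{I_perm >= I_obs}) /
    (1 + n_perm) under random relabelling of the values.
    """
    x = np.asarray(values, dtype=float)
    if len(x) != weights.n:
        raise ValueError("values length does not match weights")
    z = x - x.mean()
    denom = (z**2).sum()
    if denom < 1e-300:
        raise ValueError("Moran's I undefined for constant values")
    W = weights.row_standardized
    s0 = W.sum()
    n = weights.n
    const = n / (s0 * denom)
    i_obs = float(const * (z @ (W @ z)))
    if n_perm <= 0:
        return MoranResult(I=i_obs, p=float("nan"), n_perm=0)
    rng = rng or np.random.default_rng()
    count = 0
    for _ in range(n_perm):
        zp = z[rng.permutation(n)]
        if const * (zp @ (W @ zp)) >= i_obs:
            count += 1
    return MoranResult(I=i_obs, p=(1 + count) / (1 + n_perm), n_perm=n_perm)


def pair_correlation(coords, r_grid, ring_width, window) -> np.ndarray:
    """Ring-count estimate of the pair correlation function g(r).

    For each r, counts point pairs at distance within [r - h/2, r + h/2)
    and divides by the count expected under complete spatial randomness
    at the window's intensity. No edge correction is applied (the
    estimate is biased low near the window boundary; adequate for
    choosing a clustering scale). Empty annuli give g = 0 with a warning.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < 2:
        raise ValueError("need at least 2 points")
    r_grid = np.asarray(r_grid, dtype=float)
    area = float(window[0]) * float(window[1])
    tree = cKDTree(coords)
    h = ring_width
    edges_lo = np.maximum(r_grid - h / 2.0, 0.0)
    edges_hi = r_grid + h / 2.0
    cum_lo = tree.count_neighbors(tree, edges_lo) - n  # remove self pairs
    cum_hi = tree.count_neighbors(tree, edges_hi) - n
    observed = (cum_hi - cum_lo) / 2.0  # unordered pairs
    ann_area = np.pi * (edges_hi**2 - edges_lo**2)
    expected = n * (n - 1) / 2.0 * ann_area / area
    g = np.where(expected > 0, observed / np.where(expected > 0, expected, 1.0), 0.0)
    if np.any(observed == 0):
        warnings.warn("empty annulus in pair correlation; g set to 0 there")
    return g


def assign_blocks(
    coords,
    block_side: float,
    k_folds: int,
    rng: np.random.Generator | None = None,
    ids=None,
) -> BlockAssignment:
    """Tessellate the bounding box into square blocks and deal them to folds.

    Blocks are visited in random order and each is assigned to the fold
    with the fewest lakes so far (greedy balancing), so all lakes of one
    block share a fold and fold sizes differ by at most the largest block
    occupancy.
    """
    if block_side <= 0:
        raise ValueError("block_side must be > 0")
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    coords = np.asarray(coords, dtype=float)
    rng = rng or np.random.default_rng()
    gx = np.floor((coords[:, 0] - coords[:, 0].min()) / block_side).astype(int)
    gy = np.floor((coords[:, 1] - coords[:, 1].min()) / block_side).astype(int)
    ncol = gx.max() + 1
    block = gy * ncol + gx
    occupied, counts = np.unique(block, return_counts=True)
    if len(occupied) < k_folds:
        raise ValueError(
            f"only {len(occupied)} occupied blocks of side {block_side} for "
            f"{k_folds} folds; decrease block_side or k_folds"
        )
    order = rng.permutation(len(occupied))
    fold_of_block: dict[int, int] = {}
    fold_counts = np.zeros(k_folds, dtype=int)
    for idx in order:
        f = int(fold_counts.argmin())
        fold_of_block[int(occupied[idx])] = f + 1
        fold_counts[f] += counts[idx]
    fold = np.array([fold_of_block[int(b)] for b in block])
    df = pd.DataFrame({"block": block, "fold": fold})
    if ids is not None:
        df.insert(0, "id", np.asarray(ids))
    return BlockAssignment(block_side=float(block_side), df=df)
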