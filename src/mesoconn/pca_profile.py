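"""Multivariate node profiling: 6-feature PCA and Parzen density map.

Each region is described by six local connectivity features — degree
all, average neighbor degree, clustering (all), clustering of the
2nd-neighbor set, the variation coefficient of neighbor degree, and
locality — chosen because together they quantify how a region relates
to its direct and indirect neighborhood.  PCA of the standardized
feature vectors maps regions to a plane; a Parzen (Gaussian kernel)
window turns the scatter into a probability density surface whose modes
are groups of regions with similar wiring character.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._graphops import index_adjacency
from .connectome import Connectome
from .local_metrics import local_table

__all__ = [
    "FEATURES",
    "feature_table",
    "PCAResult",
    "pca",
    "parzen_density",
    "neighborhood_rings",
    "NeighborhoodRings",
]

FEATURES = ["DG_all", "AvgDG_nb", "CluC_all", "CluC_2", "VC_DG", "Loc"]

_LOCAL_TO_FEATURE = {"DGa": "DG_all", "ADG": "AvgDG_nb", "CCa": "CluC_all",
                     "CC2": "CluC_2", "VC": "VC_DG", "Loc": "Loc"}


def feature_table(c: Connectome) -> pd.DataFrame:
    """Per-node 6-feature vectors (isolated-node features are 0)."""
    lt = local_table(c, shapley_mode="monte_carlo", shapley_perms=1, seed=0)
    out = lt[list(_LOCAL_TO_FEATURE)].rename(columns=_LOCAL_TO_FEATURE)
    return out[FEATURES]


@dataclass
class PCAResult:
    feature_names: list[str]
    nodes: list[str]
    loadings: np.ndarray      # feature x component, orthonormal columns
    shares: np.ndarray        # % variance per component, sums to 100
    scores: np.ndarray        # node x 2 plane coordinates
    scores_full: np.ndarray   # node x component
    mean: np.ndarray
    sd: np.ndarray


def pca(features: pd.DataFrame, standardize: bool = True) -> PCAResult:
    """Principal components of the feature table.

    Features are z-scored by default (they mix raw degrees with [0,1]
    coefficients); zero-variance features are dropped with a warning.
    Components are ordered by decreasing variance share and signed so
    the largest-magnitude loading of each component is positive.
    """
    if len(features) < 3:
        raise ValueError("PCA needs at least 3 nodes")
    x = features.to_numpy(dtype=float)
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [n for n, k in zip(features.columns, keep) if not k]
        warnings.warn(f"zero-variance features dropped: {dropped}")
    names = [n for n, k in zip(features.columns, keep) if k]
    x = x[:, keep]
    mean, sd = mean[keep], sd[keep]
    z = (x - mean) / sd if standardize else x - mean
    cov = np.cov(z, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0, None)
    for j in range(eigvec.shape[1]):
        col = eigvec[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            eigvec[:, j] = -col
    shares = 100 * eigval / eigval.sum()
    scores = z @ eigvec
    return PCAResult(
        feature_names=names,
        nodes=list(features.index),
        loadings=eigvec,
        shares=shares,
        scores=scores[:, :2],
        scores_full=scores,
        mean=mean,
        sd=sd,
    )


def pca_table(result: PCAResult) -> pd.DataFrame:
    """Loadings with a Share row, in the conventional table layout."""
    cols = [f"C{j + 1}" for j in range(result.loadings.shape[1])]
    df = pd.DataFrame(result.loadings, index=result.feature_names, columns=cols)
    df.loc["Share"] = result.shares
    return df


def parzen_density(
    scores: np.ndarray,
    bandwidth: float | tuple[float, float] | None = None,
    grid_spec: tuple[int, int] = (64, 64),
):
    """Gaussian Parzen-window density on a padded grid over the plane.

    ``bandwidth`` defaults to Silverman's rule per dimension; a scalar
    gives an isotropic kernel.  The grid extends 4 bandwidths beyond the
    data hull so the surface integrates to ~1.  Returns (xs, ys, density)
    with density[iy, ix] evaluated at (xs[ix], ys[iy]).
    """
    pts = np.atleast_2d(np.asarray(scores, dtype=float))
    if pts.shape[0] < 1:
        raise ValueError("need at least one point")
    m = pts.shape[0]
    if bandwidth is None:
        sd = pts.std(axis=0, ddof=1) if m > 1 else np.ones(2)
        sd[sd == 0] = 1.0
        bw = 1.06 * sd * m ** (-1 / 5)
    else:
        bw = np.broadcast_to(np.atleast_1d(np.asarray(bandwidth, dtype=float)), (2,)).copy()
    if np.any(bw <= 0):
        raise ValueError("bandwidth must be positive")
    nx_, ny_ = grid_spec
    lo = pts.min(axis=0) - 4 * bw
    hi = pts.max(axis=0) + 4 * bw
    xs = np.linspace(lo[0], hi[0], nx_)
    ys = np.linspace(lo[1], hi[1], ny_)
    gx, gy = np.meshgrid(xs, ys)
    dens = np.zeros_like(gx)
    norm = 1.0 / (2 * np.pi * bw[0] * bw[1] * m)
    for p in pts:
        dens += np.exp(-0.5 * (((gx - p[0]) / bw[0]) ** 2
                               + ((gy - p[1]) / bw[1]) ** 2))
    return xs, ys, dens * norm


@dataclass
class NeighborhoodRings:
    region: str
    ring1: set[str]
    ring2: set[str]
    arcs_within_ring1: int
    arcs_between_rings: int
    arcs_within_ring2: int


def neighborhood_rings(c: Connectome, region: str) -> NeighborhoodRings:
    """1st/2nd neighbor rings of a region and the arc tallies among them.

    Ring 1 is the union of in- and out-neighbors; ring 2 the neighbors
    of ring 1 not already in ring 1 or the region itself.  Arc tallies
    count directed arcs within ring 1, crossing between the rings
    (either direction), and within ring 2.
    """
    if region not in c.nodes:
        raise KeyError(region)
    idx = {v: i for i, v in enumerate(c.nodes)}
    out_adj, in_adj = index_adjacency(c)
    r = idx[region]
    ring1_idx = set(out_adj[r]) | set(in_adj[r])
    ring2_idx = set()
    for j in ring1_idx:
        ring2_idx.update(out_adj[j])
        ring2_idx.update(in_adj[j])
    ring2_idx -= ring1_idx | {r}
    w1 = between = w2 = 0
    for (s, t) in c.arcs:
        si, ti = idx[s], idx[t]
        if si in ring1_idx and ti in ring1_idx:
            w1 += 1
        elif si in ring2_idx and ti in ring2_idx:
            w2 += 1
        elif (si in ring1_idx and ti in ring2_idx) or (si in ring2_idx and ti in ring1_idx):
            between += 1
    names = c.nodes
    return NeighborhoodRings(
        region=region,
        ring1={names[i] for i in ring1_idx},
        ring2={names[i] for i in ring2_idx},
        arcs_within_ring1=w1,
        arcs_between_rings=between,
        arcs_within_ring2=w2,
    )
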