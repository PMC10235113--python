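"""The four per-site functional diversity indices.

FDis — abundance-weighted mean distance to the abundance-weighted centroid.
FDiv — abundance concentration toward the extremities of the occupied trait
       space (convex-hull based); in [0, 1].
FEve — regularity of abundance along the minimum spanning tree; in [0, 1].
U    — functional uniqueness, Rao quadratic entropy over Simpson diversity;
       1 - U is functional redundancy.

All indices treat species with zero abundance at a site as absent and
renormalize weights over the present species.  FDiv and FEve need at least
three species and are NaN below that; undefined values propagate as missing
rather than being imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist, squareform

from .io import AnalysisDataset, CommunityMatrix
from .traitspace import FunctionalSpace, TraitDistanceMatrix, gower_matrix, pcoa_embed

__all__ = ["fdis", "fdiv", "feve", "uniqueness", "fd_table", "FDResult",
           "build_spaces"]


def _present(coords: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    w = np.asarray(w, dtype=float)
    mask = w > 0
    wp = w[mask] / w[mask].sum()
    return coords[mask], wp


# Leading-axis cap for the hull/MST-based indices (FDiv, FEve).  Hulls need
# more points than dimensions, and Qhull degrades numerically in high
# dimension, so the per-site space is truncated to the leading axes.
MAX_HULL_AXES = 6


def _site_axes(x: np.ndarray) -> np.ndarray:
    s = x.shape[0]
    return x[:, : max(1, min(x.shape[1], s - 1, MAX_HULL_AXES))]


def fdis(space: FunctionalSpace | np.ndarray, w: np.ndarray) -> float:
    """Functional dispersion: sum_i w_i ||x_i - c||, c = sum_i w_i x_i."""
    coords = space.coords if isinstance(space, FunctionalSpace) else np.asarray(space, float)
    x, wp = _present(coords, w)
    if x.shape[0] == 1:
        return 0.0
    c = wp @ x
    return float(wp @ np.linalg.norm(x - c, axis=1))


def fdiv(space: FunctionalSpace | np.ndarray, w: np.ndarray) -> float:
    """Functional divergence from convex-hull vertex distances.

    g is the unweighted centroid of the hull vertices; dG_i the distance of
    each present species from g.  With Delta d = sum w_i (dG_i - mean dG) and
    Delta|d| its absolute counterpart, FDiv = (Delta d + mean dG) /
    (Delta|d| + mean dG).  NaN for S < 3.  A degenerate (flat) point cloud
    falls back to the hull in the largest non-degenerate subspace.
    """
    coords = space.coords if isinstance(space, FunctionalSpace) else np.asarray(space, float)
    x, wp = _present(coords, w)
    s = x.shape[0]
    if s < 3:
        return float("nan")
    x = _site_axes(x)
    verts = _hull_vertices(x)
    g = x[verts].mean(axis=0)
    dG = np.linalg.norm(x - g, axis=1)
    mean_dG = dG.mean()
    dev = dG - mean_dG
    delta_d = float(wp @ dev)
    delta_abs = float(wp @ np.abs(dev))
    denom = delta_abs + mean_dG
    if denom == 0:  # all species at one point
        return float("nan")
    return float((delta_d + mean_dG) / denom)


def _hull_vertices(x: np.ndarray) -> np.ndarray:
    """Convex hull vertex indices, reducing dimension for flat clouds."""
    pts = x - x.mean(axis=0)
    while pts.shape[1] > 1:
        try:
            return ConvexHull(pts).vertices
        except QhullError:
            # project onto principal axes and drop the flattest dimension
            _, _, vt = np.linalg.svd(pts, full_matrices=False)
            pts = pts @ vt[:-1].T
    lo, hi = np.argmin(pts[:, 0]), np.argmax(pts[:, 0])
    if lo == hi:
        return np.arange(x.shape[0])
    return np.array([lo, hi])


def feve(space: FunctionalSpace | np.ndarray, w: np.ndarray) -> float:
    """Functional evenness along the minimum spanning tree.

    Branch l = (i, j) gets EW_l = dist(i, j) / (w_i + w_j), normalized to
    PEW_l; FEve rescales sum_l min(PEW_l, 1/(S-1)) to [0, 1].  NaN for S < 3.
    """
    coords = space.coords if isinstance(space, FunctionalSpace) else np.asarray(space, float)
    x, wp = _present(coords, w)
    s = x.shape[0]
    if s < 3:
        return float("nan")
    x = _site_axes(x)
    dist = squareform(pdist(x))
    mst = minimum_spanning_tree(dist).tocoo()
    ew = np.array([dist[i, j] / (wp[i] + wp[j]) for i, j in zip(mst.row, mst.col)])
    if ew.sum() == 0:  # all species at one point
        return float("nan")
    pew = ew / ew.sum()
    thresh = 1.0 / (s - 1)
    return float((np.minimum(pew, thresh).sum() - thresh) / (1 - thresh))


def uniqueness(D: TraitDistanceMatrix | np.ndarray, w: np.ndarray) -> float:
    """Functional uniqueness U = Rao Q / Simpson D.

    Q = sum_ij w_i w_j d_ij and D = 1 - sum_i w_i^2; requires at least two
    present species (D > 0), else NaN.
    """
    d = D.d if isinstance(D, TraitDistanceMatrix) else np.asarray(D, float)
    w = np.asarray(w, dtype=float)
    mask = w > 0
    if mask.sum() < 2:
        return float("nan")
    wp = w[mask] / w[mask].sum()
    dp = d[np.ix_(mask, mask)]
    q = float(wp @ dp @ wp)
    simpson = 1.0 - float(np.sum(wp**2))
    return q / simpson


@dataclass
class FDResult:
    site: str
    category: str
    FDis: float
    FDiv: float
    FEve: float
    Uniq: float
    S: int


def build_spaces(dataset: AnalysisDataset, categories: list[str] | None = None,
                 correction: str = "sqrt"
                 ) -> dict[str, tuple[TraitDistanceMatrix, FunctionalSpace]]:
    """Gower matrix + PCoA space per functional category, on the full pool."""
    schema = dataset.traits.schema
    categories = categories or list(schema.categories)
    out = {}
    for cat in categories:
        D = gower_matrix(dataset.traits, schema, cat)
        out[cat] = (D, pcoa_embed(D, correction))
    return out


def fd_table(dataset: AnalysisDataset, categories: list[str] | None = None,
             correction: str = "sqrt", spaces=None) -> pd.DataFrame:
    """All four indices per (site, category); undefined values as NaN."""
    spaces = spaces or build_spaces(dataset, categories, correction)
    cm: CommunityMatrix = dataset.community
    W = cm.relative_abundance()
    rows = []
    for cat, (D, space) in spaces.items():
        Dsub = D.subset(cm.species_ids)
        coords = space.subset_coords(cm.species_ids)
        for s, site in enumerate(cm.site_ids):
            w = W[s]
            rows.append(FDResult(site=site, category=cat,
                                 FDis=fdis(coords, w), FDiv=fdiv(coords, w),
                                 FEve=feve(coords, w), Uniq=uniqueness(Dsub, w),
                                 S=int((w > 0).sum())))
    return pd.DataFrame([r.__dict__ for r in rows])
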