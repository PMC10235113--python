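"""Vectorized per-site metric evaluators for the null-model machinery.

Each factory binds the fixed ingredients (trait space coordinates, Gower or
cophenetic distance matrix, all aligned to the community's species columns)
and returns a callable mapping a raw abundance matrix to a per-site vector.
The trait space and phylogeny are held fixed under randomization; only the
community matrix varies.
"""

from __future__ import annotations

import numpy as np

from .functional import fdiv, feve
from .io import AnalysisDataset

__all__ = ["richness_metric", "mpd_metric", "mntd_metric", "fdis_metric",
           "fdiv_metric", "feve_metric", "uniqueness_metric",
           "standard_metrics"]


def _weights(mat: np.ndarray) -> np.ndarray:
    return mat / mat.sum(axis=1, keepdims=True)


def richness_metric():
    def metric(mat):
        return (mat > 0).sum(axis=1).astype(float)
    return metric


def total_abundance_metric():
    def metric(mat):
        return mat.sum(axis=1).astype(float)
    return metric


def mpd_metric(D: np.ndarray):
    D = np.asarray(D, dtype=float)

    def metric(mat):
        W = _weights(mat)
        num = np.einsum("sp,pq,sq->s", W, D, W)
        den = 1.0 - np.sum(W**2, axis=1)
        out = np.divide(num, den, out=np.full(len(W), np.nan), where=den > 0)
        out[(mat > 0).sum(axis=1) < 2] = np.nan
        return out
    return metric


def mntd_metric(D: np.ndarray):
    D = np.asarray(D, dtype=float)

    def metric(mat):
        W = _weights(mat)
        out = np.full(mat.shape[0], np.nan)
        for s in range(mat.shape[0]):
            mask = W[s] > 0
            if mask.sum() < 2:
                continue
            d = D[np.ix_(mask, mask)].copy()
            np.fill_diagonal(d, np.inf)
            out[s] = W[s][mask] @ d.min(axis=1)
        return out
    return metric


def fdis_metric(coords: np.ndarray):
    X = np.asarray(coords, dtype=float)

    def metric(mat):
        W = _weights(mat)
        C = W @ X  # per-site weighted centroids
        # dist[p, s] = ||X_p - C_s||
        dist = np.sqrt(np.maximum(
            (X**2).sum(1)[:, None] + (C**2).sum(1)[None, :] - 2 * X @ C.T, 0))
        return np.einsum("sp,ps->s", W, dist)
    return metric


def fdiv_metric(coords: np.ndarray):
    X = np.asarray(coords, dtype=float)

    def metric(mat):
        W = _weights(mat)
        return np.array([fdiv(X, W[s]) for s in range(mat.shape[0])])
    return metric


def feve_metric(coords: np.ndarray):
    X = np.asarray(coords, dtype=float)

    def metric(mat):
        W = _weights(mat)
        return np.array([feve(X, W[s]) for s in range(mat.shape[0])])
    return metric


def uniqueness_metric(D: np.ndarray):
    D = np.asarray(D, dtype=float)

    def metric(mat):
        W = _weights(mat)
        q = np.einsum("sp,pq,sq->s", W, D, W)
        simpson = 1.0 - np.sum(W**2, axis=1)
        out = np.divide(q, simpson, out=np.full(len(W), np.nan),
                        where=simpson > 0)
        out[(mat > 0).sum(axis=1) < 2] = np.nan
        return out
    return metric


def standard_metrics(dataset: AnalysisDataset, spaces, Dphylo) -> dict:
    """The standard index grid: 4 FD indices x functional categories, plus
    MPD and MNTD once.  Keys are (index, category) tuples; phylogenetic
    indices use category "phylo"."""
    species = dataset.community.species_ids
    metrics = {}
    for cat, (D, space) in spaces.items():
        coords = space.subset_coords(species)
        dsub = D.subset(species).d
        metrics[("FDis", cat)] = fdis_metric(coords)
        metrics[("FDiv", cat)] = fdiv_metric(coords)
        metrics[("FEve", cat)] = feve_metric(coords)
        metrics[("Uniq", cat)] = uniqueness_metric(dsub)
    dphy = Dphylo.subset(species).d
    metrics[("MPD", "phylo")] = mpd_metric(dphy)
    metrics[("MNTD", "phylo")] = mntd_metric(dphy)
    return metrics
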