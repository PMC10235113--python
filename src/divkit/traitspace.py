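"""Functional trait space: Gower dissimilarity over mixed traits and its
principal-coordinates embedding.

The space is built once per functional category on the full analyzed species
pool (quantitative ranges included), so per-site index values are comparable
across sites; per-site computations subset rows of the pooled coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CATEGORICAL, QUANTITATIVE, TraitSchema, TraitTable

__all__ = ["TraitDistanceMatrix", "FunctionalSpace", "gower_matrix", "pcoa_embed"]

EIG_REL_TOL = 1e-10


@dataclass
class TraitDistanceMatrix:
    """Pairwise Gower dissimilarity d_ij in [0, 1] for one trait category."""

    species_ids: list[str]
    d: np.ndarray
    category: str = ""

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.species_ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("nonzero diagonal")
        if np.any((self.d < -1e-12) | (self.d > 1 + 1e-12)):
            raise ValueError("Gower dissimilarities must lie in [0, 1]")
        self.d = np.clip(self.d, 0.0, 1.0)

    def subset(self, species: list[str]) -> "TraitDistanceMatrix":
        idx = np.array([self.species_ids.index(s) for s in species])
        return TraitDistanceMatrix(list(species), self.d[np.ix_(idx, idx)], self.category)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.species_ids, columns=self.species_ids)


@dataclass
class FunctionalSpace:
    """PCoA coordinates x_ik of the species pool for one category.

    Axes are ordered by decreasing eigenvalue; squared Euclidean distances
    between rows approximate the (corrected) input dissimilarities.
    """

    species_ids: list[str]
    coords: np.ndarray
    eigenvalues: np.ndarray
    correction: str = "sqrt"
    category: str = ""
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self._index = {s: i for i, s in enumerate(self.species_ids)}

    @property
    def n_axes(self) -> int:
        return self.coords.shape[1]

    def subset_coords(self, species: list[str]) -> np.ndarray:
        idx = [self._index[s] for s in species]
        return self.coords[idx]

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"axis_{k + 1}" for k in range(self.n_axes)]
        return pd.DataFrame(self.coords, index=self.species_ids, columns=cols)


def gower_matrix(tt: TraitTable, schema: TraitSchema | None = None,
                 category: str = "overall") -> TraitDistanceMatrix:
    """Gower dissimilarity over the traits of one functional category.

    Quantitative traits contribute |x_i - x_j| / range (range over the full
    analyzed pool); categorical traits contribute a 0/1 mismatch.  Traits are
    averaged with pairwise-complete weighting so that a missing value in
    either species drops that trait from that pair's average.  Zero-range
    traits are excluded with a warning; a pair with no jointly observed trait
    raises.
    """
    schema = schema or tt.schema
    if category not in schema.categories:
        raise KeyError(f"unknown category {category!r}")
    traits = schema.categories[category]
    species = tt.species_ids
    n = len(species)
    if n < 2:
        raise ValueError("need at least 2 species")

    num = np.zeros((n, n))
    cnt = np.zeros((n, n))
    for t in traits:
        col = tt.values[t]
        if schema.types[t] == QUANTITATIVE:
            x = col.to_numpy(dtype=float)
            ok = np.isfinite(x)
            rng = np.nanmax(x) - np.nanmin(x) if ok.any() else 0.0
            if not ok.any() or rng == 0:
                warnings.warn(f"trait {t!r}: zero range in category {category!r}; excluded")
                continue
            diff = np.abs(x[:, None] - x[None, :]) / rng
            both = ok[:, None] & ok[None, :]
            num += np.where(both, diff, 0.0)
            cnt += both
        else:
            vals = col.to_numpy(dtype=object)
            ok = pd.notna(col).to_numpy()
            mismatch = (vals[:, None] != vals[None, :]).astype(float)
            both = ok[:, None] & ok[None, :]
            num += np.where(both, mismatch, 0.0)
            cnt += both
    if np.all(cnt == 0):
        raise ValueError(f"no usable traits in category {category!r}")
    off = ~np.eye(n, dtype=bool)
    if np.any(cnt[off] == 0):
        i, j = np.argwhere((cnt == 0) & off)[0]
        raise ValueError(f"species pair with no jointly observed trait: "
                         f"({species[i]}, {species[j]})")
    d = np.divide(num, cnt, out=np.zeros_like(num), where=cnt > 0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    return TraitDistanceMatrix(list(species), d, category)


def _double_center(M: np.ndarray) -> np.ndarray:
    r = M.mean(axis=1, keepdims=True)
    c = M.mean(axis=0, keepdims=True)
    return M - r - c + M.mean()


def _cailliez_constant(D: np.ndarray) -> float:
    # smallest additive constant making D + c (off-diagonal) Euclidean
    n = D.shape[0]
    B1 = _double_center(-0.5 * D**2)
    B2 = _double_center(-0.5 * D)
    special = np.block([[np.zeros((n, n)), 2 * B1],
                        [-np.eye(n), -4 * B2]])
    eigs = np.linalg.eigvals(special)
    return float(max(eigs.real.max(), 0.0))


def pcoa_embed(D: TraitDistanceMatrix, correction: str = "sqrt") -> FunctionalSpace:
    """Classical PCoA of a (corrected) dissimilarity matrix.

    correction: "sqrt" embeds sqrt(d) (always Euclidean for Gower-type d),
    "cailliez" adds the smallest constant making d Euclidean, "none" embeds
    d as given.  All axes with eigenvalue > 1e-10 x the largest are kept,
    capped at S - 1; if every eigenvalue is ~0 (all species identical) a
    single all-zero axis is returned.
    """
    d = D.d
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 species")
    if correction == "sqrt":
        d = np.sqrt(d)
    elif correction == "cailliez":
        c = _cailliez_constant(d)
        if c > 0:
            d = d + c * (1 - np.eye(n))
    elif correction != "none":
        raise ValueError(f"unknown correction {correction!r}")

    B = _double_center(-0.5 * d**2)
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = EIG_REL_TOL * max(eigval[0], 0.0)
    keep = np.where(eigval > tol)[0][: n - 1]
    if len(keep) == 0:
        return FunctionalSpace(list(D.species_ids), np.zeros((n, 1)),
                               np.zeros(1), correction, D.category)
    coords = eigvec[:, keep] * np.sqrt(eigval[keep])
    return FunctionalSpace(list(D.species_ids), coords, eigval[keep],
                           correction, D.category)
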