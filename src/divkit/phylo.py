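"""Abundance-weighted phylogenetic diversity: cophenetic distances, MPD,
MNTD, and tip substitution for species missing from the reference tree."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CommunityMatrix, Phylogeny

__all__ = [
    "PhyloDistanceMatrix",
    "cophenetic",
    "mpd_w",
    "mntd_w",
    "substitute_tips",
    "pd_table",
]


@dataclass
class PhyloDistanceMatrix:
    """Pairwise cophenetic (path-length) distances between tips."""

    species_ids: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.species_ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("nonzero diagonal")
        if np.any(self.d < 0):
            raise ValueError("negative distances")

    def subset(self, species: list[str]) -> "PhyloDistanceMatrix":
        idx = np.array([self.species_ids.index(s) for s in species])
        return PhyloDistanceMatrix(list(species), self.d[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.species_ids, columns=self.species_ids)


def cophenetic(phylogeny: Phylogeny) -> PhyloDistanceMatrix:
    """Sum of branch lengths along the path between every pair of tips."""
    tree = phylogeny.tree
    pdm = tree.phylogenetic_distance_matrix()
    leaves = [leaf.taxon for leaf in tree.leaf_node_iter()]
    labels = [t.label for t in leaves]
    n = len(leaves)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(leaves[i], leaves[j])
    return PhyloDistanceMatrix(labels, d)


def tip_depths(phylogeny: Phylogeny) -> dict[str, float]:
    """Root-to-tip path length per tip."""
    depths = {}
    for leaf in phylogeny.tree.leaf_node_iter():
        depths[leaf.taxon.label] = leaf.distance_from_root()
    return depths


def mpd_w(D: PhyloDistanceMatrix | np.ndarray, w: np.ndarray) -> float:
    """Abundance-weighted mean pairwise distance.

    MPD = sum_{i != j} w_i w_j d_ij / sum_{i != j} w_i w_j, over species with
    w_i > 0 (weights renormalized over present species).  Undefined (NaN) for
    fewer than two present species.
    """
    d = D.d if isinstance(D, PhyloDistanceMatrix) else np.asarray(D, float)
    w = np.asarray(w, dtype=float)
    present = w > 0
    if present.sum() < 2:
        return float("nan")
    wp = w[present] / w[present].sum()
    dp = d[np.ix_(present, present)]
    denom = 1.0 - np.sum(wp**2)
    return float(wp @ dp @ wp / denom)


def mntd_w(D: PhyloDistanceMatrix | np.ndarray, w: np.ndarray) -> float:
    """Abundance-weighted mean nearest-taxon distance.

    MNTD = sum_i w_i min_{j != i} d_ij with the abundance weight on the focal
    species only; weights renormalized over present species.  NaN if fewer
    than two species are present.
    """
    d = D.d if isinstance(D, PhyloDistanceMatrix) else np.asarray(D, float)
    w = np.asarray(w, dtype=float)
    present = w > 0
    if present.sum() < 2:
        return float("nan")
    wp = w[present] / w[present].sum()
    dp = d[np.ix_(present, present)].copy()
    np.fill_diagonal(dp, np.inf)
    return float(wp @ dp.min(axis=1))


def _genus(name: str) -> str:
    return name.split("_", 1)[0]


def substitute_tips(phylogeny: Phylogeny, community_species: list[str]
                    ) -> tuple[Phylogeny, dict[str, str], list[str]]:
    """Map community species onto tree tips, substituting congeners.

    Species already in the tree map to themselves.  A species absent from
    the tree is placed on an unused tip of the same genus; when several are
    free, the one with the smallest mean cophenetic distance to the tips
    already mapped for that genus is taken (alphabetical tie-break).  Species
    with no free congener are returned as unmapped.  The returned tree is
    pruned to the mapped community species, tips renamed accordingly.
    """
    tips = set(phylogeny.tip_labels)
    community_species = [str(s) for s in community_species]
    mapping: dict[str, str] = {s: s for s in community_species if s in tips}
    absent = sorted(s for s in community_species if s not in tips)
    unmapped: list[str] = []

    if absent:
        D = cophenetic(phylogeny)
        index = {s: i for i, s in enumerate(D.species_ids)}
        used = set(mapping.values())
        for sp in absent:
            genus = _genus(sp)
            free = sorted(t for t in tips - used if _genus(t) == genus)
            if not free:
                unmapped.append(sp)
                continue
            anchors = [index[t] for t in used if _genus(t) == genus]
            if anchors:
                def mean_dist(t):
                    return D.d[index[t], anchors].mean()
                free.sort(key=lambda t: (mean_dist(t), t))
            mapping[sp] = free[0]
            used.add(free[0])

    mapped = [s for s in community_species if s in mapping]
    if not mapped:
        raise ValueError("no community species could be mapped to the tree")
    tree2 = phylogeny.tree.clone(depth=1)
    inverse = {v: k for k, v in mapping.items()}
    if len(mapped) >= 2:
        keep_taxa = [t for t in tree2.taxon_namespace if t.label in inverse]
        tree2.retain_taxa(keep_taxa)
    for taxon in tree2.taxon_namespace:
        if taxon.label in inverse:
            taxon.label = inverse[taxon.label]
    tree2.purge_taxon_namespace()
    return Phylogeny(tree2), mapping, unmapped


def pd_table(cm: CommunityMatrix, D: PhyloDistanceMatrix) -> pd.DataFrame:
    """Per-site abundance-weighted MPD and MNTD (tidy: site, MPD, MNTD, S)."""
    Dsub = D.subset(cm.species_ids)
    W = cm.relative_abundance()
    rows = []
    for s, site in enumerate(cm.site_ids):
        w = W[s]
        rows.append({"site": site, "MPD": mpd_w(Dsub, w), "MNTD": mntd_w(Dsub, w),
                     "S": int((w > 0).sum())})
    return pd.DataFrame(rows)
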