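"""Phylogenetic signal: maximum-likelihood Pagel's lambda.

Under a Brownian-motion model on a rooted tree, a trait vector y is
multivariate normal with mean mu*1 and covariance sigma^2 * C, where
C_ij is the shared root-to-MRCA path length of tips i and j.  Pagel's
lambda multiplies the off-diagonal entries of C: lambda = 1 recovers
Brownian motion, lambda = 0 phylogenetic independence.  The fit profiles
lambda on [0, lambda_max] (the largest value keeping C(lambda) positive
definite, so estimates slightly above 1 are possible on non-ultrametric
trees) with closed-form GLS estimates of mu and sigma^2 at each lambda,
and tests lambda = 0 by a one-degree likelihood-ratio test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import solve_triangular

from .io import Phylogeny, TraitTable
from .phylo import cophenetic

__all__ = ["PagelLambda", "PagelLambdaResults", "phylo_covariance",
           "lambda_transform", "fit_lambda", "signal_table"]

_PD_TOL = 1e-8


def phylo_covariance(tree: Phylogeny) -> tuple[list[str], np.ndarray]:
    """Brownian-motion covariance C: C_ii = tip depth, C_ij = MRCA depth.

    Built from MRCA depths directly (one postorder pass) so the matrix is
    exactly the BM covariance, with no floating-point cancellation.
    """
    t = tree.tree
    labels = [leaf.taxon.label for leaf in t.leaf_node_iter()]
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))
    # depths from the tips' MRCA: a stem edge above the root carries no
    # information about among-tip covariance once the mean is estimated
    depth = {t.seed_node: 0.0}
    for node in t.preorder_node_iter():
        if node is not t.seed_node:
            depth[node] = depth[node.parent_node] + float(node.edge.length)
    tipsets: dict = {}
    for node in t.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            C[i, i] = depth[node]
            tipsets[node] = [i]
        else:
            child_sets = [tipsets.pop(ch) for ch in node.child_nodes()]
            d = depth[node]
            for a in range(len(child_sets)):
                for b in range(a + 1, len(child_sets)):
                    for i in child_sets[a]:
                        C[i, child_sets[b]] = d
                        C[np.array(child_sets[b]), i] = d
            tipsets[node] = [i for s in child_sets for i in s]
    return labels, C


def lambda_transform(C: np.ndarray, lam: float, lam_max: float | None = None) -> np.ndarray:
    """Scale the off-diagonal phylogenetic covariances by lambda."""
    if lam < 0 or (lam_max is not None and lam > lam_max):
        raise ValueError(f"lambda {lam} outside [0, {lam_max}]")
    C = np.asarray(C, dtype=float)
    out = C * lam
    np.fill_diagonal(out, np.diag(C))
    return out


def lambda_max(C: np.ndarray, tol: float = _PD_TOL) -> float:
    """Largest lambda keeping C(lambda) positive definite (bisection on
    Cholesky feasibility), so estimates slightly above 1 are reachable."""

    def ok(lam):
        try:
            np.linalg.cholesky(lambda_transform(C, lam))
            return True
        except np.linalg.LinAlgError:
            return False

    hi = 1.0
    while ok(hi) and hi < 64:
        hi *= 2
    if ok(hi):
        return hi
    lo = 0.0 if not ok(1.0) else 1.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if ok(mid):
            lo = mid
        else:
            hi = mid
    return lo


def _profile_loglik(y: np.ndarray, C: np.ndarray, lam: float
                    ) -> tuple[float, float, float]:
    """GLS-profiled log-likelihood, mu-hat, sigma2-hat at fixed lambda."""
    n = len(y)
    Cl = lambda_transform(C, lam)
    L = np.linalg.cholesky(Cl)
    ones = np.ones(n)
    Li_y = solve_triangular(L, y, lower=True)
    Li_1 = solve_triangular(L, ones, lower=True)
    mu = float(Li_1 @ Li_y / (Li_1 @ Li_1))
    r = Li_y - mu * Li_1
    sigma2 = float(r @ r) / n
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return ll, mu, sigma2


@dataclass
class PagelLambdaResults:
    """ML fit of Pagel's lambda for one trait."""

    trait: str
    lambda_: float
    sigma2: float
    mu: float
    llf: float
    llf_lambda0: float
    lambda_max: float
    unidentifiable: bool = False

    @property
    def lr_stat(self) -> float:
        return max(2.0 * (self.llf - self.llf_lambda0), 0.0)

    @property
    def pvalue(self) -> float:
        if self.unidentifiable:
            return float("nan")
        return float(stats.chi2.sf(self.lr_stat, df=1))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "trait": [self.trait], "lambda": [self.lambda_],
            "sigma2": [self.sigma2], "mu": [self.mu], "logL": [self.llf],
            "logL_lambda0": [self.llf_lambda0], "LR": [self.lr_stat],
            "p": [self.pvalue], "lambda_max": [self.lambda_max],
            "unidentifiable": [self.unidentifiable],
        })

    def __repr__(self):
        return (f"PagelLambdaResults(trait={self.trait!r}, lambda={self.lambda_:.4g}, "
                f"p={self.pvalue:.4g})")


class PagelLambda:
    """Model for the phylogenetic signal of one quantitative trait.

    Parameters
    ----------
    trait : mapping/Series of per-species values, or array aligned to the
        tree's tips.
    tree : Phylogeny
    name : label used in summaries.
    """

    def __init__(self, trait, tree: Phylogeny, name: str = "trait"):
        species, C = phylo_covariance(tree)
        if isinstance(trait, (dict, pd.Series)):
            trait = pd.Series(trait)
            missing = [s for s in species if s not in trait.index]
            if missing:
                raise ValueError(f"trait values missing for tips: {missing[:5]}")
            y = trait.loc[species].to_numpy(dtype=float)
        else:
            y = np.asarray(trait, dtype=float)
            if len(y) != len(species):
                raise ValueError("trait length does not match number of tips")
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite trait values")
        if np.ptp(y) == 0:
            raise ValueError("constant trait: phylogenetic signal undefined")
        self.species = species
        self.C = C
        self.y = y
        self.name = name

    def fit(self, xtol: float = 1e-6) -> PagelLambdaResults:
        C, y = self.C, self.y
        off = C[~np.eye(len(y), dtype=bool)]
        ll0, _, _ = _profile_loglik(y, C, 0.0)
        if off.size == 0 or np.max(np.abs(off)) < 1e-12 * np.max(np.diag(C)):
            # star phylogeny: the likelihood does not depend on lambda
            _, mu0, s0 = _profile_loglik(y, C, 0.0)
            return PagelLambdaResults(self.name, float("nan"), s0, mu0,
                                      ll0, ll0, float("nan"), unidentifiable=True)
        lmax = lambda_max(C)
        res = optimize.minimize_scalar(
            lambda lam: -_profile_loglik(y, C, lam)[0],
            bounds=(0.0, lmax), method="bounded",
            options={"xatol": xtol})
        candidates = [0.0, res.x, lmax]
        best_lam, best_ll = None, -np.inf
        for lam in candidates:
            lam = min(max(lam, 0.0), lmax)
            try:
                ll, _, _ = _profile_loglik(y, C, lam)
            except np.linalg.LinAlgError:
                continue
            if ll > best_ll:
                best_lam, best_ll = lam, ll
        ll, mu, s2 = _profile_loglik(y, C, best_lam)
        return PagelLambdaResults(self.name, float(best_lam), s2, mu, ll,
                                  ll0, lmax)


def fit_lambda(tree: Phylogeny, trait, name: str = "trait") -> PagelLambdaResults:
    """Convenience wrapper: ``PagelLambda(trait, tree).fit()``."""
    return PagelLambda(trait, tree, name=name).fit()


def signal_table(tree: Phylogeny, tt: TraitTable) -> pd.DataFrame:
    """Pagel's lambda per quantitative trait (tidy: trait, lambda, logL, p)."""
    rows = []
    tips = set(tree.tip_labels)
    for t in tt.schema.quantitative_traits():
        vals = tt.values[t].dropna()
        vals = vals[vals.index.isin(tips)]
        subtree = tree
        if len(vals) < len(tips):
            pruned = tree.tree.clone(depth=1)
            pruned.retain_taxa_with_labels(list(vals.index))
            subtree = Phylogeny(pruned)
        res = fit_lambda(subtree, vals, name=t)
        rows.append({"trait": t, "lambda": res.lambda_, "logL": res.llf,
                     "p": res.pvalue})
    return pd.DataFrame(rows)
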