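"""Synthetic studies with known ground truth.

The generator emulates the structure of a museum-collection bat survey:
~20 sites sampled with varying effort along a 0-3670 m altitudinal gradient,
a regional pool of ~97 species dominated by one clade-rich family, per-site
richness between 5 and 43 species, strongly right-skewed abundances (a few
dominant species, many singletons), morphometric traits with strong
phylogenetic signal (lambda ~ 0.7-1.0) grouped into body-size / skull / jaw /
foraging categories, and a categorical feeding strategy biased within
clades.  Sites are exchangeable: no spatial autocorrelation is simulated.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glmm import simulate_response
from .io import (AnalysisDataset, CommunityMatrix, Phylogeny, SiteCovariates,
                 TraitSchema, TraitTable, reconcile)
from .phylosignal import lambda_transform, phylo_covariance

__all__ = ["SimConfig", "bat_trait_schema", "simulate_tree", "simulate_traits",
           "simulate_communities", "simulate_linked_responses",
           "simulate_dataset", "FEEDING_LEVELS"]

FEEDING_LEVELS = ["foliage_gleaner", "aerial_insectivore", "nomadic_frugivore",
                  "sedentary_frugivore", "sanguivore", "piscivore",
                  "nectarivore", "carnivore"]

# plausible trait baselines (means on measurement scale) for readability
_TRAIT_MEANS = {
    "wing_shape": 1.3, "relative_pinna_length": 0.35,
    "skull_length": 22.0, "maxillary_toothrow_length": 8.0,
    "middle_skull_width": 10.0, "m2_area": 3.0,
    "breadth_upper_molars": 9.0, "braincase_breadth": 9.5,
    "condylocanine_length": 20.0, "jaw_length": 15.0, "coronoid_height": 5.0,
    "forearm_length": 45.0, "body_length": 70.0, "mass": 20.0,
}


def bat_trait_schema() -> TraitSchema:
    """Trait schema mirroring the five functional categories of the study
    system: foraging (one 8-level categorical + two ratio traits), skull,
    jaw, body size, and their union (overall)."""
    types = {"feeding_strategy": "categorical"}
    types.update({t: "quantitative" for t in _TRAIT_MEANS})
    categories = {
        "foraging": ["feeding_strategy", "wing_shape", "relative_pinna_length"],
        "skull": ["skull_length", "maxillary_toothrow_length",
                  "middle_skull_width", "m2_area", "breadth_upper_molars",
                  "braincase_breadth"],
        "jaw": ["condylocanine_length", "jaw_length", "coronoid_height"],
        "body_size": ["forearm_length", "body_length", "mass"],
    }
    return TraitSchema(types=types, categories=categories)


@dataclass
class SimConfig:
    """Study-condition defaults for a synthetic survey."""

    seed: int = 0
    n_sites: int = 20
    pool_size: int = 97
    richness_range: tuple[int, int] = (5, 43)
    abundance_meanlog: float = 0.0
    abundance_sdlog: float = 1.5
    tree_model: str = "yule"
    birth_rate: float = 1.0
    death_rate: float = 0.0
    lambda_range: tuple[float, float] = (0.7, 1.0)
    trait_cv: float = 0.08  # per-trait SD as a fraction of the baseline mean
    clade_bias: float = 0.8  # P(species adopts its genus' feeding strategy)
    genus_size: int = 5
    sampling_days_range: tuple[int, int] = (3, 30)
    altitude_range: tuple[float, float] = (0.0, 3670.0)

    def __post_init__(self):
        lo, hi = self.richness_range
        if not (2 <= lo <= hi <= self.pool_size):
            raise ValueError("richness_range must lie within [2, pool_size]")
        if self.birth_rate <= 0 or self.death_rate < 0:
            raise ValueError("rates must be positive")


def _rng(rng_or_seed) -> np.random.Generator:
    if isinstance(rng_or_seed, np.random.Generator):
        return rng_or_seed
    return np.random.default_rng(rng_or_seed)


def simulate_tree(n_tips: int, model: str = "yule",
                  rng: np.random.Generator | int | None = None,
                  birth_rate: float = 1.0, death_rate: float = 0.0,
                  genus_size: int = 5) -> Phylogeny:
    """Simulate a rooted ultrametric tree and label tips Genus_species.

    Genera are assigned to blocks of adjacent tips (clades of roughly
    `genus_size`), so congeneric tips are close relatives — which is what
    the congener tip-substitution rule relies on.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if model == "yule":
        death_rate = 0.0
    elif model != "birth_death":
        raise ValueError("model must be 'yule' or 'birth_death'")
    if birth_rate <= 0 or death_rate < 0 or death_rate >= birth_rate:
        raise ValueError("invalid birth/death rates")
    rng = _rng(rng)
    pyrandom = _random.Random(int(rng.integers(2**31 - 1)))
    from dendropy.simulate import treesim

    tree = treesim.birth_death_tree(
        birth_rate=birth_rate, death_rate=death_rate,
        num_extant_tips=n_tips, rng=pyrandom,
        is_retain_extinct_tips=False)
    # the simulator stops exactly at the n-th speciation, leaving the last
    # two daughter edges at length 0; run the clock one more memoryless
    # holding time so terminal branches are positive and tips stay coeval
    delta = rng.exponential(1.0 / (n_tips * birth_rate))
    leaves = list(tree.leaf_node_iter())
    for leaf in leaves:
        leaf.edge.length = float(leaf.edge.length or 0.0) + delta
    for i, leaf in enumerate(leaves):
        genus = i // genus_size + 1
        sp = i % genus_size + 1
        leaf.taxon.label = f"Genus{genus:02d}_sp{sp:02d}"
    tree.purge_taxon_namespace()
    return Phylogeny(tree)


def simulate_traits(tree: Phylogeny, lambda_true=1.0, sigma2=1.0,
                    rng: np.random.Generator | int | None = None,
                    schema: TraitSchema | None = None,
                    clade_bias: float = 0.8, genus_size: int = 5) -> TraitTable:
    """Draw trait values under the lambda-Brownian model on `tree`.

    Each quantitative trait is multivariate normal with covariance
    sigma2 * C(lambda); `lambda_true` and `sigma2` may be scalars or
    per-trait mappings.  The categorical feeding strategy is drawn with
    clade-biased level probabilities (each genus has a preferred level).
    """
    rng = _rng(rng)
    schema = schema or bat_trait_schema()
    species, C = phylo_covariance(tree)
    n = len(species)
    data = {}
    for t in schema.quantitative_traits():
        lam = lambda_true[t] if isinstance(lambda_true, dict) else lambda_true
        s2 = sigma2[t] if isinstance(sigma2, dict) else sigma2
        if s2 <= 0:
            raise ValueError(f"sigma2 must be positive (trait {t!r})")
        if not 0 <= lam <= 1:
            raise ValueError("lambda_true must lie in [0, 1]")
        Cl = lambda_transform(C, lam) + 1e-12 * np.max(np.diag(C)) * np.eye(n)
        L = np.linalg.cholesky(s2 * Cl)
        base = _TRAIT_MEANS.get(t, 0.0)
        data[t] = base + L @ rng.standard_normal(n)
    for t, kind in schema.types.items():
        if kind != "categorical":
            continue
        k = len(FEEDING_LEVELS)
        vals = []
        genus_pref: dict[str, int] = {}
        for sp in species:
            genus = sp.split("_", 1)[0]
            if genus not in genus_pref:
                genus_pref[genus] = int(rng.integers(k))
            if rng.random() < clade_bias:
                vals.append(FEEDING_LEVELS[genus_pref[genus]])
            else:
                vals.append(FEEDING_LEVELS[int(rng.integers(k))])
        data[t] = vals
    df = pd.DataFrame(data, index=species)
    return TraitTable(df, schema)


def simulate_communities(cfg: SimConfig,
                         rng: np.random.Generator | int | None = None,
                         species_pool: list[str] | None = None
                         ) -> tuple[CommunityMatrix, SiteCovariates]:
    """Draw per-site assemblages and covariates.

    Site richness is uniform on `richness_range`; species are sampled from
    the pool with lognormal regional weights (a few regionally common
    species recur across sites) and abundances are lognormal rounded up to
    at least one individual, so singletons are common.  Species never drawn
    anywhere are pruned from the matrix.
    """
    rng = _rng(rng)
    pool = (list(species_pool) if species_pool is not None
            else [f"Genus{i // cfg.genus_size + 1:02d}_sp{i % cfg.genus_size + 1:02d}"
                  for i in range(cfg.pool_size)])
    n_pool = len(pool)
    regional_w = rng.lognormal(0.0, 1.0, size=n_pool)
    regional_w /= regional_w.sum()
    lo, hi = cfg.richness_range
    hi = min(hi, n_pool)
    mat = np.zeros((cfg.n_sites, n_pool))
    for s in range(cfg.n_sites):
        S = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(n_pool, size=S, replace=False, p=regional_w)
        counts = np.ceil(rng.lognormal(cfg.abundance_meanlog,
                                       cfg.abundance_sdlog, size=S))
        mat[s, chosen] = counts
    sites = [f"site{s + 1:02d}" for s in range(cfg.n_sites)]
    cm = CommunityMatrix(mat, sites, pool, prune_empty_species=True)
    days = rng.integers(cfg.sampling_days_range[0],
                        cfg.sampling_days_range[1] + 1, size=cfg.n_sites)
    alt = rng.uniform(*cfg.altitude_range, size=cfg.n_sites)
    cov = SiteCovariates(pd.DataFrame(
        {"sampling_days": days, "altitude_m": np.round(alt, 1)}, index=sites))
    return cm, cov


def simulate_linked_responses(family: str, params: dict, richness,
                              covariates: SiteCovariates,
                              rng: np.random.Generator | int | None = None
                              ) -> np.ndarray:
    """Per-site index values drawn from the exact GLMM generative model."""
    rng = _rng(rng)
    days = covariates.table["sampling_days"].to_numpy(dtype=float)
    alt = covariates.table["altitude_m"].to_numpy(dtype=float)
    alt_sd = alt.std() or 1.0
    z_alt = (alt - alt.mean()) / alt_sd
    return simulate_response(family, params, richness, np.log(days), z_alt, rng)


@dataclass
class SimulatedStudy:
    community: CommunityMatrix
    traits: TraitTable
    schema: TraitSchema
    tree: Phylogeny
    covariates: SiteCovariates
    config: SimConfig = field(default_factory=SimConfig)

    def to_dir(self, outdir) -> None:
        """Write the four standard input files (CSV x3 + Newick + schema)."""
        import pathlib

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.community.to_csv(outdir / "community.csv")
        self.traits.to_csv(outdir / "traits.csv")
        self.schema.to_yaml(outdir / "trait_schema.yaml")
        self.tree.write_newick(outdir / "tree.nwk")
        self.covariates.to_csv(outdir / "covariates.csv")

    def reconciled(self) -> AnalysisDataset:
        return reconcile(self.community, self.traits, self.tree,
                         self.covariates)


def simulate_dataset(cfg: SimConfig | None = None,
                     rng: np.random.Generator | int | None = None
                     ) -> SimulatedStudy:
    """One full synthetic study: tree, traits, communities, covariates."""
    cfg = cfg or SimConfig()
    rng = _rng(cfg.seed if rng is None else rng)
    tree = simulate_tree(cfg.pool_size, cfg.tree_model, rng,
                         birth_rate=cfg.birth_rate, death_rate=cfg.death_rate,
                         genus_size=cfg.genus_size)
    schema = bat_trait_schema()
    lam_lo, lam_hi = cfg.lambda_range
    lambdas = {t: float(rng.uniform(lam_lo, lam_hi))
               for t in schema.quantitative_traits()}
    depth = max(np.diag(phylo_covariance(tree)[1]))
    sigma2 = {t: (cfg.trait_cv * max(abs(_TRAIT_MEANS.get(t, 1.0)), 1e-6)) ** 2 / depth
              for t in schema.quantitative_traits()}
    traits = simulate_traits(tree, lambdas, sigma2, rng, schema,
                             clade_bias=cfg.clade_bias,
                             genus_size=cfg.genus_size)
    cm, cov = simulate_communities(cfg, rng, species_pool=tree.tip_labels)
    return SimulatedStudy(cm, traits, schema, tree, cov, cfg)
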