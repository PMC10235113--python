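"""Input artifacts and their validation.

Four artifacts feed the analysis: a site x species abundance matrix, a
species x trait table with a schema declaring trait types and functional
categories, a rooted phylogeny with branch lengths, and per-site covariates
(sampling effort, altitude).  This module reads each from its plain-text
format, enforces the invariants the downstream indices rely on, and
reconciles the four name spaces into one :class:`AnalysisDataset`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CommunityMatrix",
    "TraitSchema",
    "TraitTable",
    "Phylogeny",
    "SiteCovariates",
    "AnalysisDataset",
    "ReconcileReport",
    "read_community",
    "read_traits",
    "read_tree",
    "read_covariates",
    "reconcile",
    "normalize_name",
]

QUANTITATIVE = "quantitative"
CATEGORICAL = "categorical"


def normalize_name(name: str) -> str:
    """Canonical species/site name: trimmed, internal whitespace -> underscore."""
    return "_".join(str(name).strip().split())


class CommunityMatrix:
    """Site x species abundance matrix (counts as an abundance surrogate).

    Rows are sites, columns species.  Every site must hold at least one
    individual and every retained species must occur somewhere; relative
    abundances per site (``w_i``) are derived by dividing each row by its sum.
    """

    def __init__(self, abundance, site_ids, species_ids, *, prune_empty_species=False):
        abundance = np.asarray(abundance, dtype=float)
        if abundance.ndim != 2:
            raise ValueError("abundance must be a 2-D sites x species array")
        site_ids = [normalize_name(s) for s in site_ids]
        species_ids = [normalize_name(s) for s in species_ids]
        if abundance.shape != (len(site_ids), len(species_ids)):
            raise ValueError("abundance shape does not match id lists")
        if len(set(site_ids)) != len(site_ids):
            raise ValueError("duplicate site names")
        if len(set(species_ids)) != len(species_ids):
            raise ValueError("duplicate species names")
        if not np.all(np.isfinite(abundance)):
            raise ValueError("non-finite abundance values")
        if np.any(abundance < 0):
            raise ValueError("negative abundance values")
        if prune_empty_species:
            keep = abundance.sum(axis=0) > 0
            abundance = abundance[:, keep]
            species_ids = [s for s, k in zip(species_ids, keep) if k]
        if np.any(abundance.sum(axis=1) <= 0):
            bad = [site_ids[i] for i in np.where(abundance.sum(axis=1) <= 0)[0]]
            raise ValueError(f"sites with zero total abundance: {bad}")
        if np.any(abundance.sum(axis=0) <= 0):
            bad = [species_ids[j] for j in np.where(abundance.sum(axis=0) <= 0)[0]]
            raise ValueError(f"species never observed: {bad}")
        self.abundance = abundance
        self.site_ids = list(site_ids)
        self.species_ids = list(species_ids)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def relative_abundance(self) -> np.ndarray:
        """Per-site relative abundances w (rows sum to 1)."""
        return self.abundance / self.abundance.sum(axis=1, keepdims=True)

    def richness(self) -> np.ndarray:
        """Species richness S per site (count of nonzero abundances)."""
        return (self.abundance > 0).sum(axis=1)

    def subset_species(self, species: list[str]) -> "CommunityMatrix":
        idx = [self.species_ids.index(s) for s in species]
        return CommunityMatrix(self.abundance[:, idx], self.site_ids, species)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.abundance, index=self.site_ids, columns=self.species_ids)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="site")

    def __repr__(self):
        return f"CommunityMatrix({self.n_sites} sites x {self.n_species} species)"


@dataclass
class TraitSchema:
    """Declares each trait's type and its functional-category memberships.

    ``types`` maps trait -> {"quantitative", "categorical"}; ``categories``
    maps category name (body_size, skull, jaw, foraging, overall) -> traits.
    "overall" always equals the union of all declared traits.
    """

    types: dict[str, str]
    categories: dict[str, list[str]]
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for t, k in self.types.items():
            if k not in (QUANTITATIVE, CATEGORICAL):
                raise ValueError(f"trait {t!r}: unknown type {k!r}")
        for cat, traits in self.categories.items():
            unknown = [t for t in traits if t not in self.types]
            if unknown:
                raise ValueError(f"category {cat!r} references undeclared traits {unknown}")
        union = sorted(self.types)
        if "overall" not in self.categories:
            self.categories["overall"] = union
        elif sorted(self.categories["overall"]) != union:
            raise ValueError('"overall" category must equal the union of all traits')

    @property
    def trait_names(self) -> list[str]:
        return list(self.types)

    def quantitative_traits(self) -> list[str]:
        return [t for t, k in self.types.items() if k == QUANTITATIVE]

    @classmethod
    def from_yaml(cls, path) -> "TraitSchema":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        types, units = {}, {}
        for entry in raw["traits"]:
            types[entry["name"]] = entry["type"]
            if entry.get("unit"):
                units[entry["name"]] = entry["unit"]
        return cls(types=types, categories=dict(raw.get("categories", {})), units=units)

    def to_yaml(self, path) -> None:
        payload = {
            "traits": [
                {"name": t, "type": k, **({"unit": self.units[t]} if t in self.units else {})}
                for t, k in self.types.items()
            ],
            "categories": {c: list(ts) for c, ts in self.categories.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


class TraitTable:
    """Species-level trait values (quantitative columns numeric, categorical
    columns strings; missing values allowed as NaN)."""

    def __init__(self, values: pd.DataFrame, schema: TraitSchema):
        values = values.copy()
        values.index = [normalize_name(s) for s in values.index]
        if values.index.has_duplicates:
            raise ValueError("duplicate species in trait table")
        missing_cols = [t for t in schema.trait_names if t not in values.columns]
        if missing_cols:
            raise ValueError(f"schema traits missing from table: {missing_cols}")
        for t in schema.quantitative_traits():
            try:
                values[t] = pd.to_numeric(values[t])
            except (ValueError, TypeError) as exc:
                raise ValueError(f"quantitative trait {t!r} has non-numeric values") from exc
        for t, k in schema.types.items():
            if k == CATEGORICAL:
                values[t] = values[t].astype("string")
        self.values = values[schema.trait_names]
        self.schema = schema

    @property
    def species_ids(self) -> list[str]:
        return list(self.values.index)

    def subset(self, species: list[str]) -> "TraitTable":
        return TraitTable(self.values.loc[species], self.schema)

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index_label="species")

    @classmethod
    def aggregate_individuals(cls, measurements: pd.DataFrame, schema: TraitSchema,
                              species_col: str = "species") -> "TraitTable":
        """Collapse individual-level measurements to species means.

        Quantitative traits: arithmetic mean over individuals (all sites
        pooled).  Categorical traits must be constant within a species.
        """
        rows = {}
        for sp, grp in measurements.groupby(species_col):
            row = {}
            for t, k in schema.types.items():
                if k == QUANTITATIVE:
                    row[t] = pd.to_numeric(grp[t]).mean()
                else:
                    levels = grp[t].dropna().unique()
                    if len(levels) > 1:
                        raise ValueError(
                            f"categorical trait {t!r} varies within species {sp!r}: {list(levels)}")
                    row[t] = levels[0] if len(levels) else pd.NA
            rows[normalize_name(sp)] = row
        return cls(pd.DataFrame.from_dict(rows, orient="index"), schema)


class Phylogeny:
    """Rooted tree with branch lengths, backed by dendropy.

    Every edge except the root's must carry a nonnegative length; tip labels
    are unique after whitespace/underscore normalization.
    """

    def __init__(self, tree: dendropy.Tree):
        for taxon in tree.taxon_namespace:
            taxon.label = normalize_name(taxon.label)
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(labels) < 2:
            raise ValueError("tree must have at least 2 tips")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            if node.edge.length is None:
                raise ValueError("edge without branch length")
            if node.edge.length < 0:
                raise ValueError("negative branch length")
        self.tree = tree

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True,
                                   unquoted_underscores=True).strip()

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.as_newick() + "\n")

    def clone(self) -> "Phylogeny":
        return Phylogeny(self.tree.clone(depth=1))

    def __repr__(self):
        return f"Phylogeny({self.n_tips} tips)"


class SiteCovariates:
    """Per-site sampling effort (days) and altitude (m)."""

    def __init__(self, table: pd.DataFrame):
        table = table.copy()
        table.index = [normalize_name(s) for s in table.index]
        for col in ("sampling_days", "altitude_m"):
            if col not in table.columns:
                raise ValueError(f"covariates missing column {col!r}")
            table[col] = pd.to_numeric(table[col])
        if (table["sampling_days"] <= 0).any() or (table["sampling_days"] % 1 != 0).any():
            raise ValueError("sampling_days must be positive integers")
        if (table["altitude_m"] < 0).any():
            raise ValueError("altitude_m must be nonnegative")
        self.table = table[["sampling_days", "altitude_m"]]

    @property
    def site_ids(self) -> list[str]:
        return list(self.table.index)

    def subset(self, sites: list[str]) -> "SiteCovariates":
        missing = [s for s in sites if s not in self.table.index]
        if missing:
            raise ValueError(f"sites without covariates: {missing}")
        return SiteCovariates(self.table.loc[sites])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="site")


@dataclass
class ReconcileReport:
    dropped_species: list[str] = field(default_factory=list)
    tip_substitutions: dict[str, str] = field(default_factory=dict)
    unmapped_species: list[str] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not (self.dropped_species or self.tip_substitutions or self.unmapped_species)


@dataclass
class AnalysisDataset:
    """The four artifacts, reconciled onto a common species and site set."""

    community: CommunityMatrix
    traits: TraitTable
    tree: Phylogeny
    covariates: SiteCovariates
    report: ReconcileReport

    @property
    def species_ids(self) -> list[str]:
        return self.community.species_ids

    @property
    def site_ids(self) -> list[str]:
        return self.community.site_ids


def read_community(path, *, prune_empty_species: bool = False) -> CommunityMatrix:
    """Read a site x species abundance CSV (first column = site names)."""
    import csv

    with open(path, newline="") as fh:
        header = next(csv.reader(fh))[1:]  # pandas silently mangles dupes
    if len(set(header)) != len(header):
        raise ValueError("duplicate species columns in community CSV")
    df = pd.read_csv(path, index_col=0)
    try:
        values = df.to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise ValueError("non-numeric cell in community CSV") from exc
    return CommunityMatrix(values, df.index, df.columns,
                           prune_empty_species=prune_empty_species)


def read_traits(path, schema_path) -> tuple[TraitTable, TraitSchema]:
    """Read a species x trait CSV plus its YAML schema."""
    schema = TraitSchema.from_yaml(schema_path)
    df = pd.read_csv(path, index_col=0)
    return TraitTable(df, schema), schema


def read_tree(path) -> Phylogeny:
    """Read a rooted Newick tree with branch lengths."""
    with open(path) as fh:
        text = fh.read()
    return parse_newick(text)


def parse_newick(text: str) -> Phylogeny:
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 suppress_internal_node_taxa=True)
    except Exception as exc:
        raise ValueError(f"malformed Newick: {exc}") from exc
    return Phylogeny(tree)


def read_covariates(path) -> SiteCovariates:
    return SiteCovariates(pd.read_csv(path, index_col=0))


def reconcile(cm: CommunityMatrix, tt: TraitTable, tree: Phylogeny,
              cov: SiteCovariates, *, policy: str = "error") -> AnalysisDataset:
    """Align the four artifacts onto a common species and site set.

    Community species lacking trait data are dropped (policy="drop", with a
    warning) or raise (policy="error").  Species absent from the tree are
    mapped onto unused congeneric tips; species with neither trait data nor
    a tree mapping always raise.  Covariates are aligned to community sites.
    Applying reconcile to an already reconciled dataset is a no-op.
    """
    from .phylo import substitute_tips

    if policy not in ("error", "drop"):
        raise ValueError("policy must be 'error' or 'drop'")
    report = ReconcileReport()

    trait_species = set(tt.species_ids)
    no_traits = [s for s in cm.species_ids if s not in trait_species]
    if no_traits:
        if policy == "error":
            raise ValueError(f"community species without trait data: {no_traits}")
        warnings.warn(f"dropping species without trait data: {no_traits}")
        report.dropped_species.extend(no_traits)
    keep = [s for s in cm.species_ids if s in trait_species]
    if not keep:
        raise ValueError("no community species have trait data")
    cm = cm.subset_species(keep)

    tree2, mapping, unmapped = substitute_tips(tree, cm.species_ids)
    report.tip_substitutions = {k: v for k, v in mapping.items() if k != v}
    if unmapped:
        no_data = [s for s in unmapped if s not in trait_species]
        if no_data:
            raise ValueError(
                f"community species with neither trait data nor tree mapping: {no_data}")
        if policy == "error":
            raise ValueError(f"community species unmappable to tree: {unmapped}")
        warnings.warn(f"dropping species unmappable to tree: {unmapped}")
        report.unmapped_species.extend(unmapped)
        cm = cm.subset_species([s for s in cm.species_ids if s not in set(unmapped)])
        tree2, mapping, _ = substitute_tips(tree, cm.species_ids)
        report.tip_substitutions = {k: v for k, v in mapping.items() if k != v}

    tt = tt.subset(cm.species_ids)
    cov = cov.subset(cm.site_ids)
    return AnalysisDataset(cm, tt, tree2, cov, report)
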