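"""Full-study orchestration: validate -> trait spaces -> FD/PD tables ->
phylogenetic signal -> null-model SES -> richness-association GLMMs.

A single YAML config names the four input files (or a `simulate` block for
a synthetic study) and the run parameters; one global seed is split
deterministically into independent per-stage streams.  Beta-family models
are fitted for the (0,1)-bounded indices (FDiv, FEve, Uniq) and normal
models for the unbounded ones (FDis, MPD, MNTD).
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .functional import build_spaces, fd_table
from .glmm import DiversityRichnessModel, spearman_effort_check
from .io import (AnalysisDataset, read_community, read_covariates, read_traits,
                 read_tree, reconcile)
from .metrics import standard_metrics
from .nullmodels import ses_table
from .phylo import cophenetic, pd_table
from .phylosignal import signal_table
from .simulate import SimConfig, simulate_dataset

__all__ = ["ResultBundle", "run_pipeline", "load_config", "BETA_INDICES",
           "NORMAL_INDICES"]

log = logging.getLogger("divkit")

BETA_INDICES = ("FDiv", "FEve", "Uniq")
NORMAL_INDICES = ("FDis", "MPD", "MNTD")


@dataclass
class ResultBundle:
    """All stage outputs of one pipeline run plus reproducibility metadata."""

    dataset: AnalysisDataset
    fd: pd.DataFrame
    pd_: pd.DataFrame
    signal: pd.DataFrame
    ses: pd.DataFrame
    glmm_summary: pd.DataFrame
    glmm_diagnostics: pd.DataFrame
    effort_check: dict
    metadata: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tidy_fd = self.fd.melt(id_vars=["site", "category", "S"],
                               value_vars=["FDis", "FDiv", "FEve", "Uniq"],
                               var_name="index", value_name="value")
        tidy_fd[["site", "category", "index", "value", "S"]].to_csv(
            outdir / "fd_table.csv", index=False)
        self.pd_.to_csv(outdir / "pd_table.csv", index=False)
        self.signal.to_csv(outdir / "lambda_table.csv", index=False)
        self.ses.to_csv(outdir / "ses_table.csv", index=False)
        self.glmm_summary.to_csv(outdir / "glmm_summary.csv", index=False)
        self.glmm_diagnostics.to_csv(outdir / "glmm_diagnostics.csv", index=False)
        with open(outdir / "run_metadata.json", "w") as fh:
            json.dump({**self.metadata, "effort_check": self.effort_check},
                      fh, indent=2, default=str)


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        return dict(path_or_dict)
    with open(path_or_dict) as fh:
        return yaml.safe_load(fh)


def load_dataset(cfg: dict, rng: np.random.Generator) -> AnalysisDataset:
    if "simulate" in cfg:
        sim_kwargs = dict(cfg["simulate"] or {})
        for key in ("richness_range", "sampling_days_range", "altitude_range",
                    "lambda_range"):
            if key in sim_kwargs:
                sim_kwargs[key] = tuple(sim_kwargs[key])
        study = simulate_dataset(SimConfig(**sim_kwargs), rng)
        return study.reconciled()
    inputs = cfg.get("inputs")
    if not inputs:
        raise ValueError("config needs an 'inputs' or 'simulate' block")
    for key in ("community", "traits", "trait_schema", "tree", "covariates"):
        if key not in inputs:
            raise ValueError(f"config missing input {key!r}")
        if not pathlib.Path(inputs[key]).exists():
            raise FileNotFoundError(f"input {key!r} not found: {inputs[key]}")
    cm = read_community(inputs["community"])
    tt, _ = read_traits(inputs["traits"], inputs["trait_schema"])
    tree = read_tree(inputs["tree"])
    cov = read_covariates(inputs["covariates"])
    return reconcile(cm, tt, tree, cov, policy=cfg.get("reconcile_policy", "error"))


def _stage(name):
    def deco(fn):
        def wrapped(*a, **k):
            log.info("stage %s ...", name)
            try:
                return fn(*a, **k)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config, outdir=None) -> ResultBundle:
    """Run the whole analysis from a config dict or YAML path."""
    cfg = load_config(config)
    seed = int(cfg.get("seed", 0))
    streams = np.random.SeedSequence(seed).spawn(4)
    rng_sim, rng_ses, rng_glmm, rng_ppc = (np.random.default_rng(s) for s in streams)

    dataset = _stage("validate")(load_dataset)(cfg, rng_sim)
    correction = cfg.get("correction", "sqrt")
    categories = cfg.get("categories")

    spaces = _stage("space")(build_spaces)(dataset, categories, correction)
    fd = _stage("fd")(fd_table)(dataset, spaces=spaces)
    Dphylo = cophenetic(dataset.tree)
    pdt = _stage("pd")(pd_table)(dataset.community, Dphylo)
    sig = _stage("signal")(signal_table)(dataset.tree, dataset.traits)

    n_iter = int(cfg.get("null_model", {}).get("iters", 1000))
    metrics = standard_metrics(dataset, spaces, Dphylo)
    sest = _stage("ses")(ses_table)(dataset.community, metrics,
                                    n_iter=n_iter, rng=rng_ses)

    mcmc = {"n_chains": 3, "n_samples": 20_000, "burn_in": 5_000, "thin": 10}
    mcmc.update(cfg.get("mcmc", {}))
    glmm_summary, glmm_diag = _stage("glmm")(_fit_glmms)(
        dataset, fd, pdt, mcmc, rng_glmm, rng_ppc)

    richness = dataset.community.richness()
    days = dataset.covariates.table["sampling_days"].to_numpy()
    rho, pval = spearman_effort_check(richness, days)
    effort = {"rho": rho, "p": pval}

    meta = {
        "seed": seed, "divkit_version": __version__,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest(),
        "n_sites": dataset.community.n_sites,
        "n_species": dataset.community.n_species,
        "null_iters": n_iter, "mcmc": mcmc,
    }
    bundle = ResultBundle(dataset, fd, pdt, sig, sest, glmm_summary,
                          glmm_diag, effort, meta)
    if outdir or cfg.get("output"):
        bundle.write(outdir or cfg["output"])
    return bundle


def _fit_glmms(dataset, fd, pdt, mcmc, rng, rng_ppc):
    days = dataset.covariates.table["sampling_days"]
    alt = dataset.covariates.table["altitude_m"]
    frames, diags = [], []
    jobs = []
    for cat in fd["category"].unique():
        sub = fd[fd["category"] == cat].set_index("site")
        for index in ("FDis", "FDiv", "FEve", "Uniq"):
            jobs.append((index, cat, sub[index], sub["S"]))
    psub = pdt.set_index("site")
    for index in ("MPD", "MNTD"):
        jobs.append((index, "phylo", psub[index], psub["S"]))
    for index, cat, y, S in jobs:
        family = "beta" if index in BETA_INDICES else "normal"
        sites = y.index
        model = DiversityRichnessModel(
            y.to_numpy(), S.to_numpy(), days.loc[sites].to_numpy(),
            alt.loc[sites].to_numpy(), family=family, name=f"{index}:{cat}")
        fit_seed = int(rng.integers(2**31 - 1))
        res = model.fit(seed=fit_seed, **mcmc)
        summ = res.summary()
        summ.insert(0, "index", index)
        summ.insert(1, "category", cat)
        frames.append(summ)
        bp, ratio = res.posterior_predictive_check(
            seed=int(rng_ppc.integers(2**31 - 1)))
        lo, hi = res.credible_interval("beta1")
        diags.append({"index": index, "category": cat, "family": family,
                      "beta1_mean": res.posterior_mean("beta1"),
                      "beta1_q2.5": lo, "beta1_q97.5": hi,
                      "max_rhat": max(res.rhat_.values()),
                      "converged": res.converged,
                      "bayes_p": bp, "chi2_fit_ratio": ratio})
    return pd.concat(frames, ignore_index=True), pd.DataFrame(diags)
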