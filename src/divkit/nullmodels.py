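"""Independent-swap null models and standardized effect sizes.

The randomization repeatedly finds 2x2 submatrices with a checkerboard
occupancy pattern and swaps the two occupied cells between the two sites
(within their species columns).  This preserves, exactly: species richness
of every site (row occupancy), occurrence frequency of every species
(column occupancy), and each species' multiset of abundance values — the
quantities the study design holds fixed.  Each null replicate is a fresh
swap chain started from the observed matrix; the standardized effect size
SES = (obs - null mean) / null SD is classified with the +/-2 rule
(< -2 clustered, > 2 overdispersed, otherwise random).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .io import CommunityMatrix

__all__ = ["SESResult", "independent_swap", "null_distribution", "ses",
           "ses_table", "classify_ses"]


@njit(cache=False)
def _swap_kernel(mat, target, max_attempts, seed, count_successes):
    """Run a chain of independent swaps in place.

    Counts either candidate 2x2 inspections ("attempts") or completed swaps,
    per `count_successes`.  Returns (successes, attempts).
    """
    np.random.seed(seed)
    nr, nc = mat.shape
    succ = 0
    att = 0
    while att < max_attempts:
        if count_successes and succ >= target:
            break
        if not count_successes and att >= target:
            break
        i = np.random.randint(0, nr)
        j = np.random.randint(0, nr)
        k = np.random.randint(0, nc)
        l = np.random.randint(0, nc)
        if i == j or k == l:
            continue
        att += 1
        a = mat[i, k]
        b = mat[i, l]
        c = mat[j, k]
        d = mat[j, l]
        if (a > 0 and d > 0 and b == 0 and c == 0) or \
           (b > 0 and c > 0 and a == 0 and d == 0):
            mat[i, k] = c
            mat[j, k] = a
            mat[i, l] = d
            mat[j, l] = b
            succ += 1
    return succ, att


def _run_chain(matrix: np.ndarray, rng: np.random.Generator, *,
               n_swaps: int, count_successes: bool,
               max_attempts: int | None = None) -> tuple[np.ndarray, int]:
    out = matrix.copy()
    if max_attempts is None:
        max_attempts = 200 * n_swaps + 10_000
    seed = int(rng.integers(1, 2**31 - 1))
    succ, _ = _swap_kernel(out, n_swaps, max_attempts, seed, count_successes)
    return out, succ


def independent_swap(cm: CommunityMatrix, n_swaps: int,
                     rng: np.random.Generator, *,
                     count_successes: bool = False,
                     max_attempts: int | None = None) -> CommunityMatrix:
    """Randomize a community matrix by independent swaps.

    `n_swaps` counts candidate 2x2 inspections by default, or completed
    swaps with ``count_successes=True``.  A matrix admitting no checkerboard
    (e.g. all cells occupied) is returned unchanged with a warning.
    """
    if n_swaps <= 0:
        raise ValueError("n_swaps must be positive")
    out, succ = _run_chain(cm.abundance, rng, n_swaps=n_swaps,
                           count_successes=count_successes,
                           max_attempts=max_attempts)
    if succ == 0:
        warnings.warn("no checkerboard submatrix found; matrix unchanged")
    return CommunityMatrix(out, cm.site_ids, cm.species_ids)


def default_n_swaps(cm: CommunityMatrix) -> int:
    """Successful swaps per null replicate: 2 x occupied cells."""
    return 2 * int((cm.abundance > 0).sum())


def null_distribution(cm: CommunityMatrix, metric, n_iter: int = 1000,
                      rng: np.random.Generator | None = None,
                      n_swaps: int | None = None):
    """Evaluate a per-site metric on `n_iter` independently randomized
    matrices (each a fresh swap chain from the observed matrix).

    `metric` maps an abundance matrix (sites x species, columns aligned to
    ``cm.species_ids``) to a per-site array or a dict of named per-site
    arrays; undefined values are NaN.  Returns an (n_iter x n_sites) array,
    or a dict of such arrays for a dict-valued metric.
    """
    rng = rng if rng is not None else np.random.default_rng()
    n_swaps = n_swaps if n_swaps is not None else default_n_swaps(cm)
    samples = None
    for it in range(n_iter):
        mat, _ = _run_chain(cm.abundance, rng, n_swaps=n_swaps,
                            count_successes=True)
        vals = metric(mat)
        if samples is None:
            if isinstance(vals, dict):
                samples = {k: np.empty((n_iter, len(v))) for k, v in vals.items()}
            else:
                samples = np.empty((n_iter, len(vals)))
        if isinstance(vals, dict):
            for k, v in vals.items():
                samples[k][it] = v
        else:
            samples[it] = vals
    return samples


def classify_ses(s: float) -> str:
    if not np.isfinite(s):
        return "undefined"
    if s < -2:
        return "clustered"
    if s > 2:
        return "overdispersed"
    return "random"


@dataclass
class SESResult:
    """Observed value against its null distribution for one site/index."""

    observed: float
    null_mean: float
    null_sd: float
    ses: float
    n_valid: int
    classification: str
    site: str = ""
    category: str = ""
    index: str = ""


def ses(observed: float, null_samples: np.ndarray, **labels) -> SESResult:
    """Standardized effect size of one observed value.

    Null moments use the sample SD (n-1); draws where the metric was
    undefined (NaN) are excluded and reported via ``n_valid``.  SES is
    undefined when the observed value is missing, fewer than two valid null
    samples exist, or the null SD is zero.
    """
    null_samples = np.asarray(null_samples, dtype=float)
    valid = null_samples[np.isfinite(null_samples)]
    n_valid = int(valid.size)
    if n_valid < 2 or not np.isfinite(observed):
        return SESResult(observed, float("nan"), float("nan"), float("nan"),
                         n_valid, "undefined", **labels)
    mean = float(valid.mean())
    sd = float(valid.std(ddof=1))
    if sd == 0:
        return SESResult(observed, mean, 0.0, float("nan"), n_valid,
                         "undefined", **labels)
    s = (observed - mean) / sd
    return SESResult(observed, mean, sd, float(s), n_valid, classify_ses(s),
                     **labels)


def ses_table(cm: CommunityMatrix, metrics: dict, n_iter: int = 1000,
              rng: np.random.Generator | None = None,
              n_swaps: int | None = None) -> pd.DataFrame:
    """SES per (site, index) for several metrics sharing one null ensemble.

    `metrics` maps (index, category) labels to per-site metric callables
    (see :func:`null_distribution`); all metrics are evaluated on the same
    randomized matrices so their SES values are comparable.
    """
    rng = rng if rng is not None else np.random.default_rng()

    def combined(mat):
        return {key: np.asarray(fn(mat), dtype=float) for key, fn in metrics.items()}

    observed = combined(cm.abundance)
    nulls = null_distribution(cm, combined, n_iter=n_iter, rng=rng,
                              n_swaps=n_swaps)
    rows = []
    for key, fn in metrics.items():
        index, category = key if isinstance(key, tuple) else (key, "")
        for s_idx, site in enumerate(cm.site_ids):
            r = ses(float(observed[key][s_idx]), nulls[key][:, s_idx],
                    site=site, category=category, index=index)
            rows.append({"site": site, "category": category, "index": index,
                         "observed": r.observed, "null_mean": r.null_mean,
                         "null_sd": r.null_sd, "ses": r.ses,
                         "classification": r.classification,
                         "n_valid": r.n_valid})
    return pd.DataFrame(rows)
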