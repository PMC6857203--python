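"""Permutation-based GO over-representation test.

For a gene set of interest, the expected membership of each GO category is
estimated from equally sized random draws from the gene universe; the
observed membership is converted to a Z-score against the resampling
distribution, a two-sided normal p-value, and a Benjamini-Hochberg
correction across the categories of each annotation domain (biological
process and cellular component are tested separately).  Categories with an
undefined resampling spread are flagged and excluded from the correction;
categories with expected count below one and at most one observed gene are
flagged as unsupported singletons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class EnrichmentResult:
    """Per-category permutation-test outcome."""

    category: str
    domain: str
    observed: int
    expected: float
    sd: float
    z: float
    p: float
    p_adjusted: float
    significant: bool
    kept: bool


def _category_matrix(universe: list, categories: dict) -> np.ndarray:
    index = {g: i for i, g in enumerate(universe)}
    M = np.zeros((len(universe), len(categories)), dtype=bool)
    for j, members in enumerate(categories.values()):
        for g in members:
            if g in index:
                M[index[g], j] = True
    return M


def permutation_enrichment(gene_set, universe, go_annotation, *,
                           n_resamples: int = 1000, seed: int = 0,
                           alpha: float = 0.05, two_sided: bool = True
                           ) -> pd.DataFrame:
    """Permutation GO over-representation test for one gene set.

    ``gene_set`` must be a subset of ``universe``.  Each annotation domain
    of ``go_annotation`` is tested separately; within a domain, category
    counts of ``n_resamples`` random same-size gene draws give the expected
    count and spread.  Returns one row per (domain, category).
    """
    gene_set = list(dict.fromkeys(gene_set))
    universe = list(dict.fromkeys(universe))
    uset = set(universe)
    if not gene_set:
        raise ValueError("empty gene set")
    missing = [g for g in gene_set if g not in uset]
    if missing:
        raise ValueError(f"gene set not contained in universe: {missing[:5]}")
    rng = np.random.default_rng(seed)
    k = len(gene_set)
    results = []
    for domain, categories in go_annotation.domains.items():
        if not categories:
            continue
        M = _category_matrix(universe, categories)
        obs_idx = [universe.index(g) for g in gene_set]
        observed = M[obs_idx].sum(axis=0)
        counts = np.empty((n_resamples, M.shape[1]))
        for r in range(n_resamples):
            draw = rng.choice(len(universe), size=k, replace=False)
            counts[r] = M[draw].sum(axis=0)
        expected = counts.mean(axis=0)
        sd = counts.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (observed - expected) / sd
        # a constant resampling distribution matching the observation is a
        # well-defined null result (Z = 0); constant but mismatched is not
        exact = (sd == 0) & (observed == expected)
        z[exact] = 0.0
        testable = (sd > 0) | exact
        p = np.full(M.shape[1], np.nan)
        if two_sided:
            p[testable] = 2.0 * sps.norm.sf(np.abs(z[testable]))
        else:
            p[testable] = sps.norm.sf(z[testable])
        p_adj = np.full(M.shape[1], np.nan)
        if testable.any():
            p_adj[testable] = bh_adjust(p[testable])
        for j, cat in enumerate(categories):
            kept = not (expected[j] < 1.0 and observed[j] <= 1)
            results.append(EnrichmentResult(
                category=cat, domain=domain, observed=int(observed[j]),
                expected=float(expected[j]), sd=float(sd[j]),
                z=float(z[j]) if testable[j] else np.nan,
                p=float(p[j]) if testable[j] else np.nan,
                p_adjusted=float(p_adj[j]) if testable[j] else np.nan,
                significant=bool(testable[j] and kept
                                 and p_adj[j] < alpha),
                kept=kept,
            ))
    return pd.DataFrame([r.__dict__ for r in results])
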