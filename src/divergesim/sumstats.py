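"""Per-locus population-genetic statistics and across-locus summaries.

All statistics operate on integer allele matrices with rows = samples and
columns = sites.  Two encodings are supported via the ``ploidy`` argument:
phased haplotypes (entries 0/1, ``ploidy=1``) and diploid allele dosages
(entries 0/1/2, ``ploidy=2``).  Missing data is encoded as -1 and handled by
pairwise/sitewise-complete allele counts.

Estimators:

* nucleotide diversity (pi): mean pairwise difference per site, computed
  from per-site allele counts;
* Tajima's D in the standard normalisation (NaN when S < 3);
* F_ST: Weir & Cockerham (1984) variance components on diploid genotypes,
  aggregated over sites as a ratio of sums (the "weighted" estimator);
  negative estimates are reported as-is;
* d_XY: mean between-population pairwise difference per site (Nei), and
  d_f: count of fixed differences;
* mean r^2: average squared Pearson correlation of dosages over all pairs
  of polymorphic sites.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .simulator import HaplotypeData

#: default statistics entering the ABC summary vector, in declared order
DEFAULT_SUMMARY_STATS = ("pi_K", "pi_W", "d_K", "d_W", "fst", "dxy", "r2")

#: all per-locus statistic fields, matching the engine row order
LOCUS_STAT_FIELDS = ("pi_K", "pi_W", "d_K", "d_W", "fst", "dxy", "df", "r2",
                     "S", "d_pool")


def _counts(M: np.ndarray, ploidy: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-site derived-allele and called-allele counts (missing = -1)."""
    M = np.asarray(M)
    called = M >= 0
    derived = np.where(called, M, 0).sum(axis=0).astype(float)
    n_alleles = ploidy * called.sum(axis=0).astype(float)
    return derived, n_alleles


def _pi_sites(M: np.ndarray, ploidy: int) -> np.ndarray:
    """Per-site mean pairwise difference (0 where fewer than 2 alleles)."""
    c, n = _counts(M, ploidy)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = 2.0 * c * (n - c) / (n * (n - 1.0))
    pi[n < 2] = 0.0
    return pi


def nucleotide_diversity(M: np.ndarray, length: float, ploidy: int = 1) -> float:
    """Nucleotide diversity per site over a region of ``length`` bp."""
    if length <= 0:
        raise ValueError("region length must be positive")
    M = np.atleast_2d(np.asarray(M))
    if M.shape[0] < 2 and ploidy == 1:
        raise ValueError("need at least two sequences")
    if M.shape[1] == 0:
        return 0.0
    return float(_pi_sites(M, ploidy).sum() / length)


def tajima_constants(n: int) -> tuple[float, float, float]:
    """(a1, e1, e2) of the Tajima's D normalisation for sample size n."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1 ** 2
    return a1, c1 / a1, c2 / (a1 ** 2 + a2)


def tajimas_d(M: np.ndarray, ploidy: int = 1) -> float:
    """Tajima's D; NaN when fewer than 3 segregating sites or n < 4.

    With missing data, per-site allele counts are sitewise-complete while the
    normalisation constants use the nominal sample size.
    """
    M = np.atleast_2d(np.asarray(M))
    n = ploidy * M.shape[0]
    c, ns = _counts(M, ploidy)
    seg = (c > 0) & (c < ns)
    S = int(seg.sum())
    if S < 3 or n < 4:
        return math.nan
    pi_sum = float(_pi_sites(M, ploidy).sum())
    a1, e1, e2 = tajima_constants(n)
    var = e1 * S + e2 * S * (S - 1.0)
    if var <= 0:
        return math.nan
    return (pi_sum - S / a1) / math.sqrt(var)


def wc_fst(G: np.ndarray, pop_labels: np.ndarray
           ) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Weir-Cockerham (1984) F_ST from diploid dosages, two populations.

    Returns per-site variance components ``(a, b, c)`` and the ratio-of-sums
    estimate ``sum(a) / sum(a+b+c)`` over sites with a defined denominator.
    Sites with fewer than 2 called genotypes in either population are NaN in
    the component arrays and excluded from the aggregate.
    """
    G = np.atleast_2d(np.asarray(G))
    pop_labels = np.asarray(pop_labels)
    groups = [G[pop_labels == p] for p in np.unique(pop_labels)]
    if len(groups) != 2:
        raise ValueError("F_ST requires exactly two populations")
    ni, pi_, hi = [], [], []
    for sub in groups:
        called = sub >= 0
        n_i = called.sum(axis=0).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_i = np.where(called, sub, 0).sum(axis=0) / (2.0 * n_i)
            h_i = np.where(called & (sub == 1), 1, 0).sum(axis=0) / n_i
        ni.append(n_i)
        pi_.append(p_i)
        hi.append(h_i)
    n1, n2 = ni
    p1, p2 = pi_
    h1, h2 = hi
    with np.errstate(divide="ignore", invalid="ignore"):
        nbar = (n1 + n2) / 2.0
        nc = 2.0 * nbar - (n1 ** 2 + n2 ** 2) / (2.0 * nbar)
        pbar = (n1 * p1 + n2 * p2) / (2.0 * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
        hbar = (n1 * h1 + n2 * h2) / (2.0 * nbar)
        pq = pbar * (1.0 - pbar)
        inner = pq - s2 / 2.0 - hbar / 4.0
        a = (nbar / nc) * (s2 - inner / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (pq - s2 / 2.0
                                     - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar))
        cc = hbar / 2.0
    bad = (n1 < 2) | (n2 < 2)
    for arr in (a, b, cc):
        arr[bad] = np.nan
    den = np.nansum(a + b + cc)
    fst = float(np.nansum(a) / den) if den != 0 and np.isfinite(den) else math.nan
    return a, b, cc, fst


def dxy_and_df(M: np.ndarray, pop_labels: np.ndarray, length: float,
               ploidy: int = 1) -> tuple[float, int]:
    """Absolute divergence d_XY (per site) and the count of fixed differences.

    Sites with no called alleles in either population are skipped.
    """
    if length <= 0:
        raise ValueError("region length must be positive")
    M = np.atleast_2d(np.asarray(M))
    pop_labels = np.asarray(pop_labels)
    pops = np.unique(pop_labels)
    if len(pops) != 2:
        raise ValueError("d_XY requires exactly two populations")
    freqs = []
    oks = []
    for p in pops:
        c, n = _counts(M[pop_labels == p], ploidy)
        with np.errstate(divide="ignore", invalid="ignore"):
            freqs.append(c / n)
        oks.append(n > 0)
    p1, p2 = freqs
    ok = oks[0] & oks[1]
    dxy = float(np.sum((p1 * (1 - p2) + p2 * (1 - p1))[ok]) / length)
    fixed = ok & (((p1 == 1) & (p2 == 0)) | ((p1 == 0) & (p2 == 1)))
    return dxy, int(fixed.sum())


def mean_r2(M: np.ndarray, ploidy: int = 2, *,
            exact_cap: int | None = None, sample_pairs: int = 100,
            rng: np.random.Generator | None = None) -> float:
    """Mean squared Pearson correlation of allele dosage over pairs of
    polymorphic sites; NaN when fewer than 2 polymorphic sites.

    By default all site pairs are used.  With ``exact_cap`` set, loci whose
    total number of site pairs exceeds the cap are instead estimated from
    ``sample_pairs`` uniformly drawn site pairs (unbiased) -- the same rule
    the fast simulation path uses, so summaries of observed and simulated
    data stay estimator-consistent.  Missing entries are handled by
    pairwise-complete correlation.
    """
    M = np.atleast_2d(np.asarray(M)).astype(float)
    M[M < 0] = np.nan
    with np.errstate(invalid="ignore"):
        var = np.nanvar(M, axis=0)
    poly = var > 0
    X = M[:, poly]
    S = X.shape[1]
    if S < 2:
        return math.nan
    n_pairs_total = S * (S - 1) // 2
    if exact_cap is not None and n_pairs_total > exact_cap:
        rng = rng or np.random.default_rng(0)
        vals = []
        drawn = 0
        attempts = 0
        while drawn < sample_pairs and attempts < 20 * sample_pairs:
            attempts += 1
            u, v = rng.integers(0, S, size=2)
            if u == v:
                continue
            drawn += 1
            pair = X[:, [u, v]]
            ok = ~np.isnan(pair).any(axis=1)
            if ok.sum() < 2:
                continue
            with np.errstate(invalid="ignore"):
                r = np.corrcoef(pair[ok, 0], pair[ok, 1])[0, 1]
            if np.isfinite(r):
                vals.append(r ** 2)
        return float(np.mean(vals)) if vals else math.nan
    if np.isnan(X).any():
        corr = np.ma.corrcoef(np.ma.masked_invalid(X), rowvar=False)
        r2 = np.asarray(corr) ** 2
    else:
        r2 = np.corrcoef(X, rowvar=False) ** 2
    iu = np.triu_indices(S, k=1)
    vals = r2[iu]
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if vals.size else math.nan


def segregating_sites(M: np.ndarray, ploidy: int = 1) -> int:
    c, n = _counts(np.atleast_2d(np.asarray(M)), ploidy)
    return int(((c > 0) & (c < n)).sum())


# ---------------------------------------------------------------------------
# per-locus bundles

@dataclass
class LocusStats:
    """All per-locus statistics; NaN marks undefined values."""

    pi_K: float
    pi_W: float
    d_K: float
    d_W: float
    fst: float
    dxy: float
    df: float
    r2: float
    S: float
    d_pool: float
    length: float = math.nan

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in LOCUS_STAT_FIELDS])

    @classmethod
    def from_array(cls, row: np.ndarray, length: float = math.nan
                   ) -> "LocusStats":
        return cls(*[float(v) for v in row], length=length)


def locus_stats_from_haplotypes(hap: HaplotypeData, *,
                                r2_exact_cap: int | None = None,
                                r2_sample_pairs: int = 100,
                                rng: np.random.Generator | None = None
                                ) -> LocusStats:
    """Per-locus statistics for phased simulated data.

    pi, Tajima's D, d_XY and d_f use the haplotypes directly; F_ST and r^2
    use diploid dosages from the fixed sequential haplotype pairing (matching
    how the same statistics are computed on observed genotype data).  The
    ``r2_*`` arguments select the pair-sampled r^2 estimator of
    :func:`mean_r2` so summaries can be made estimator-consistent with the
    fast simulation path.
    """
    H = hap.matrix
    pops = hap.pops
    L = hap.length
    HK = H[pops == "K"]
    HW = H[pops == "W"]
    G = hap.dosages()
    dpops = hap.diploid_pops()
    dxy, df = dxy_and_df(H, pops, L, ploidy=1)
    _, _, _, fst = wc_fst(G, dpops)
    return LocusStats(
        pi_K=nucleotide_diversity(HK, L, ploidy=1),
        pi_W=nucleotide_diversity(HW, L, ploidy=1),
        d_K=tajimas_d(HK, ploidy=1),
        d_W=tajimas_d(HW, ploidy=1),
        fst=fst,
        dxy=dxy,
        df=df,
        r2=mean_r2(G, ploidy=2, exact_cap=r2_exact_cap,
                   sample_pairs=r2_sample_pairs, rng=rng),
        S=segregating_sites(H, ploidy=1),
        d_pool=tajimas_d(H, ploidy=1),
        length=L,
    )


def locus_stats_from_genotypes(G: np.ndarray, pop_labels: np.ndarray,
                               length: float, *,
                               r2_exact_cap: int | None = None,
                               r2_sample_pairs: int = 100,
                               rng: np.random.Generator | None = None
                               ) -> LocusStats:
    """Per-locus statistics for (possibly unphased) diploid dosage data."""
    G = np.atleast_2d(np.asarray(G))
    pop_labels = np.asarray(pop_labels)
    GK = G[pop_labels == "K"]
    GW = G[pop_labels == "W"]
    dxy, df = dxy_and_df(G, pop_labels, length, ploidy=2)
    _, _, _, fst = wc_fst(G, pop_labels)
    return LocusStats(
        pi_K=nucleotide_diversity(GK, length, ploidy=2),
        pi_W=nucleotide_diversity(GW, length, ploidy=2),
        d_K=tajimas_d(GK, ploidy=2),
        d_W=tajimas_d(GW, ploidy=2),
        fst=fst,
        dxy=dxy,
        df=df,
        r2=mean_r2(G, ploidy=2, exact_cap=r2_exact_cap,
                   sample_pairs=r2_sample_pairs, rng=rng),
        S=segregating_sites(G, ploidy=2),
        d_pool=tajimas_d(G, ploidy=2),
        length=length,
    )


# ---------------------------------------------------------------------------
# across-locus summaries

@dataclass
class SummaryVector:
    """Across-locus means and variances of selected per-locus statistics.

    ``values`` holds ``(mean_s, var_s)`` pairs in the declared statistic
    order; ``n_excluded`` counts loci dropped per statistic for being
    undefined.  ``aux`` carries auxiliary across-locus means that are not
    part of the distance vector (the pooled Tajima's D used by the
    simulation filter, the mean F_ST and the locus count).
    """

    values: np.ndarray
    names: list
    statistics: tuple
    n_loci: int
    n_excluded: dict = field(default_factory=dict)
    aux: dict = field(default_factory=dict)

    def to_frame(self) -> "pd.DataFrame":
        """Single-row table with the named summary entries."""
        import pandas as pd

        return pd.DataFrame([dict(zip(self.names, self.values))])


def locus_stats_frame(stats: list) -> "pd.DataFrame":
    """One row per locus, columns in the declared statistic order."""
    import pandas as pd

    return pd.DataFrame([{f: getattr(s, f) for f in
                          LOCUS_STAT_FIELDS + ("length",)} for s in stats])


def summary_names(statistics=DEFAULT_SUMMARY_STATS) -> list:
    names = []
    for s in statistics:
        names += [f"mean_{s}", f"var_{s}"]
    return names


def summarize_rows(rows: np.ndarray, statistics=DEFAULT_SUMMARY_STATS
                   ) -> np.ndarray:
    """Vectorised summary over engine statistic rows.

    ``rows`` has shape (n_sims, n_loci, len(LOCUS_STAT_FIELDS)); returns an
    array of shape (n_sims, 2 * len(statistics)) with NaN where a statistic
    has fewer than two defined loci.
    """
    rows = np.asarray(rows)
    idx = [LOCUS_STAT_FIELDS.index(s) for s in statistics]
    out = np.empty((rows.shape[0], 2 * len(idx)))
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for j, i in enumerate(idx):
            col = rows[:, :, i]
            ndef = np.sum(~np.isnan(col), axis=1)
            out[:, 2 * j] = np.where(ndef >= 1, np.nanmean(col, axis=1), np.nan)
            out[:, 2 * j + 1] = np.where(
                ndef >= 2, np.nanvar(col, axis=1, ddof=1), np.nan)
    return out


def summarize_dataset(stats: list, statistics=DEFAULT_SUMMARY_STATS
                      ) -> SummaryVector:
    """Across-locus summary vector from a list of LocusStats."""
    if len(stats) < 2:
        raise ValueError("need at least two loci to form a summary vector")
    rows = np.stack([s.as_array() for s in stats])[None, :, :]
    values = summarize_rows(rows, statistics)[0]
    n_excluded = {}
    for s in statistics:
        col = rows[0, :, LOCUS_STAT_FIELDS.index(s)]
        n_excluded[s] = int(np.isnan(col).sum())
        if np.isnan(col).all():
            raise ValueError(f"statistic {s!r} undefined for every locus")
    if np.isnan(values).any():
        bad = [n for n, v in zip(summary_names(statistics), values)
               if np.isnan(v)]
        raise ValueError(f"undefined summary entries: {bad}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        aux = {
            "mean_d_pool": float(np.nanmean(
                rows[0, :, LOCUS_STAT_FIELDS.index("d_pool")])),
            "mean_fst": float(np.nanmean(
                rows[0, :, LOCUS_STAT_FIELDS.index("fst")])),
        }
    return SummaryVector(values=values, names=summary_names(statistics),
                         statistics=tuple(statistics), n_loci=len(stats),
                         n_excluded=n_excluded, aux=aux)
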