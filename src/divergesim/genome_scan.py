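"""Genome divergence scan: SNP filtering, windowed and per-gene statistics,
percentile outlier calling, and extraction of ABC loci from a variant table.

Windows tile each scaffold from its first base (50 kb by default); windows
spanning fewer than 25 kb of scaffold are excluded.  Statistics within
windows and gene coding regions come from :mod:`divergesim.sumstats`.
Percentile cutoffs are computed within chromosome strata (autosomes and the
Z separately) with the type-7 linear-interpolation quantile; W-chromosome
scaffolds are excluded from the scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import sumstats
from .io_formats import GeneAnnotation, ScaffoldMap, VariantTable


def snp_prefilter(table: VariantTable, *, max_missing: float = 0.10,
                  min_maf: float = 0.05, span: int = 10,
                  max_snps_per_span: int = 3
                  ) -> tuple[VariantTable, dict]:
    """Site filters applied before any scan statistic.

    Keeps sites with missing fraction <= ``max_missing`` and minor-allele
    frequency strictly greater than ``min_maf``; then enforces at most
    ``max_snps_per_span`` SNPs within any ``span`` bp on a scaffold by
    greedy left-to-right removal of the rightmost excess site.  Returns the
    filtered table and a tally of exclusions per rule.
    """
    if table.n_sites == 0:
        raise ValueError("empty variant table")
    miss = table.missing_fraction()
    G = table.genotypes
    called = (G >= 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(G >= 0, G, 0).sum(axis=0) / (2.0 * called)
    maf = np.minimum(p, 1.0 - p)
    keep = (miss <= max_missing) & (maf > min_maf) & (called > 0)
    tally = {"missing_rate": int((miss > max_missing).sum()),
             "allele_frequency": int(((maf <= min_maf) | (called == 0))
                                     [miss <= max_missing].sum())}
    idx = np.flatnonzero(keep)
    # density rule, per scaffold, greedy left-to-right
    dense_keep = []
    removed = 0
    for scaf in pd.unique(table.scaffolds[idx]):
        sub = idx[table.scaffolds[idx] == scaf]
        window = []  # kept positions within the trailing span
        for i in sub:
            pos = table.pos[i]
            window = [p_ for p_ in window if p_ > pos - span]
            if len(window) >= max_snps_per_span:
                removed += 1
                continue
            window.append(pos)
            dense_keep.append(i)
    tally["snp_density"] = removed
    dense_keep = np.array(sorted(dense_keep), dtype=int)
    return table.take_sites(dense_keep), tally


def _stats_row(G, pops, length) -> dict:
    ls = sumstats.locus_stats_from_genotypes(G, pops, length)
    return {f: getattr(ls, f) for f in sumstats.LOCUS_STAT_FIELDS}


def window_scan(table: VariantTable, smap: ScaffoldMap, *,
                window_size: int = 50_000, min_span: int = 25_000
                ) -> pd.DataFrame:
    """Non-overlapping windowed statistics from the first scaffold base.

    Scaffold lengths come from the table's contig headers; scaffolds absent
    from the map are classed ``unassigned`` with a warning, W-chromosome
    scaffolds are skipped.  Windows spanning less than ``min_span`` bases of
    scaffold are excluded.
    """
    rows = []
    for scaf in pd.unique(table.scaffolds):
        if scaf not in smap:
            warnings.warn(f"scaffold {scaf} absent from scaffold map; "
                          "classed unassigned")
            cls, chrom = "unassigned", scaf
        else:
            chrom, cls, _ = smap.entries[scaf]
        if cls == "W":
            continue
        length = table.scaffold_lengths.get(scaf)
        sites = table.scaffold_sites(scaf)
        if length is None:
            length = int(table.pos[sites].max()) + 1
            warnings.warn(f"no contig length for {scaf}; using last SNP")
        for start in range(0, length, window_size):
            end = min(start + window_size, length)
            if end - start < min_span:
                continue
            in_win = sites[(table.pos[sites] >= start)
                           & (table.pos[sites] < end)]
            row = {"scaffold": scaf, "chrom": chrom, "chrom_class": cls,
                   "start": start, "end": end, "start_1based": start + 1,
                   "n_snps": len(in_win)}
            if len(in_win):
                row.update(_stats_row(table.genotypes[:, in_win],
                                      table.pops, end - start))
            else:
                row.update({f: (0.0 if f in ("pi_K", "pi_W", "dxy", "df", "S")
                                else np.nan)
                            for f in sumstats.LOCUS_STAT_FIELDS})
            rows.append(row)
    return pd.DataFrame(rows)


def per_gene_stats(table: VariantTable, genes: GeneAnnotation,
                   smap: ScaffoldMap) -> pd.DataFrame:
    """Statistics over merged coding intervals of each gene.

    Genes on unassigned scaffolds are retained but flagged (excluded from
    percentile analyses); genes without coding SNPs keep NaN statistics.
    """
    rows = []
    for gene_id, rec in genes.genes.items():
        scaf = rec["scaffold"]
        cls = smap.chrom_class(scaf)
        sites = table.scaffold_sites(scaf)
        pos = table.pos[sites]
        take = []
        for s, e in rec["cds"]:
            lo, hi = np.searchsorted(pos, [s, e])
            take.extend(sites[lo:hi])
        length = sum(e - s for s, e in rec["cds"])
        row = {"gene_id": gene_id, "scaffold": scaf, "chrom_class": cls,
               "n_snps": len(take), "cds_length": length,
               "in_percentile_universe": cls in ("autosome", "Z")}
        if take:
            stats = _stats_row(table.genotypes[:, np.array(take)],
                               table.pops, length)
            row.update({k: stats[k] for k in ("fst", "d_K", "d_W", "pi_K",
                                              "pi_W", "dxy", "S")})
        else:
            row.update({k: np.nan for k in ("fst", "d_K", "d_W", "pi_K",
                                            "pi_W", "dxy", "S")})
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class OutlierSet:
    """Members of one stratum strictly beyond a percentile cutoff."""

    statistic: str
    stratum: str
    direction: str
    percentile: float
    cutoff: float
    members: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)


def call_outliers(df: pd.DataFrame, statistic: str, percentile: float,
                  direction: str = "high", stratum: str = "autosome", *,
                  id_col: str = "gene_id", stratum_col: str = "chrom_class",
                  signed_subset: bool = False, min_values: int = 20
                  ) -> OutlierSet:
    """Percentile outliers of one statistic within one chromosome stratum.

    The cutoff is the type-7 empirical quantile of the stratum's defined
    values; members lie strictly beyond it.  With ``signed_subset`` (the
    Tajima's D convention) the high cutoff is the ``percentile`` of the
    positive values only and the low cutoff the ``100 - percentile`` of the
    negative values only.
    """
    if direction not in ("high", "low"):
        raise ValueError("direction must be 'high' or 'low'")
    sub = df[(df[stratum_col] == stratum) & df[statistic].notna()]
    vals = sub[statistic].to_numpy(dtype=float)
    if signed_subset:
        vals = vals[vals > 0] if direction == "high" else vals[vals < 0]
    if len(vals) < min_values:
        raise ValueError(f"fewer than {min_values} defined values of "
                         f"{statistic} in stratum {stratum!r}")
    q = percentile if direction == "high" else 100.0 - percentile
    cutoff = float(np.quantile(vals, q / 100.0))  # type-7 interpolation
    if direction == "high":
        hit = sub[sub[statistic] > cutoff]
    else:
        hit = sub[sub[statistic] < cutoff]
    return OutlierSet(statistic=statistic, stratum=stratum,
                      direction=direction, percentile=percentile,
                      cutoff=cutoff, members=hit[id_col].tolist())


def stratified_outliers(df: pd.DataFrame, percentile: float = 95.0, *,
                        id_col: str = "gene_id") -> dict:
    """Standard outlier panel: high F_ST plus high/low per-species D,
    autosomes and Z separately.

    Strata with too few defined (or too few same-signed, for D) values are
    skipped with a warning rather than failing the whole panel.
    """
    out = {}
    for stratum in ("autosome", "Z"):
        jobs = [("fst", "high", False)]
        for d_stat in ("d_K", "d_W"):
            jobs += [(d_stat, "high", True), (d_stat, "low", True)]
        for stat, direction, signed in jobs:
            try:
                out[(stat, stratum, direction)] = call_outliers(
                    df, stat, percentile, direction, stratum,
                    id_col=id_col, signed_subset=signed)
            except ValueError as exc:
                warnings.warn(f"outlier calling skipped: {exc}")
    return out


def extract_abc_loci(table: VariantTable, coverage: dict, *,
                     locus_length: int = 10_000,
                     min_coverage: float = 0.8,
                     min_distance: int = 500_000,
                     max_individual_missing: float = 0.4,
                     max_average_missing: float = 0.3,
                     fst_max: float = 0.159,
                     d_range: tuple = (0.0, 1.0),
                     n_loci: int | None = None,
                     seed: int = 0,
                     max_tries_per_scaffold: int = 2000
                     ) -> tuple[list, list, dict]:
    """Random well-spaced loci passing the missingness and neutrality filters.

    Candidate loci are drawn uniformly on scaffolds whose callable-fraction
    exceeds ``min_coverage``, non-overlapping with pairwise start distance
    greater than ``min_distance``; loci are then dropped if any individual
    misses more than 40% of the locus' sites, the average missingness
    exceeds 30%, the locus F_ST exceeds 0.159, or the pooled Tajima's D
    falls outside [0, 1].  Returns (loci, per-locus stats, exclusion
    tallies); each locus is (scaffold, start, end) in 0-based half-open
    coordinates.  Deterministic given ``seed``.
    """
    eligible = [s for s, c in coverage.items()
                if c > min_coverage and s in table.scaffold_lengths]
    if not eligible:
        raise ValueError("no scaffold passes the coverage threshold")
    rng = np.random.default_rng(seed)
    tallies = {"candidates": 0, "no_snps": 0, "individual_missing": 0,
               "average_missing": 0, "fst": 0, "tajimas_d": 0}
    loci, stats = [], []
    for scaf in sorted(eligible):
        length = table.scaffold_lengths[scaf]
        if length < locus_length:
            continue
        starts = []
        for _ in range(max_tries_per_scaffold):
            if n_loci is not None and len(loci) + len(starts) >= 4 * n_loci:
                break
            cand = int(rng.integers(0, length - locus_length + 1))
            if all(abs(cand - s) > min_distance for s in starts):
                starts.append(cand)
        sites = table.scaffold_sites(scaf)
        pos = table.pos[sites]
        for start in sorted(starts):
            tallies["candidates"] += 1
            lo, hi = np.searchsorted(pos, [start, start + locus_length])
            take = sites[lo:hi]
            if len(take) == 0:
                tallies["no_snps"] += 1
                continue
            G = table.genotypes[:, take]
            ind_missing = (G < 0).mean(axis=1)
            if ind_missing.max() > max_individual_missing:
                tallies["individual_missing"] += 1
                continue
            if ind_missing.mean() > max_average_missing:
                tallies["average_missing"] += 1
                continue
            ls = sumstats.locus_stats_from_genotypes(
                G, table.pops, locus_length, r2_exact_cap=300,
                rng=np.random.default_rng(seed + start))
            if not np.isnan(ls.fst) and ls.fst > fst_max:
                tallies["fst"] += 1
                continue
            if not np.isnan(ls.d_pool) and not (
                    d_range[0] <= ls.d_pool <= d_range[1]):
                tallies["tajimas_d"] += 1
                continue
            loci.append((scaf, start, start + locus_length))
            stats.append(ls)
    if n_loci is not None and len(loci) > n_loci:
        pick = rng.choice(len(loci), size=n_loci, replace=False)
        pick.sort()
        loci = [loci[i] for i in pick]
        stats = [stats[i] for i in pick]
    return loci, stats, tallies
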