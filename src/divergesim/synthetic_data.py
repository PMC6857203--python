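"""Synthetic inputs with known ground truth.

Two generators cover everything the pipeline consumes:

* :func:`make_pseudo_observed` -- multi-locus diploid datasets drawn under
  any of the eight demographic models, with optional per-genotype
  missingness, written as VCF + popmap;
* :func:`make_toy_genome` -- a small multi-scaffold genome (VCF, GFF3,
  scaffold map, GO table) whose background windows are simulated under a
  high-migration two-population coalescent tuned to a low F_ST target and
  whose planted island windows use a low-migration coalescent tuned to an
  elevated F_ST target.  Island divergence is therefore mechanistic (the
  island's own genealogies), not post-hoc allele editing, so pi, d_XY and
  Tajima's D co-vary realistically.  A chosen GO category is preferentially
  assigned to island genes at a configurable odds ratio.

Every generator records a :class:`TruthLedger` sufficient to regenerate its
outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import sumstats
from .io_formats import VariantTable, write_popmap, write_vcf
from .simulator import (HaplotypeData, LocusConfig, ModelId, ParameterSet,
                        build_timeline, simulate_dataset,
                        simulate_locus_stats)


@dataclass
class TruthLedger:
    """Everything needed to regenerate a synthetic dataset bit-identically."""

    kind: str
    seed: int
    model: str | None = None
    params: dict | None = None
    config: dict | None = None
    islands: list = field(default_factory=list)
    enriched_category: str | None = None
    island_genes: list = field(default_factory=list)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=True))

    @classmethod
    def load(cls, path) -> "TruthLedger":
        return cls(**yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# pseudo-observed locus datasets

def _loci_to_variant_table(loci: list, missing_mask_rng=None,
                           missingness: float = 0.0) -> VariantTable:
    """Diploidize loci into one VariantTable (one contig per locus)."""
    n_dip = loci[0].matrix.shape[0] // 2
    dpops = loci[0].diploid_pops()
    counts = {"K": 0, "W": 0}
    sample_ids = []
    for p in dpops:
        counts[p] += 1
        sample_ids.append(f"{p}{counts[p]:02d}")
    scafs, pos, ref, alt, blocks = [], [], [], [], []
    lengths = {}
    for i, hap in enumerate(loci):
        name = f"locus_{i:04d}"
        lengths[name] = hap.length
        G = hap.dosages()
        if missingness > 0:
            mask = missing_mask_rng.random(G.shape) < missingness
            G = np.where(mask, -1, G).astype(np.int8)
        blocks.append(G)
        scafs.extend([name] * hap.n_sites)
        pos.extend(hap.positions.tolist())
        ref.extend(["A"] * hap.n_sites)
        alt.extend(["T"] * hap.n_sites)
    return VariantTable(
        sample_ids=sample_ids, pops=dpops,
        scaffolds=np.array(scafs, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        genotypes=np.hstack(blocks).astype(np.int8)
        if blocks else np.empty((n_dip, 0), dtype=np.int8),
        ref=np.array(ref, dtype=object), alt=np.array(alt, dtype=object),
        scaffold_lengths=lengths)


@dataclass
class PseudoObserved:
    """A simulated multi-locus dataset plus its truth ledger."""

    loci: list
    table: VariantTable
    ledger: TruthLedger
    locus_config: LocusConfig

    def summary_vector(self, statistics=sumstats.DEFAULT_SUMMARY_STATS,
                       r2_exact_cap: int = 300, r2_sample_pairs: int = 100
                       ) -> sumstats.SummaryVector:
        """Across-locus summary with the estimator set used for reference
        simulations (pair-sampled r^2), for ABC use."""
        rng = np.random.default_rng(self.ledger.seed + 0x5EED)
        stats = [sumstats.locus_stats_from_haplotypes(
                     h, r2_exact_cap=r2_exact_cap,
                     r2_sample_pairs=r2_sample_pairs, rng=rng)
                 for h in self.loci]
        return sumstats.summarize_dataset(stats, statistics)


def make_pseudo_observed(model, params: ParameterSet, n_loci: int,
                         locus_config: LocusConfig | None = None, *,
                         missingness: float = 0.0, n_K: int = 20,
                         n_W: int = 20, seed: int = 0,
                         out_dir=None) -> PseudoObserved:
    """Simulate a diploid pseudo-observed dataset under one model.

    ``missingness`` is the per-genotype missing probability (uniform across
    individuals and sites).  When ``out_dir`` is given, writes
    ``observed.vcf``, ``popmap.tsv`` and ``truth.yaml`` there.
    """
    if not 0 <= missingness < 1:
        raise ValueError("missingness must lie in [0, 1)")
    model = ModelId.parse(model)
    cfg = locus_config or LocusConfig()
    loci = simulate_dataset(model, params, n_loci, cfg, n_K=n_K, n_W=n_W,
                            seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(101,)))
    table = _loci_to_variant_table(loci, rng, missingness)
    ledger = TruthLedger(kind="pseudo_observed", seed=seed, model=model.name,
                         params=params.as_dict(),
                         config={"n_loci": n_loci, "n_K": n_K, "n_W": n_W,
                                 "missingness": missingness,
                                 **dataclasses.asdict(cfg)})
    obs = PseudoObserved(loci=loci, table=table, ledger=ledger,
                         locus_config=cfg)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_vcf(table, out / "observed.vcf")
        write_popmap(table, out / "popmap.tsv")
        ledger.save(out / "truth.yaml")
    return obs


# ---------------------------------------------------------------------------
# migration calibration

def calibrate_migration(target_fst: float, *, n_K: int = 20, n_W: int = 20,
                        ne: float = 41_000.0, locus_config: LocusConfig
                        | None = None, n_loci: int = 4000, seed: int = 0,
                        max_iter: int = 22) -> float:
    """Symmetric migration rate (2NM) reaching a mean-F_ST target.

    Uses the monotone decrease of F_ST in migration: bisection on log(2NM)
    against the mean Weir-Cockerham F_ST of ``n_loci`` simulated loci under
    a deep-split symmetric two-population model.  Every evaluation reuses
    the same random-number streams (common random numbers), making the
    target function effectively deterministic and monotone so the bisection
    runs to full depth; the residual error is the Monte-Carlo error of one
    ``n_loci``-locus mean.
    """
    if not 0 < target_fst <= 0.9:
        raise ValueError("F_ST target must lie in (0, 0.9] for these "
                         "sample sizes")
    cfg = locus_config or LocusConfig(length=50_000)

    def mean_fst(m):
        params = ParameterSet(T=2e7, Ne_K=ne, Ne_W=ne, Ne_A=ne,
                              M_WtoK=m, M_KtoW=m)
        tl = build_timeline(params, "IM-A", cfg)
        rows = simulate_locus_stats(np.repeat(tl.array[None, :], n_loci,
                                              axis=0),
                                    n_K, n_W, cfg, 1, seed)
        return float(np.nanmean(rows[:, 0, 4]))

    lo, hi = 1e-3, 5e3  # 2NM bracket; F_ST decreasing in M
    if mean_fst(hi) > target_fst or mean_fst(lo) < target_fst:
        raise ValueError("F_ST target outside the reachable bracket")
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)
        if mean_fst(mid) > target_fst:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


# ---------------------------------------------------------------------------
# toy genome

@dataclass
class ToyGenomeConfig:
    """Geometry, divergence targets and annotation layout of the toy genome.

    Defaults emulate the study system at reduced scale: a low genome-wide
    F_ST background (0.046) with localized high-F_ST islands, background
    diversity near 2.6e-3, ~200 windows of 50 kb with islands covering ~1%
    of them, and several-hundred genes with GO categories of at least 50
    members plus a planted enriched category among island genes.
    """

    n_autosomes: int = 4
    scaffold_length: int = 2_000_000
    z_length: int = 2_000_000
    unassigned_length: int = 120_000
    window: int = 50_000
    background_fst: float = 0.046
    island_fst: float = 0.6
    background_pi: float = 2.6e-3
    islands: tuple = (("scaffold_2", 500_000, 600_000),
                      ("scaffold_4", 1_000_000, 1_100_000))
    gene_spacing: int = 20_000
    gene_cds: tuple = ((2_000, 4_000), (6_000, 8_000), (10_000, 12_000))
    n_bp_categories: int = 5
    n_cc_categories: int = 3
    category_size: int = 60
    n_small_categories: int = 3
    planted_category: str = "GO:0009999"
    planted_odds_ratio: float = 20.0
    unannotated_fraction: float = 0.1
    missingness: float = 0.02
    mu: float = 0.8e-8

    @property
    def scaffolds(self) -> dict:
        out = {f"scaffold_{i + 1}": self.scaffold_length
               for i in range(self.n_autosomes)}
        out["scaffold_Z"] = self.z_length
        out["scaffold_un"] = self.unassigned_length
        return out


@dataclass
class ToyGenome:
    table: VariantTable
    gff_lines: list
    scaffold_map_lines: list
    go_lines: list
    coverage: dict
    ledger: TruthLedger

    def write(self, out_dir) -> dict:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {"vcf": out / "genome.vcf", "popmap": out / "popmap.tsv",
                 "gff": out / "genes.gff3", "map": out / "scaffold_map.tsv",
                 "go": out / "go.tsv", "coverage": out / "coverage.tsv",
                 "truth": out / "truth.yaml"}
        write_vcf(self.table, paths["vcf"])
        write_popmap(self.table, paths["popmap"])
        paths["gff"].write_text("\n".join(self.gff_lines) + "\n")
        paths["map"].write_text("\n".join(self.scaffold_map_lines) + "\n")
        paths["go"].write_text("\n".join(self.go_lines) + "\n")
        paths["coverage"].write_text("\n".join(
            f"{s}\t{c}" for s, c in self.coverage.items()) + "\n")
        self.ledger.save(paths["truth"])
        return paths


def make_toy_genome(config: ToyGenomeConfig | None = None, *, seed: int = 0,
                    out_dir=None, n_K: int = 20, n_W: int = 20) -> ToyGenome:
    """Simulate a toy multi-scaffold genome with planted divergence islands.

    Windows are simulated as independent loci: background windows under a
    migration rate calibrated to ``background_fst``, island windows under a
    rate calibrated to ``island_fst``.  Genes are tiled at fixed spacing
    with three CDS exons each; the planted GO category is assigned to
    island genes at ``planted_odds_ratio`` against the baseline membership
    odds.
    """
    cfg = config or ToyGenomeConfig()
    for scaf, s, e in cfg.islands:
        if scaf not in cfg.scaffolds or e > cfg.scaffolds[scaf] or s < 0:
            raise ValueError(f"island {scaf}:{s}-{e} outside its scaffold")
        if s % cfg.window or e % cfg.window:
            raise ValueError("islands must align to window boundaries")
    ne = cfg.background_pi / (8.0 * cfg.mu)  # two demes of size Ne mix
    win_cfg = LocusConfig(length=cfg.window, mu=cfg.mu)
    m_bg = calibrate_migration(cfg.background_fst, n_K=n_K, n_W=n_W, ne=ne,
                               locus_config=win_cfg, seed=seed + 1)
    m_isl = calibrate_migration(cfg.island_fst, n_K=n_K, n_W=n_W, ne=ne,
                                locus_config=win_cfg, seed=seed + 2)

    def window_timeline(m):
        params = ParameterSet(T=2e7, Ne_K=ne, Ne_W=ne, Ne_A=ne,
                              M_WtoK=m, M_KtoW=m)
        return build_timeline(params, "IM-A", win_cfg)

    island_lookup = {}
    for scaf, s, e in cfg.islands:
        for w in range(s // cfg.window, e // cfg.window):
            island_lookup[(scaf, w)] = True

    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(1,)))
    loci = []
    meta = []
    for scaf, length in cfg.scaffolds.items():
        for w in range(length // cfg.window):
            m = m_isl if (scaf, w) in island_lookup else m_bg
            tl = window_timeline(m)
            tree_seed = int(rng.integers(0, 2 ** 31))
            from .simulator import drop_mutations, simulate_genealogy
            tree = simulate_genealogy(tl, n_K, n_W, tree_seed)
            hap = drop_mutations(tree, win_cfg.theta, cfg.window, rng)
            loci.append(hap)
            meta.append((scaf, w * cfg.window))

    # assemble the variant table
    n_dip = (n_K + n_W) // 2
    dpops = loci[0].diploid_pops()
    counts = {"K": 0, "W": 0}
    sample_ids = []
    for p in dpops:
        counts[p] += 1
        sample_ids.append(f"{p}{counts[p]:02d}")
    scafs, pos, blocks = [], [], []
    for hap, (scaf, offset) in zip(loci, meta):
        G = hap.dosages()
        if cfg.missingness > 0:
            mask = rng.random(G.shape) < cfg.missingness
            G = np.where(mask, -1, G).astype(np.int8)
        blocks.append(G)
        scafs.extend([scaf] * hap.n_sites)
        pos.extend((hap.positions + offset).tolist())
    table = VariantTable(
        sample_ids=sample_ids, pops=dpops,
        scaffolds=np.array(scafs, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        genotypes=np.hstack(blocks).astype(np.int8),
        ref=np.array(["A"] * len(pos), dtype=object),
        alt=np.array(["T"] * len(pos), dtype=object),
        scaffold_lengths=dict(cfg.scaffolds))

    # gene models: tiled genes with three CDS exons
    gff = ["##gff-version 3"]
    genes = []
    gene_scaffold = {}
    for scaf, length in cfg.scaffolds.items():
        for i, start in enumerate(range(0, length - cfg.gene_spacing,
                                        cfg.gene_spacing)):
            gid = f"gene_{scaf.split('_')[1]}_{i:03d}"
            genes.append(gid)
            gene_scaffold[gid] = scaf
            for s, e in cfg.gene_cds:
                gff.append(f"{scaf}\tdivergesim\tCDS\t{start + s + 1}\t"
                           f"{start + e}\t.\t+\t0\tID=cds_{gid};Parent={gid}")

    island_genes = []
    for gid in genes:
        scaf = gene_scaffold[gid]
        start = int(gid.split("_")[-1]) * cfg.gene_spacing
        for iscaf, s, e in cfg.islands:
            if scaf == iscaf and start + cfg.gene_cds[0][0] < e \
                    and start + cfg.gene_cds[-1][1] > s:
                island_genes.append(gid)
                break

    # scaffold map
    smap_lines = []
    for i, scaf in enumerate(cfg.scaffolds):
        if scaf == "scaffold_Z":
            smap_lines.append(f"{scaf}\tchrZ\tZ\t{i}")
        elif scaf == "scaffold_un":
            continue  # deliberately absent from the map
        else:
            smap_lines.append(f"{scaf}\tchr{i + 1}\tautosome\t{i}")

    # GO annotations
    go_rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                          spawn_key=(2,)))
    annotated = [g for g in genes
                 if go_rng.random() > cfg.unannotated_fraction]
    go_lines = []
    p0 = cfg.category_size / max(len(genes), 1)
    odds1 = cfg.planted_odds_ratio * p0 / (1 - p0)
    p1 = odds1 / (1 + odds1)
    cats = [(f"GO:{1000 + i:07d}", "biological_process")
            for i in range(cfg.n_bp_categories)]
    cats += [(f"GO:{2000 + i:07d}", "cellular_component")
             for i in range(cfg.n_cc_categories)]
    cats.append((cfg.planted_category, "biological_process"))
    for cat, domain in cats:
        for g in annotated:
            prob = p0
            if cat == cfg.planted_category and g in island_genes:
                prob = p1
            if go_rng.random() < prob:
                go_lines.append(f"{g}\t{cat}\t{domain}")
    for i in range(cfg.n_small_categories):
        cat = f"GO:{3000 + i:07d}"
        for g in go_rng.choice(annotated, size=10, replace=False):
            go_lines.append(f"{g}\t{cat}\tbiological_process")

    coverage = {s: 0.95 for s in cfg.scaffolds}
    def _yaml_safe(obj):
        if isinstance(obj, tuple):
            return [_yaml_safe(v) for v in obj]
        if isinstance(obj, dict):
            return {k: _yaml_safe(v) for k, v in obj.items()}
        return obj

    ledger = TruthLedger(
        kind="toy_genome", seed=seed,
        config={**_yaml_safe(dataclasses.asdict(cfg)),
                "n_K": n_K, "n_W": n_W, "ne": ne,
                "m_background": m_bg, "m_island": m_isl},
        islands=[list(i) for i in cfg.islands],
        enriched_category=cfg.planted_category,
        island_genes=island_genes)
    genome = ToyGenome(table=table, gff_lines=gff,
                       scaffold_map_lines=smap_lines, go_lines=go_lines,
                       coverage=coverage, ledger=ledger)
    if out_dir is not None:
        genome.write(out_dir)
    return genome
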