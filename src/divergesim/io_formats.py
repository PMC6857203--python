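"""File formats and run configuration.

Coordinate convention: VCF and GFF3 are 1-based inclusive on disk; every
in-memory structure in this package is 0-based half-open.  The conversion
happens here and only here.

Formats handled:

* VCF 4.x genotypes (read via cyvcf2; written as plain text) -- only
  biallelic SNPs are retained, multi-allelic records and indels dropped;
  half-called genotypes are treated as missing;
* GFF3 CDS features (gffutils) merged into per-gene coding intervals;
* TSV sidecar tables: population map (``sample<TAB>pop``), scaffold map
  (``scaffold<TAB>chrom<TAB>class<TAB>index``) and gene-to-GO annotations
  (``gene<TAB>go_id<TAB>domain``);
* YAML run configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .simulator import LocusConfig, PriorSet, default_priors

POP_LABELS = ("K", "W")
CHROM_CLASSES = ("autosome", "Z", "W", "unassigned")


# ---------------------------------------------------------------------------
# variant table

@dataclass
class VariantTable:
    """Biallelic SNP genotypes for all samples of both populations.

    ``genotypes`` is samples x sites allele dosage in {0, 1, 2} with -1 for
    missing; ``pos`` is 0-based; sites are ordered by (scaffold, position)
    with strictly increasing positions within a scaffold.
    """

    sample_ids: list
    pops: np.ndarray
    scaffolds: np.ndarray
    pos: np.ndarray
    genotypes: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    scaffold_lengths: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.genotypes.shape != (len(self.sample_ids), len(self.pos)):
            raise ValueError("genotype matrix shape mismatch")
        if len(self.pops) != len(self.sample_ids):
            raise ValueError("every sample needs a population label")
        for scaf in np.unique(self.scaffolds):
            p = self.pos[self.scaffolds == scaf]
            if len(p) > 1 and not np.all(np.diff(p) > 0):
                raise ValueError(
                    f"positions not strictly increasing on {scaf}")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def positions_1based(self) -> np.ndarray:
        return self.pos + 1

    def take_sites(self, index: np.ndarray) -> "VariantTable":
        return VariantTable(self.sample_ids, self.pops,
                            self.scaffolds[index], self.pos[index],
                            self.genotypes[:, index], self.ref[index],
                            self.alt[index], self.scaffold_lengths)

    def scaffold_sites(self, scaffold: str) -> np.ndarray:
        return np.flatnonzero(self.scaffolds == scaffold)

    def missing_fraction(self) -> np.ndarray:
        """Per-site fraction of missing genotypes."""
        return (self.genotypes < 0).mean(axis=0)


def read_popmap(path) -> dict:
    """Read a sample<TAB>population table; labels must be K or W."""
    out = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{ln}: expected 'sample<TAB>pop'")
        sample, pop = parts
        if pop not in POP_LABELS:
            raise ValueError(f"{path}:{ln}: unknown population {pop!r} "
                             f"(expected one of {POP_LABELS})")
        out[sample] = pop
    return out


def read_variant_table(path, pop_map) -> VariantTable:
    """Read a VCF into a VariantTable, keeping only biallelic SNPs.

    ``pop_map`` maps sample id to population label (or is a path to a
    popmap TSV).  Every VCF sample must appear in the map.  Missing and
    half-called genotypes become dosage -1.
    """
    from cyvcf2 import VCF

    if not isinstance(pop_map, dict):
        pop_map = read_popmap(pop_map)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in pop_map]
    if unknown:
        raise ValueError(f"samples missing from population map: {unknown}")
    pops = np.array([pop_map[s] for s in samples])
    lengths = dict(zip(vcf.seqnames, vcf.seqlens)) if vcf.seqlens else {}

    scafs, pos, ref, alt, dosages = [], [], [], [], []
    nucleotides = {"A", "C", "G", "T"}
    for i, v in enumerate(vcf):
        try:
            if len(v.ALT) != 1:
                continue
            if v.REF not in nucleotides or v.ALT[0] not in nucleotides:
                continue
            g = np.asarray(v.genotype.array())[:, :2]
            d = g.sum(axis=1).astype(np.int8)
            d[(g < 0).any(axis=1)] = -1
            scafs.append(v.CHROM)
            pos.append(v.POS - 1)  # VCF is 1-based
            ref.append(v.REF)
            alt.append(v.ALT[0])
            dosages.append(d)
        except Exception as exc:  # pragma: no cover - defensive
            raise ValueError(f"malformed VCF record at index {i} "
                             f"({v.CHROM}:{v.POS}): {exc}") from exc
    G = np.array(dosages, dtype=np.int8).T if dosages \
        else np.empty((len(samples), 0), dtype=np.int8)
    return VariantTable(sample_ids=samples, pops=pops,
                        scaffolds=np.array(scafs, dtype=object),
                        pos=np.array(pos, dtype=np.int64),
                        genotypes=G, ref=np.array(ref, dtype=object),
                        alt=np.array(alt, dtype=object),
                        scaffold_lengths=lengths)


def write_vcf(table: VariantTable, path) -> None:
    """Write a VariantTable as an uncompressed VCF 4.2 text file."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=divergesim\n")
        for scaf, length in table.scaffold_lengths.items():
            fh.write(f"##contig=<ID={scaf},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.sample_ids) + "\n")
        for j in range(table.n_sites):
            gts = "\t".join(gt_map[int(g)] for g in table.genotypes[:, j])
            fh.write(f"{table.scaffolds[j]}\t{table.pos[j] + 1}\t.\t"
                     f"{table.ref[j]}\t{table.alt[j]}\t.\tPASS\t.\tGT\t{gts}\n")


def write_popmap(table: VariantTable, path) -> None:
    with open(path, "w") as fh:
        for s, p in zip(table.sample_ids, table.pops):
            fh.write(f"{s}\t{p}\n")


# ---------------------------------------------------------------------------
# annotations

@dataclass
class GeneAnnotation:
    """Merged coding intervals per gene (0-based half-open internally)."""

    genes: dict  # gene_id -> dict(scaffold=str, strand=str, cds=[(s, e)])

    def __len__(self) -> int:
        return len(self.genes)

    def cds_length(self, gene_id: str) -> int:
        return sum(e - s for s, e in self.genes[gene_id]["cds"])

    def gene_ids(self) -> list:
        return list(self.genes)


def merge_intervals(intervals) -> list:
    """Union of half-open intervals."""
    merged = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def read_gff3(path) -> GeneAnnotation:
    """Read CDS features from a GFF3 file and merge per gene.

    The owning gene is taken from the ``Parent`` (falling back to ``ID`` or
    ``gene_id``) attribute.  A gene whose CDS spans two scaffolds is dropped
    with a warning.
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            merge_strategy="create_unique",
                            keep_order=True)
    raw = {}
    for cds in db.features_of_type("CDS"):
        gene = (cds.attributes.get("Parent")
                or cds.attributes.get("gene_id")
                or cds.attributes.get("ID"))
        if not gene:
            continue
        gene = gene[0]
        rec = raw.setdefault(gene, {"scaffolds": set(), "strand": cds.strand,
                                    "cds": []})
        rec["scaffolds"].add(cds.seqid)
        # GFF3 is 1-based inclusive
        rec["cds"].append((cds.start - 1, cds.end))
    genes = {}
    for gene, rec in raw.items():
        if len(rec["scaffolds"]) > 1:
            warnings.warn(f"gene {gene} has CDS on multiple scaffolds; "
                          "dropped")
            continue
        genes[gene] = {"scaffold": next(iter(rec["scaffolds"])),
                       "strand": rec["strand"],
                       "cds": merge_intervals(rec["cds"])}
    return GeneAnnotation(genes)


@dataclass
class ScaffoldMap:
    """scaffold id -> (chromosome, chromosome class, ordering index)."""

    entries: dict

    def chrom_class(self, scaffold: str) -> str:
        if scaffold not in self.entries:
            return "unassigned"
        return self.entries[scaffold][1]

    def __contains__(self, scaffold: str) -> bool:
        return scaffold in self.entries


def read_scaffold_map(path) -> ScaffoldMap:
    entries = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ValueError(f"{path}:{ln}: expected 4 tab-separated fields")
        scaf, chrom, cls, idx = parts
        if cls not in CHROM_CLASSES:
            raise ValueError(f"{path}:{ln}: unknown chromosome class {cls!r}")
        if scaf in entries:
            raise ValueError(f"{path}:{ln}: scaffold {scaf} listed twice")
        entries[scaf] = (chrom, cls, int(idx))
    return ScaffoldMap(entries)


@dataclass
class GOAnnotation:
    """Per-domain gene-category memberships with small-category merging.

    Categories with fewer than ``min_genes`` members (within the annotation
    universe) are merged into one ``small`` category per domain; genes
    without any annotation in a domain belong to that domain's
    ``uncharacterized`` category.
    """

    domains: dict        # domain -> {category -> set(gene_id)}
    category_names: dict
    min_genes: int = 50

    @classmethod
    def build(cls, gene_to_cats: dict, cat_domain: dict, universe,
              min_genes: int = 50, cat_names: dict | None = None
              ) -> "GOAnnotation":
        universe = list(universe)
        domains = {}
        for cat, dom in cat_domain.items():
            members = {g for g in universe if cat in gene_to_cats.get(g, ())}
            bucket = domains.setdefault(dom, {})
            if len(members) < min_genes:
                bucket.setdefault("small", set()).update(members)
            else:
                bucket[cat] = members
        for dom, bucket in domains.items():
            annotated = set().union(*bucket.values()) if bucket else set()
            uncharacterized = set(universe) - annotated
            if uncharacterized:
                bucket["uncharacterized"] = uncharacterized
        names = dict(cat_names or {})
        names.setdefault("small", "small categories (< min_genes members)")
        names.setdefault("uncharacterized", "no annotation")
        return cls(domains=domains, category_names=names, min_genes=min_genes)

    def domain_names(self) -> list:
        return list(self.domains)


def read_go_table(path, universe=None, min_genes: int = 50) -> GOAnnotation:
    """Read a gene<TAB>go_id<TAB>domain table.

    ``universe`` defaults to the genes present in the table; pass the full
    gene list so unannotated genes land in ``uncharacterized``.
    """
    gene_to_cats = {}
    cat_domain = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}:{ln}: expected 3 tab-separated fields")
        gene, cat, dom = parts
        gene_to_cats.setdefault(gene, set()).add(cat)
        if cat_domain.setdefault(cat, dom) != dom:
            raise ValueError(f"{path}:{ln}: category {cat} in two domains")
    if universe is None:
        universe = sorted(gene_to_cats)
    return GOAnnotation.build(gene_to_cats, cat_domain, universe,
                              min_genes=min_genes)


def read_annotations(gff_path, map_path, go_path, universe=None,
                     min_genes: int = 50):
    """Read gene models, scaffold map and GO annotations together."""
    genes = read_gff3(gff_path)
    smap = read_scaffold_map(map_path)
    go = read_go_table(go_path,
                       universe=universe or genes.gene_ids(),
                       min_genes=min_genes)
    return genes, smap, go


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Run-level settings in natural units.

    mu is per site per generation, generation time in years; sample sizes
    are haplotype counts per population; tolerances are acceptance
    fractions in (0, 1].
    """

    mu: float = 0.8e-8
    gen_time: float = 2.5
    n_K: int = 20
    n_W: int = 20
    locus_length: int = 10_000
    n_loci: int = 30
    n_ref: float = 1e6
    window_size: int = 50_000
    min_window_span: int = 25_000
    fst_percentile: float = 95.0
    tolerance_model_choice: float = 0.005
    tolerance_regression: float = 0.002
    n_networks: int = 50
    n_sims_per_model: int = 20_000
    n_sims_best: int = 100_000
    seed: int = 0
    priors: PriorSet = field(default_factory=default_priors)

    def __post_init__(self):
        if min(self.mu, self.gen_time, self.locus_length, self.n_ref) <= 0:
            raise ValueError("rates and sizes must be strictly positive")
        for tol in (self.tolerance_model_choice, self.tolerance_regression):
            if not (0 < tol <= 1):
                raise ValueError("tolerances must lie in (0, 1]")
        if self.n_K < 1 or self.n_W < 1:
            raise ValueError("sample sizes must be positive")

    @property
    def locus_config(self) -> LocusConfig:
        return LocusConfig(length=self.locus_length, mu=self.mu,
                           gen_time=self.gen_time, n_ref=self.n_ref)


def load_config(path) -> RunConfig:
    """Load a RunConfig from YAML; prior entries override the defaults."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    priors = default_priors()
    for name, spec in (data.pop("priors", None) or {}).items():
        priors.specs[name] = (spec[0], float(spec[1]), float(spec[2]))
    return RunConfig(priors=priors, **data)
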