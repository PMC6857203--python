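import numpy as np
import pytest

from divergesim.io_formats import ScaffoldMap, read_annotations, read_variant_table
from divergesim.simulator import LocusConfig, ParameterSet
from divergesim.synthetic_data import make_toy_genome

#: published posterior medians of the study system, used as simulation truth
STUDY_MEDIANS = dict(T=0.863e6, Ne_K=3.581e6, Ne_W=0.649e6, Ne_A=0.752e6,
                      M_WtoK=236.503, M_KtoW=51.476, T1=0.059e6,
                      N0_K=0.086e6, N0_W=0.082e6)


@pytest.fixture(scope="session")
def median_params():
    return ParameterSet(**STUDY_MEDIANS)


@pytest.fixture(scope="session")
def locus_config():
    return LocusConfig()


@pytest.fixture(scope="session")
def panmictic_timeline(locus_config):
    """Single constant-size population of relative size 1."""
    from divergesim.simulator import build_timeline
    params = ParameterSet(T=1e12, Ne_K=1e6, Ne_W=1e6, Ne_A=1e6)
    return build_timeline(params, "ISO-A", locus_config)


@pytest.fixture(scope="session")
def toy_genome(tmp_path_factory):
    out = tmp_path_factory.mktemp("toy_genome")
    genome = make_toy_genome(seed=3, out_dir=out)
    return genome, out


@pytest.fixture(scope="session")
def toy_genome_inputs(toy_genome):
    genome, out = toy_genome
    table = read_variant_table(out / "genome.vcf", out / "popmap.tsv")
    genes, smap, go = read_annotations(out / "genes.gff3",
                                       out / "scaffold_map.tsv",
                                       out / "go.tsv")
    return dict(genome=genome, out=out, table=table, genes=genes,
                smap=smap, go=go)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def scan_result(toy_genome, tmp_path_factory):
    """Full divergence-scan pipeline on the toy genome (run once)."""
    import warnings
    from divergesim.io_formats import RunConfig
    from divergesim.pipeline_cli import run_divergence_scan
    genome, out = toy_genome
    outdir = tmp_path_factory.mktemp("scan_out")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = run_divergence_scan(
            RunConfig(seed=1), vcf=out / "genome.vcf",
            popmap=out / "popmap.tsv", gff=out / "genes.gff3",
            scaffold_map=out / "scaffold_map.tsv", go_table=out / "go.tsv",
            out_dir=outdir)
    return genome, res, outdir
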