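import pytest

from gbmkit import methylome
from gbmkit.io_formats import CpGRecord
from gbmkit.synthetic_data import (
    generate_genome,
    simulate_methylome,
    simulate_truth,
)


@pytest.fixture(scope="session")
def genome():
    """Small deterministic synthetic genome: annotation + CpG sites."""
    return generate_genome(40, seed=7)


@pytest.fixture(scope="session")
def truth(genome):
    ann, sites = genome
    return simulate_truth(ann, sites, seed=8)


@pytest.fixture(scope="session")
def exact_methylome(genome, truth):
    """Noise-free per-sample records (coverage 100, deterministic counts)."""
    ann, sites = genome
    return simulate_methylome(ann, sites, truth, n_replicates=3, seed=9, exact=True)


@pytest.fixture(scope="session")
def noisy_methylome(genome, truth):
    ann, sites = genome
    return simulate_methylome(
        ann, sites, truth, n_replicates=3, mean_coverage=30.0, seed=10
    )


@pytest.fixture(scope="session")
def demo_dir(tmp_path_factory):
    """A complete simulated dataset + analysis run, shared across tests."""
    from gbmkit.pipeline import run_demo

    outdir = tmp_path_factory.mktemp("demo")
    result = run_demo(outdir, seed=3, n_genes=80)
    result["outdir"] = outdir
    return result


def records_from_levels(positions, levels, coverage=20, chrom="chr1"):
    """Helper: integer-count CpG records realizing given percent levels."""
    out = []
    for pos, level in zip(positions, levels):
        meth = int(round(level / 100.0 * coverage))
        out.append(CpGRecord(chrom, int(pos), "+", meth, coverage - meth))
    return out
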