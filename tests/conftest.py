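import numpy as np
import pytest

from srnakit.io_formats import GeneFeature, GenomeAnnotation, StrandCoverage
from srnakit.synthetic import SimulationConfig, simulate_all


@pytest.fixture
def toy_annotation() -> GenomeAnnotation:
    """Two replicons, genes on both strands, with intergenic room."""
    genes = [
        GeneFeature("SPO0001", "chr", 100, 700, "+", "ABC transporter"),
        GeneFeature("SPO0002", "chr", 1000, 1600, "-", "hypothetical protein"),
        GeneFeature("SPO0003", "chr", 2500, 3400, "+", "acetate kinase"),
        GeneFeature("SPOA0001", "plasmid", 200, 900, "-", "sulfatase"),
    ]
    return GenomeAnnotation(replicons={"chr": 5000, "plasmid": 2000}, genes=genes)


@pytest.fixture
def empty_coverage(toy_annotation) -> StrandCoverage:
    return StrandCoverage(replicon_lengths=dict(toy_annotation.replicons))


def block_coverage(annotation, blocks) -> StrandCoverage:
    """Coverage with rectangular depth blocks: (replicon, strand, start, end, depth)."""
    cov = StrandCoverage(replicon_lengths=dict(annotation.replicons))
    for rep, strand, start, end, depth in blocks:
        cov.get(rep, strand)[start:end] += depth
    return cov


@pytest.fixture(scope="session")
def default_dataset():
    """One default-config simulated dataset shared by read-only tests."""
    return simulate_all(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
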