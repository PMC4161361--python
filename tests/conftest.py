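import numpy as np
import pytest

from glmqtl import crosssim, genmap


@pytest.fixture(scope="session")
def bench_map():
    """The benchmark genome: 6 chromosomes x 100 cM, 11 evenly spaced markers."""
    return crosssim.standard_map()


@pytest.fixture(scope="session")
def bench_grid(bench_map):
    return genmap.build_locus_grid(bench_map, 1.0)


@pytest.fixture(scope="session")
def two_marker_map():
    """A minimal one-chromosome map with markers at 0 and 10 cM."""
    chrom = genmap.Chromosome("chr1", ("m1", "m2"), np.array([0.0, 10.0]))
    return genmap.GeneticMap((chrom,))


@pytest.fixture(scope="session")
def binary_dataset():
    """One replicate of the 10-QTL binary backcross benchmark at n = 200."""
    spec = crosssim.ten_qtl_scenario("binary", 200, seed=42)
    return crosssim.simulate_dataset(spec), spec
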