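import numpy as np
import pytest

from seriesbin import features, synthetic_community as sc


@pytest.fixture(scope="session")
def small_community():
    """A small but fully-featured synthetic community shared across tests.

    6 genomes (incl. archaea), 10 samples, short genomes so the whole bundle
    generates in ~1 s.
    """
    design = sc.design_community(
        6, 10, seed=42, overrides={"genome_length": 120_000}
    )
    genomes = sc.generate_genome_sequences(design)
    scaffolds, coverage, truth, rps3 = sc.fragment_and_cover(
        design, genomes, scaffold_len_median=9000
    )
    return {
        "design": design,
        "genomes": genomes,
        "scaffolds": scaffolds,
        "coverage": coverage,
        "truth": truth,
        "rps3": rps3,
    }


@pytest.fixture(scope="session")
def normalized_coverage(small_community):
    return features.normalize_coverage(small_community["coverage"])


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
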