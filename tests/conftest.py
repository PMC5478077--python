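import warnings

import numpy as np
import pytest

from mitochron.seq_io import Feature, GenomeRecord
from mitochron.synthetic_data import SimulationConfig, simulate_dataset

warnings.filterwarnings("ignore", message="zero-length sister lineages")


@pytest.fixture(scope="session")
def sim_default():
    """One full-size simulated dataset under the study-like defaults."""
    return simulate_dataset(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def sim_small():
    """A fast 6-taxon dataset for likelihood-heavy tests."""
    return simulate_dataset(SimulationConfig(seed=4, n_taxa=6, n_outgroups=2))


@pytest.fixture()
def toy_genome():
    """A 60 bp genome with one CDS, one tRNA and a control region."""
    #           CR(0..12)     CDS ND1 (12..33, 7 codons)   tRNA (33..45)
    seq = ("ACGTACGTACGT" + "ATGAAACCCGGGTTTACATGA" + "ACGTACGTACGT"
           + "GGGCCCTTTAAACCC")
    features = [
        Feature(name="CR", ftype="control_region", start=0, end=12),
        Feature(name="ND1", ftype="CDS", start=12, end=33),
        Feature(name="trnF", ftype="tRNA", start=33, end=45),
    ]
    return GenomeRecord(id="toy", sequence=seq, circular=True,
                        features=features)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
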