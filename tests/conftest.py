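import numpy as np
import pytest

from hnnaffinity import SyntheticSpec, generate
from hnnaffinity.dataset_io import ComplexRecord
from hnnaffinity.featurize import AffinityLabel


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_records():
    """Three hand-built complexes with width-4 descriptors."""
    return [
        ComplexRecord(id="c1", smiles="CCO", pocket_seq="ARV",
                      descriptors=[1.0, 0.0, 2.0, 0.5],
                      label=AffinityLabel.from_pk("Kd", 6.0)),
        ComplexRecord(id="c2", smiles="c1ccccc1", pocket_seq="GHWML",
                      descriptors=[0.0, 1.0, 0.0, 1.5],
                      label=AffinityLabel.from_pk("Ki", 4.2)),
        ComplexRecord(id="c3", smiles="N=C", pocket_seq="VVV",
                      descriptors=[2.0, 2.0, 2.0, 2.0],
                      label=AffinityLabel.from_pk("Kd", 8.8)),
    ]


@pytest.fixture(scope="session")
def tiny_synth():
    """A small synthetic dataset shared across tests (n=120, D=12)."""
    spec = SyntheticSpec(
        n=120, seed=7, descriptor_width=12, n_active_descriptors=3,
        beta=(0.8, -0.6, 0.5), smiles_len_range=(10, 40),
        seq_len_range=(10, 30), noise_sd=0.1,
    )
    records, truth = generate(spec)
    return spec, records, truth
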