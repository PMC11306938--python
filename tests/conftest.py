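import numpy as np
import pytest

from transfacpred.seqio import NATURAL_AA, SequenceRecord, stratified_split
from transfacpred.simulate import GeneratorConfig, generate_dataset


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(NATURAL_AA))[rng.integers(0, 20, length)])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_dataset():
    """120-sequence biased dataset with homolog families of 3."""
    return generate_dataset(
        GeneratorConfig(n_pos=60, n_neg=60, len_range=(60, 120), family_size=3,
                        mutation_rate=0.1, seed=7)
    )


@pytest.fixture(scope="session")
def small_split(small_dataset):
    return stratified_split(small_dataset, 0.8, seed=7)


@pytest.fixture(scope="session")
def blast_db(small_split, tmp_path_factory):
    """Labelled BLAST reference database built from the small training split."""
    from transfacpred.similarity import build_reference_db

    train, _ = small_split
    return build_reference_db(train, tmp_path_factory.mktemp("db") / "refdb", engine="blast")


@pytest.fixture()
def toy_records():
    return [
        SequenceRecord("P1", "ACDEFGHIKLMNPQRSTVWY"),
        SequenceRecord("P2", "AAAA"),
        SequenceRecord("P3", "ACAC"),
    ]
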