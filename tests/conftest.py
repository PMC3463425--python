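import pytest

from crebox import build_pfm, build_weight_matrix, datasets
from crebox.synthetic_data import calibrated_cutoff, default_matrices


@pytest.fixture(scope="session")
def ref_table():
    return datasets.load_reference_table()


@pytest.fixture(scope="session")
def strong_seqs(ref_table):
    return ref_table[ref_table["group"] == "high"]["cre_sequence"].tolist()


@pytest.fixture(scope="session")
def weak_seqs(ref_table):
    return ref_table[ref_table["group"] == "low"]["cre_sequence"].tolist()


@pytest.fixture(scope="session")
def ref_records():
    return datasets.reference_expression_records()


@pytest.fixture(scope="session")
def operon_map():
    return datasets.reference_operon_map()


@pytest.fixture(scope="session")
def matrices():
    return default_matrices()


@pytest.fixture(scope="session")
def scan_cutoff(matrices):
    return calibrated_cutoff(matrices["combined"], [matrices["strong"], matrices["weak"]])


@pytest.fixture
def toy_matrix():
    """Width-2 matrix from {"AC","AC"}, pseudocount 0, uniform background."""
    from crebox import MotifAlignment

    pfm = build_pfm(MotifAlignment(["AC", "AC"]), pseudocount=0.0)
    return build_weight_matrix(pfm)
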