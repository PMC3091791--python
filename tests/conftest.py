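import pytest

from ntacet.io import ProteinRecord, load_table1_fixture


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture()
def glc7():
    # Annotated N-terminal region of the Glc7 phosphatase (NatB consensus MD).
    return ProteinRecord(
        accession="YER133W",
        gene_name="GLC7",
        sequence="MDSQPVDVDNIIDRLLEVRGSKPGQQVDLEENEIR",
    )
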