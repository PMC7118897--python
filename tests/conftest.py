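import pytest

from cancersig.fixtures import make_reference


@pytest.fixture(scope="session")
def reference():
    return make_reference(seed=11, contigs=("chr1", "chr2"), length=30000)


@pytest.fixture(scope="session")
def reference_fasta(reference, tmp_path_factory):
    path = tmp_path_factory.mktemp("ref") / "reference.fa"
    reference.write(path)
    return path
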