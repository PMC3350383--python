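import pytest

from splicetree import load_resources, reference_tree


@pytest.fixture(scope="session")
def bundle():
    return load_resources()


@pytest.fixture(scope="session")
def ref_tree(bundle):
    return reference_tree(bundle)


@pytest.fixture()
def toy_genome(tmp_path):
    """A 400-nt single-contig FASTA plus a BED with three labeled exons."""
    import numpy as np

    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=400))
    fasta = tmp_path / "toy.fa"
    fasta.write_text(">chrT\n" + "\n".join(
        seq[i:i + 60] for i in range(0, 400, 60)) + "\n")
    bed = tmp_path / "toy.bed"
    bed.write_text(
        "chrT\t100\t140\texA\t0\t+\tauthentic\n"
        "chrT\t200\t236\texB\t0\t+\tcryptic\n"
        "chrT\t300\t340\texC\t0\t-\tunknown\n"
    )
    return seq, fasta, bed
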