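import pytest

from kataclust import simulate_dataset, write_reference, write_sample_vcfs, write_truth


@pytest.fixture(scope="session")
def dataset():
    """Default-scale synthetic dataset shared by read-only tests."""
    return simulate_dataset(seed=11)


@pytest.fixture(scope="session")
def dataset_files(dataset, tmp_path_factory):
    """The same dataset written out to FASTA/GFF3/BED/VCF/TSV files."""
    out = tmp_path_factory.mktemp("sim")
    paths = write_reference(dataset.reference, out)
    paths["vcfs"] = write_sample_vcfs(dataset.samples, dataset.reference, out)
    truth_path = out / "truth.tsv"
    write_truth(dataset.truth, truth_path)
    paths["truth"] = truth_path
    return paths
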