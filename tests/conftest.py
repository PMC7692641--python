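"""Shared fixtures: the packaged mitochondria-targeting ACP FASTA and a
small synthetic data set / model reused across tests (session-scoped so the
forest is trained once)."""

import importlib.resources

import pytest

from acpstack import ModelConfig, SyntheticConfig, read_fasta, train
from acpstack.synthetic import generate_peptides


@pytest.fixture(scope="session")
def mito_fasta_path(tmp_path_factory):
    ref = importlib.resources.files("acpstack") / "data" / "mito_acps.fasta"
    with importlib.resources.as_file(ref) as path:
        yield path


@pytest.fixture(scope="session")
def mito_peptides(mito_fasta_path):
    return read_fasta(mito_fasta_path)


@pytest.fixture(scope="session")
def tiny_dataset():
    peptides, provenance = generate_peptides(
        SyntheticConfig(n_per_class=30, length_range=(5, 20), seed=3)
    )
    return peptides


@pytest.fixture(scope="session")
def tiny_config():
    return ModelConfig(trees_layer1=50, trees_layer2=30, seed=5)


@pytest.fixture(scope="session")
def tiny_model(tiny_dataset, tiny_config):
    return train(tiny_dataset, tiny_config)
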