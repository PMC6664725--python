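import numpy as np
import pytest

from twincnn.gdsc_io import (build_interaction_table, load_cell_lines,
                             load_drug_list)
from twincnn.model import BranchConfig, HeadConfig, TrainConfig, prepare_tensors
from twincnn.synthetic_data import SyntheticConfig, generate


@pytest.fixture(scope="session")
def tiny_config():
    """Miniature corpus for plumbing tests (seconds, not minutes)."""
    return SyntheticConfig(n_drugs=12, n_cells=16, n_features=20,
                           smiles_len_range=(8, 16), known_density=0.9,
                           tissues=("lung", "blood"), seed=7)


@pytest.fixture(scope="session")
def tiny_corpus(tiny_config, tmp_path_factory):
    return generate(tiny_config, tmp_path_factory.mktemp("tiny_corpus"))


@pytest.fixture(scope="session")
def tiny_table(tiny_corpus):
    drugs = load_drug_list(tiny_corpus.drug_list_path,
                           tiny_corpus.smiles_map_path)
    cells = load_cell_lines(tiny_corpus.cell_features_path)
    return build_interaction_table(drugs, cells, tiny_corpus.ic50_path)


@pytest.fixture(scope="session")
def tiny_tensors(tiny_table):
    return prepare_tensors(tiny_table)


@pytest.fixture(scope="session")
def small_model_kwargs():
    """Down-sized architecture for tests that only exercise plumbing."""
    branch = BranchConfig(conv_widths=(5,), conv_strides=(1,), channels=(6,),
                          pool_widths=(3,), pool_strides=(3,))
    return {"drug_cfg": branch, "cell_cfg": branch,
            "head_cfg": HeadConfig(hidden_sizes=(24,), dropout=0.25)}


@pytest.fixture(scope="session")
def fast_train_cfg():
    return TrainConfig(patience_epochs=3, max_epochs=3, batch_size=64,
                       learning_rate=3e-3, seed=0)


@pytest.fixture(scope="session")
def study_table(tmp_path_factory):
    """The standard desk-scale corpus (60 drugs x 120 cells, planted signal)."""
    corpus = generate(SyntheticConfig(seed=0),
                      tmp_path_factory.mktemp("study_corpus"))
    drugs = load_drug_list(corpus.drug_list_path, corpus.smiles_map_path)
    cells = load_cell_lines(corpus.cell_features_path)
    return build_interaction_table(drugs, cells, corpus.ic50_path)


@pytest.fixture(scope="session")
def study_tensors(study_table):
    return prepare_tensors(study_table)
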