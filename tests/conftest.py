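import numpy as np
import pytest

from fuzzyhep import normalize as nm
from fuzzyhep import pkn
from fuzzyhep import synthetic_data as sd
from fuzzyhep import train


@pytest.fixture(scope="session")
def toy_net():
    return sd.make_benchmark_pkn("toy")


@pytest.fixture(scope="session")
def toy_compressed(toy_net):
    net, _ = pkn.compress(toy_net)
    return net


@pytest.fixture(scope="session")
def toy_benchmark(toy_compressed):
    """Noisy toy benchmark: truth, data, normalized tables, gate space."""
    truth = sd.sample_truth(toy_compressed, seed=11)
    tables = sd.emit_dataset(truth, n_donors=5)
    scheme = nm.assign_midpoints(tables, "IL6")
    norm = nm.normalize_tables(tables, scheme)
    space = pkn.expand_and_gates(toy_compressed, 2)
    return truth, tables, norm, space


@pytest.fixture(scope="session")
def paper_compressed():
    net, _ = pkn.compress(sd.make_benchmark_pkn("paper"))
    return net


@pytest.fixture(scope="session")
def paper_benchmark(paper_compressed):
    """The paper-scale noisy benchmark at its default study conditions."""
    truth = sd.sample_truth(paper_compressed, seed=7)
    tables = sd.emit_dataset(truth, n_donors=5)
    scheme = nm.assign_midpoints(tables, "IL6")
    norm = nm.normalize_tables(tables, scheme)
    space = pkn.expand_and_gates(paper_compressed, 2)
    return truth, tables, norm, space


@pytest.fixture(scope="session")
def quick_hp():
    """GA settings for small test problems (full defaults are slower)."""
    return train.GAHyperparams(seed=1, population_size=40, stall_generations=40)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
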