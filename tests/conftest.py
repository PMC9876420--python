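import numpy as np
import pytest

from dtifusion import SyntheticSpec, build_graph, gen_dataset


@pytest.fixture
def toy_records():
    """2 drugs, 2 targets, 2 diseases; 3 DTI + 2 DDI(1 dup) + 2 DDA records."""
    return [
        ("dr:a", "t:x", "DTI"),
        ("dr:a", "t:y", "DTI"),
        ("dr:b", "t:y", "DTI"),
        ("dr:a", "dr:b", "DDI"),
        ("dr:b", "dr:a", "DDI"),  # duplicate of the previous edge (undirected)
        ("dr:a", "di:p", "DDA"),
        ("dr:b", "di:q", "DDA"),
    ]


@pytest.fixture
def toy_graph(toy_records):
    return build_graph(toy_records)


@pytest.fixture
def star_graph():
    """One drug connected to 4 targets and 3 diseases; 2 extra drugs."""
    records = [("dr:hub", f"t:{i}", "DTI") for i in range(4)]
    records += [("dr:hub", f"di:{i}", "DDA") for i in range(3)]
    records += [("dr:hub", "dr:left", "DDI"), ("dr:hub", "dr:right", "DDI")]
    return build_graph(records)


@pytest.fixture(scope="session")
def small_dataset():
    """Small planted-block dataset reused by pipeline-level tests."""
    spec = SyntheticSpec(
        n_drugs=20, n_targets=15, n_diseases=10, n_blocks=3,
        p_in=0.4, p_out=0.02, seed=7,
    )
    dataset, blocks = gen_dataset(spec)
    return dataset, blocks


@pytest.fixture
def rng():
    return np.random.default_rng(0)
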