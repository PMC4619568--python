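import pytest

from panrep import (generate_pre_library, load_reference, load_scheme,
                    load_templates, simulate_selection)
from panrep.synthetic_repertoire import SyntheticConfig


@pytest.fixture(scope="session")
def templates():
    return load_templates()


@pytest.fixture(scope="session")
def scheme():
    return load_scheme()


@pytest.fixture(scope="session")
def heavy_ref():
    return load_reference("heavy")


@pytest.fixture(scope="session")
def lambda_ref():
    return load_reference("lambda")


@pytest.fixture(scope="session")
def small_cfg():
    """A small but fully featured library + panning configuration."""
    return SyntheticConfig(
        seed=11, n_pre_heavy=40, n_pre_lambda=30,
        n_post_clones=4, post_copies=3, post_target="SQA",
        planted_conserved={"heavy": ["66", "67", "70", "71"],
                           "lambda": ["57", "58", "61"]},
        planted_mode="identical")


@pytest.fixture(scope="session")
def small_library(small_cfg):
    return generate_pre_library(small_cfg)


@pytest.fixture(scope="session")
def pre_small(small_library):
    return small_library[0]


@pytest.fixture(scope="session")
def small_panel(pre_small, small_cfg):
    return simulate_selection(pre_small, small_cfg)


@pytest.fixture(scope="session")
def post_small(small_panel):
    return small_panel[0]
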