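import numpy as np
import pytest

from coosig.datatypes import ExpressionMatrix
from coosig.simulate import (
    CellLineSimConfig,
    CohortSimConfig,
    default_signature,
    simulate_paired_cell_lines,
    simulate_tumor_cohort,
)


@pytest.fixture(scope="session")
def cell_line_sim():
    """A mid-size paired simulation shared across read-only tests."""
    config = CellLineSimConfig(n_probesets=1000, n_de_per_direction=25, seed=11)
    return simulate_paired_cell_lines(config)


@pytest.fixture(scope="session")
def signature10():
    return default_signature()


@pytest.fixture(scope="session")
def tumor_cohort(signature10):
    config = CohortSimConfig(n_tumors=250, class_mean_shift=1.2, seed=21)
    return simulate_tumor_cohort(config, signature10)


@pytest.fixture()
def small_matrix():
    rng = np.random.default_rng(0)
    return ExpressionMatrix(
        probeset_ids=[f"p{i}" for i in range(20)],
        sample_ids=[f"s{j}" for j in range(6)],
        values=rng.normal(7, 1, size=(20, 6)),
        scale="normalized",
        annotation={f"p{i}": f"g{i}" for i in range(20)},
    )
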