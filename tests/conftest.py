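import numpy as np
import pytest

from softinverse.bayesopt import Dimension
from softinverse.cases import CaseDefinition, get_case


def make_tiny_beam(name, unknowns, truth_model="neo_hookean"):
    """Very coarse beam case for fast pipeline tests (not a benchmark preset)."""
    base = get_case("beam_case4")
    return CaseDefinition(
        name=name,
        body="beam",
        description="tiny test beam",
        truth=dict(base.truth),
        unknowns=list(unknowns),
        bounds=dict(base.bounds),
        presets={
            "desk": {
                "divisions": (5, 1, 1),
                "n_steps": 3,
                "total_time": 60.0,
                "substeps": 5,
            }
        },
        truth_model=truth_model,
    )


@pytest.fixture(scope="session")
def tiny_beam_case():
    return make_tiny_beam("tiny_beam", ["E_b", "E_a", "C", "W"])


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
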