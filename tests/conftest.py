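import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")

from foramsig.seqio import OtuRecord, SampleMeta
from foramsig.simulate import (
    CONSERVED_UPSTREAM,
    CONSERVED_DOWNSTREAM,
    TERMINAL,
    SimulationParams,
    simulate_dataset,
)


def make_amplicon(span: str, upstream: str = CONSERVED_UPSTREAM,
                  terminal: str = TERMINAL) -> str:
    """Assemble a structurally valid 37F amplicon around a given span."""
    return upstream + "GACAG" + span + terminal + CONSERVED_DOWNSTREAM


@pytest.fixture
def two_area_meta():
    return [
        SampleMeta("s1", "OMS", "CCFZ"),
        SampleMeta("s2", "Svalbard", "shallow"),
    ]


@pytest.fixture
def small_dataset(two_area_meta):
    """Two valid amplicons with simple counts."""
    records = [
        OtuRecord("otu1", make_amplicon("G" + "ATC" * 30), {"s1": 120, "s2": 30}),
        OtuRecord("otu2", make_amplicon("G" + "CGA" * 30), {"s1": 0, "s2": 400}),
    ]
    return records, two_area_meta


@pytest.fixture(scope="session")
def decoy_simulation():
    """One representative simulated community with all three decoy kinds."""
    params = SimulationParams(
        seed=11,
        decoy_categories=("described_clade", "ENFOR", "monothalamids_X"),
    )
    return params, simulate_dataset(params)


def random_acgt(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
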