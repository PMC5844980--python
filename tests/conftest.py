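import numpy as np
import pandas as pd
import pytest

import ampliem as am


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down study: 20 reference OTUs, 3+3+3 subjects, shallow
    libraries — enough structure for every pipeline stage."""
    return am.SimulationConfig(
        seed=3,
        n_otus=20,
        group_sizes={"O": 3, "V": 3, "VG": 3},
        library_mean=400,
        library_range=(100, 800),
        richness_mean={"O": 12, "V": 16, "VG": 14},
        richness_sd=2,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return am.simulate_study(small_config)


@pytest.fixture(scope="session")
def small_reads(small_config, small_study):
    return am.simulate_reads(small_study.references, small_study.truth, small_config)


def make_derep(spec):
    """Build DereplicatedSequence stubs from {id: (sequence, abundance)}."""
    return [
        am.DereplicatedSequence(
            sequence=seq,
            abundance=ab,
            per_sample_counts={"s": ab},
            id=name,
        )
        for name, (seq, ab) in spec.items()
    ]


@pytest.fixture
def star_tree():
    return am.read_tree("(A:1,B:1,C:1);")
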