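import numpy as np
import pytest
from hypothesis import settings

from ploidyflow import PopulationSpec, SampleSpec
from ploidyflow.synthetic import internal_standard

settings.register_profile(
    "deterministic", deadline=None, derandomize=True, max_examples=50
)
settings.load_profile("deterministic")


@pytest.fixture
def standard_only_spec():
    """A sample with only the internal standard (2.00 pg, AT 64.50%)."""
    return SampleSpec(
        sample_id="std_only",
        populations=(internal_standard(event_fraction=1.0, cv_true=2.0),),
        n_events=10_000,
        seed=11,
    )


@pytest.fixture
def diploid_spec():
    """Internal standard + a diploid guava-like access (0.96 pg, GC ~38%)."""
    return SampleSpec(
        sample_id="gua_01",
        populations=(
            internal_standard(event_fraction=0.5, cv_true=2.0),
            PopulationSpec("gua", c2_true=0.96, at_true=62.0, cv_true=2.0,
                           event_fraction=0.5),
        ),
        n_events=10_000,
        seed=23,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
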