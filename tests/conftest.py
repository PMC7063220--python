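import numpy as np
import pytest

from netpharm import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_universe():
    """A modest universe with one planted hub and one planted pathway."""
    spec = synthetic.UniverseSpec(
        n_herbs=6,
        n_compounds=80,
        n_targets=40,
        n_pathways=15,
        planted_hub_compounds=(3,),
        planted_enriched_pathways=((5, 12.0),),
        seed=7,
    )
    return synthetic.generate_universe(spec)


@pytest.fixture(scope="session")
def control_model_cohort():
    return synthetic.reference_cohort(("control", "model"), seed=42)
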