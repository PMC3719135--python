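import numpy as np
import pytest
from hypothesis import settings

from grseval import InteractionTerm, LiabilityModelSpec, LocusSpec

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_liability_spec(mafs, betas, beta34=0.0, **kw):
    """Four-locus liability model with loci 3 and 4 declared the interacting pair."""
    return LiabilityModelSpec(
        loci=tuple(LocusSpec(f"SNP{i + 1}", m) for i, m in enumerate(mafs)),
        main_effects=tuple(betas),
        interactions=(InteractionTerm(loci=(2, 3), coefficient=beta34),),
        **kw,
    )


@pytest.fixture
def common_equal_spec():
    """All-common equal-effects, no interaction: the lowest rung of the ladder."""
    return make_liability_spec((0.4,) * 4, (0.2,) * 4)


@pytest.fixture
def null_spec():
    return make_liability_spec((0.4,) * 4, (0.0,) * 4)
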