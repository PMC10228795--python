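import numpy as np
import pytest

from woundfield.model import DimensionlessParameters, ModelConfiguration


@pytest.fixture
def default_cfg():
    return ModelConfiguration()


@pytest.fixture
def default_q():
    return DimensionlessParameters()


@pytest.fixture
def zero_activation_q():
    """All activations off: the fixed point is closed-form."""
    return DimensionlessParameters(
        k_act_EIG=0.0, k_act_JNK=0.0, k_act_JAK=0.0, k_act_UPD=0.0,
        k_deg_JNK=2.0, k_deg_JAK=0.5, k_deg_UPD=4.0,
    )


@pytest.fixture
def uniform_wound_cfg():
    """Wound indicator covering the whole domain: spatially uniform forcing."""
    return ModelConfiguration(n_compartments=4, wound=(0.0, 1.0))


def random_parameters(rng: np.random.Generator) -> DimensionlessParameters:
    """One draw from the tabulated ranges (test helper, not the sampler)."""
    from woundfield.explore import DEFAULT_RANGES
    from woundfield.model import HILL_NAMES, PARAM_NAMES

    vals = {}
    for name in PARAM_NAMES:
        lo, hi = DEFAULT_RANGES[name]
        if name in HILL_NAMES:
            vals[name] = float(rng.uniform(lo, hi))
        else:
            vals[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return DimensionlessParameters(**vals)
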