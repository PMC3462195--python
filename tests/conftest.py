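import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from secprod.synthetic_data import EffectConfig, generate_proteins


@pytest.fixture(scope="session")
def small_dataset():
    """30+30 labeled synthetic proteins with annotations and ORFs."""
    return generate_proteins(30, 30, EffectConfig(), seed=7)


@pytest.fixture(scope="session")
def medium_dataset():
    """200+200 proteins at the default planted effect sizes."""
    return generate_proteins(200, 200, EffectConfig(), seed=11)
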