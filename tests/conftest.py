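import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """A mid-size synthetic cohort under the frozen default conditions."""
    from ihiscale.simulate import GeneratorConfig, generate_assessments

    return generate_assessments(GeneratorConfig(n_subjects=2000), seed=11)
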