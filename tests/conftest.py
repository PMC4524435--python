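import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def published_genome():
    from limptools import published_genome

    return published_genome()


@pytest.fixture(scope="session")
def published_limps(published_genome):
    from limptools import detect_limps, extend_palindrome

    genome, _ = published_genome
    return [extend_palindrome(genome, r) for r in detect_limps(genome)]
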