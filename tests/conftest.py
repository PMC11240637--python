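import pytest

from crhaplo import HaplotypeSurvey, build_fixture


@pytest.fixture(scope="session")
def regional_bundle():
    return build_fixture("regional", seed=11)


@pytest.fixture(scope="session")
def global_bundle():
    return build_fixture("global_192", seed=11)


@pytest.fixture(scope="session")
def regional_results():
    """Fitted six-region survey on the regional fixture (no permutations)."""
    return HaplotypeSurvey.from_fixture("regional", seed=11).fit()


@pytest.fixture(scope="session")
def global_results():
    """Fitted pooled-inventory survey on the 192-sample global fixture."""
    return HaplotypeSurvey.from_fixture("global_192", seed=11).fit()
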