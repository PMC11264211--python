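import pytest

import sitewater as sw


@pytest.fixture(scope="session")
def site() -> sw.SiteSpec:
    return sw.synthetic_sitespec()


@pytest.fixture(scope="session")
def convention(site) -> sw.FaceConvention:
    return sw.FaceConvention.from_site(site)


@pytest.fixture(scope="session")
def small_config() -> sw.SyntheticConfig:
    return sw.SyntheticConfig(n_frames=200, n_replicas=2, seed=123)
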