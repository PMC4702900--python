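import pytest

from lncseeker.fixtures import FixtureSpec, generate_fixture


@pytest.fixture(scope="session")
def bundle():
    """One shared synthetic bundle for read-only tests."""
    return generate_fixture(FixtureSpec(seed=3))


@pytest.fixture(scope="session")
def fixture_dir(bundle, tmp_path_factory):
    """The shared bundle written to disk in its standard formats."""
    from lncseeker.fixtures import write_fixture

    out = tmp_path_factory.mktemp("bundle")
    write_fixture(bundle, out)
    return out
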