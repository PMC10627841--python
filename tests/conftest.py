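import pytest

from ampstd.simdata import make_demo_bundle


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """One shared demo bundle (seed 42) for end-to-end style tests."""
    out = tmp_path_factory.mktemp("bundle")
    return make_demo_bundle(out, seed=42)
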