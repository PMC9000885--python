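import pytest

from flavotier.synthetic import build_quasi_library


@pytest.fixture(scope="session")
def fixture_library():
    """The 39 (quasi) reference compounds, built once per session."""
    return build_quasi_library()
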