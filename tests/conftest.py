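import pytest

from psmcea.config import default_config


@pytest.fixture(scope="session")
def cfg():
    """The bundled default model configuration (session-wide, read-only)."""
    return default_config()


@pytest.fixture()
def cfg_copy(cfg):
    import copy

    return copy.deepcopy(cfg)
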