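import pytest

import clintypes as ct


@pytest.fixture(scope="session")
def registry():
    """The shipped 100-type registry (session-scoped, read-only)."""
    return ct.default_registry()


@pytest.fixture()
def worked(registry):
    """A fresh copy of the packaged worked-example store."""
    return ct.worked_example_store(registry)


@pytest.fixture()
def resolved(registry):
    """The worked example after mention-to-element resolution."""
    return ct.resolve_document(ct.worked_example_store(registry))
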