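import pytest

from ampdiv.demo import demo_panel


@pytest.fixture(scope="session")
def panel():
    """The deterministic 13-amplicon demonstration panel."""
    return demo_panel()


@pytest.fixture(scope="session")
def mytb(panel):
    """A single-amplicon AMP with flanks hosting both primers."""
    return panel.amplicons["MytB"]


@pytest.fixture(scope="session")
def mytm(panel):
    """The longest amplicon (440 bp, partial cds coverage)."""
    return panel.amplicons["MytM"]
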