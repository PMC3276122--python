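import pytest

from qtnmap import datasets


@pytest.fixture
def panel():
    """Bundled 10-sire panel at the NGS-58779 marker."""
    return datasets.sire_panel()


@pytest.fixture
def phases():
    return datasets.phase_assignments()


@pytest.fixture
def window():
    """Bundled 20-SNP phased window of the 10 sires."""
    return datasets.phased_window()


@pytest.fixture
def profiles():
    return datasets.amplicon_profiles()
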