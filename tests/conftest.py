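import pytest

from finemav.variant_table_io import PopulationPanel


@pytest.fixture
def panel3() -> PopulationPanel:
    return PopulationPanel(("HAN", "IND", "MAL"))


@pytest.fixture
def panel2() -> PopulationPanel:
    return PopulationPanel(("EAS", "EUR"))
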