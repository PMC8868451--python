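import pytest

from meatid.panel import generate_panel, insilico_pcr, meat_panel


@pytest.fixture(scope="session")
def meat9():
    """The 9-species study panel at a reduced genome length for speed."""
    panel = meat_panel(seed=101, genome_length=800)
    return panel, insilico_pcr(panel)


@pytest.fixture(scope="session")
def meat9_full():
    """The 9-species study panel at the default 2,000-bp genome length."""
    panel = meat_panel(seed=101)
    return panel, insilico_pcr(panel)


@pytest.fixture(scope="session")
def tiny_panel():
    """Three single-species genera with short (250 bp) references, small
    enough for exhaustive dynamic-programming oracles."""
    panel = generate_panel(
        n_genera=3, species_per_genus=1, between_genus_divergence=0.15,
        within_genus_divergence=0.01, seed=5, genome_length=250,
    )
    return panel, insilico_pcr(panel)
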