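import pytest

from xrecomb.genodata import Marker, MarkerPanel
from xrecomb.simulate import SimConfig, simulate_dataset


def make_panel(n: int, **kwargs) -> MarkerPanel:
    return MarkerPanel([Marker(f"M{i+1}", i + 1, **kwargs) for i in range(n)])


@pytest.fixture(scope="session")
def small_panel() -> MarkerPanel:
    return make_panel(6)


@pytest.fixture(scope="session")
def clean_sim(small_panel):
    """A clean (no missingness, no miscalls) simulated intercross in which
    full-sisters can inherit either grand-maternal haplotype."""
    cfg = SimConfig(
        panel=small_panel, seed=7,
        n_crosses=3, f1_females_per_cross=2, offspring_per_female=40,
        theta=0.1, founder_model="two_sow_haplotypes")
    return cfg, simulate_dataset(cfg)
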