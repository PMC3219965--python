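import numpy as np
import pytest

from helixchrom import PolymerModel, SimulationDesign, simulate_contact_profile

# Global best-fit statistical helix of the reference analysis
# (D = 292.03 nm, P = 162.13 nm, S = 2.709 kb, L = 9.6 nm/kb).
GENE_RICH_HELIX = PolymerModel(
    family="helix", S=2.709, D=292.03, P=162.13, L=9.6, k=1.0
)

SILENT_HELIX = PolymerModel(family="helix", S=2.709, D=278.83, P=149.20, L=9.6, k=1.0)
EXPRESSED_HELIX = PolymerModel(family="helix", S=2.709, D=303.92, P=177.38, L=9.6, k=1.0)


@pytest.fixture(scope="session")
def fig_helix():
    return GENE_RICH_HELIX


@pytest.fixture(scope="session")
def noiseless_profile():
    """Dense noise-free profile generated from the reference helix."""
    design = SimulationDesign(
        model=GENE_RICH_HELIX,
        anchors=1,
        sites_per_anchor=200,
        s_range=(5.0, 340.0),
        noise_cv=0.0,
        n_assays=1,
        seed=11,
    )
    return simulate_contact_profile(design)


@pytest.fixture(scope="session")
def noisy_profile():
    """Realistic profile: 5 anchors x 50 sites, 20% lognormal noise."""
    design = SimulationDesign(
        model=GENE_RICH_HELIX,
        anchors=5,
        sites_per_anchor=50,
        s_range=(5.0, 340.0),
        noise_cv=0.2,
        n_assays=3,
        seed=7,
    )
    return simulate_contact_profile(design)


@pytest.fixture
def rng():
    return np.random.default_rng(20_000)
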