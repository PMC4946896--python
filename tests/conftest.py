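import numpy as np
import pytest

from cystseq.panel import make_toy_panel
from cystseq.simulate import SimulationConfig

COHORT_GENES = ("TP53", "KRAS", "BRAF", "NRAS", "PIK3CA", "PIK3R1", "PPP2R1A", "PTEN")


@pytest.fixture(scope="session")
def toy_panel():
    """Six-amplicon toy panel over TP53/KRAS/BRAF with literature codon anchors."""
    panel, _, _ = make_toy_panel(6, ("TP53", "KRAS", "BRAF"), seed=7)
    return panel


@pytest.fixture(scope="session")
def cohort_panel():
    """Eight-gene panel covering the cohort simulator's gene sets."""
    panel, _, _ = make_toy_panel(8, COHORT_GENES, seed=11)
    return panel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def noiseless_config(**kw) -> SimulationConfig:
    defaults = dict(
        n_templates_per_amplicon=800, family_size_mean=5.0,
        seq_error_rate=0.0, early_pcr_error_rate=0.0, seed=0,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)
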