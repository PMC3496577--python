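import numpy as np
import pytest

from rhpanel.io import GenotypeMatrix
from rhpanel.simulate import Chromosome, SimConfig, markers_at, simulate_panel


@pytest.fixture
def small_matrix() -> GenotypeMatrix:
    """2 markers x 3 hybrids with one unknown call."""
    return GenotypeMatrix(
        marker_ids=["mA", "mB"],
        hybrid_ids=["H0", "H1", "H2"],
        calls=np.array([[1, 0, -1], [0, 1, 1]], dtype=np.int8),
    )


def micro_panel(seed: int, positions=(1.0, 1.7, 2.4, 3.2, 3.9, 4.7, 5.4),
                **overrides):
    """A 90-hybrid panel on one 7 Mb microchromosome (APL22-like scale)."""
    chrom = Chromosome("c1", 7.0, "micro")
    cfg = SimConfig(
        chromosomes=[chrom],
        seed=seed,
        **overrides,
    )
    markers = markers_at(chrom, list(positions))
    truth, matrix = simulate_panel(cfg, markers)
    return cfg, markers, truth, matrix


@pytest.fixture
def clean_micro_panel():
    """Noiseless seven-marker panel: observed calls equal the hidden truth."""
    return micro_panel(seed=101, fp_rate=0.0, fn_rate=0.0, unknown_rate=0.0)
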