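import numpy as np
import pytest

from dnacyclize import MoleculeSpec


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def baseline_spec():
    """Reference molecule: planar 90-degree bend over 63 bp, 147 bp total."""
    return MoleculeSpec.single_bend(90.0, 147)


def random_chart_helix(rng, ell=3.4):
    """Random helix parameters inside the Cayley chart (D > 1)."""
    from dnacyclize.geometry import HelixParams

    while True:
        alpha = rng.uniform(-1.0, 1.0)
        psi = rng.uniform(0.005, 1.0)
        beta = rng.uniform(-2.5, 2.5)
        D = (
            1.0
            + np.cos(psi) * np.cos(beta / 2)
            + np.sin(psi) * np.sin(beta / 2) * np.sin(alpha)
        )
        if D - 1.0 > 0.05:
            return HelixParams(alpha, psi, beta, ell)
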