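import numpy as np
import pytest

from psboundary import CellFrame, SynthesisConfig, generate_epithelium


@pytest.fixture
def noise_free_cfg():
    """Perfect lattice: no angular disorder, no dot noise."""
    return SynthesisConfig(sigma0=0.0, sigma1=0.0, vertex_jitter_frac=0.0,
                           dot_jitter=0.0, dot_noise_sd=0.0, p_on=1.0,
                           t_start=-2.0, t_end=2.0, seed=0)


@pytest.fixture
def noise_free_tissue(noise_free_cfg):
    return generate_epithelium(noise_free_cfg)


def quad_row_frame(n_cells: int, index: int = 0, time_min: float = 0.0) -> CellFrame:
    """A single AP row of unit-square cells, cell i spanning x in [i, i+1]."""
    cells = {
        i: np.array([[i, 0.0], [i + 1.0, 0.0], [i + 1.0, 1.0], [i, 1.0]])
        for i in range(n_cells)
    }
    return CellFrame(index=index, time_min=time_min, cells=cells)
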