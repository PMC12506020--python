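import numpy as np
import pytest

from bactorg import cellseg, synthgen


@pytest.fixture(scope="session")
def rod_mask():
    """4 x 1 µm spherocylinder at 60 nm/px, horizontal."""
    return synthgen.make_cell_mask(4.0, 1.0)


@pytest.fixture(scope="session")
def rod_morphology(rod_mask):
    labels = np.zeros_like(rod_mask, dtype=np.int32)
    labels[rod_mask] = 1
    return cellseg.cell_morphology(labels, 60.0)[0]


@pytest.fixture(scope="session")
def big_square_mask():
    """A 110 x 110 all-true mask: >10^4 pixels for sampling-bound tests."""
    return np.ones((110, 110), dtype=bool)
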