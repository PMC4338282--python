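import numpy as np
import pytest

from segcpm import (AdhesionTable, SimConfig, SimState, TissueSpec,
                    build_segmented_tissue)
from segcpm.params import GREEN, RED


@pytest.fixture
def two_cell_state() -> SimState:
    """Two 5x5 cells stacked vertically (one red, one green) on a 20x20 field."""
    spec = TissueSpec(n_segments=2, segment_rows=1, segment_cols=1,
                      cell_target_area=25)
    return build_segmented_tissue(spec, field=(20, 20))


@pytest.fixture
def standard_table() -> AdhesionTable:
    """Segment-specific adhesion at the strongest published tension pair:
    gamma_rg = 10, gamma_cm = 6 (J_cm = 10, J_rg = 18, J_rr = 8)."""
    return AdhesionTable.segmented(J_cm=10, J_rr=8, J_rg=18)


def random_state(rng: np.random.Generator, size: int = 12, n_cells: int = 4,
                 target_area: int = 20) -> SimState:
    """A random small lattice: n_cells identities sprinkled over the field
    (possibly fragmented — the model allows it), medium elsewhere."""
    state = SimState(size, size, n_cells)
    interior = state.sites[1:-1, 1:-1]
    labels = rng.integers(0, n_cells + 1, size=interior.shape)
    interior[...] = labels
    state.resync()
    state.target_area[1:] = target_area
    for sigma in range(1, n_cells + 1):
        state.ctype[sigma] = RED if sigma % 2 else GREEN
        state.segment[sigma] = sigma % 2
    return state
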