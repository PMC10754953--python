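"""Shared fixtures: phantoms are expensive, so they are session-scoped."""

import numpy as np
import pytest

from vemseg.phantom import PhantomConfig, generate_phantom_stack
from vemseg.stack_io import equalize_stack


@pytest.fixture(scope="session")
def phantom_small():
    """Compact phantom for unit tests: 3 cells, 2 protrusions each."""
    cfg = PhantomConfig(shape=(64, 128, 128), n_cells=3, n_protrusions_per_cell=2,
                        organelle_counts={"nucleolus": (1, 3), "mitochondrion": 3,
                                          "endosome": 1, "lysosome": 1},
                        seed=7)
    stack, truth = generate_phantom_stack(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def phantom_std():
    """Full-size phantom shared by the separation/tracking/learning suites."""
    cfg = PhantomConfig(seed=11)
    stack, truth = generate_phantom_stack(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def phantom_std_equalized(phantom_std):
    _, stack, _ = phantom_std
    return equalize_stack(stack)


def truth_main_and_islands(truth):
    """Emulate ideal per-slice separation output from phantom truth.

    Main-cell labels keep 2D components connected to a cell body; detached
    protrusion cross-sections become unlabeled islands, exactly what the
    separation stage hands to the tracker.
    """
    from scipy import ndimage as ndi

    cells = truth.cell_labels
    tubes = truth.protrusion_labels
    body = np.where(tubes == 0, cells, 0)
    Z = cells.shape[0]
    mains = np.zeros_like(cells)
    islands = np.zeros_like(cells)
    s8 = np.ones((3, 3))
    for z in range(Z):
        isl_id = 0
        for cid in np.unique(cells[z]):
            if cid == 0:
                continue
            comp, n = ndi.label(cells[z] == cid, structure=s8)
            for ci in range(1, n + 1):
                m = comp == ci
                if ((body[z] > 0) & m).any():
                    mains[z][m] = cid
                else:
                    isl_id += 1
                    islands[z][m] = isl_id
    return mains, islands
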