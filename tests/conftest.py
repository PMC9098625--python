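import numpy as np
import pytest

from metafoci.foci_io import BrainGrid, Experiment, Focus


@pytest.fixture(scope="session")
def small_grid() -> BrainGrid:
    """12^3 grid at 4 mm with the default ellipsoid mask."""
    return BrainGrid.create((12, 12, 12), 4.0)


@pytest.fixture(scope="session")
def test_grid() -> BrainGrid:
    """The default 40x48x40 grid at 4 mm."""
    return BrainGrid.create((40, 48, 40), 4.0)


def make_experiment(
    grid: BrainGrid,
    rng: np.random.Generator,
    n_foci: int = 5,
    n_subjects: int = 15,
    study: str | None = None,
) -> Experiment:
    """An experiment with uniform in-brain foci at voxel centres."""
    idx = grid.mask_indices()
    sel = idx[rng.integers(0, len(idx), size=n_foci)]
    mm = np.atleast_2d(grid.voxel_to_mm(sel.astype(float)))
    return Experiment(
        study=study or f"study-{rng.integers(1 << 30)}",
        contrast="c",
        n_subjects=n_subjects,
        foci=[Focus(*row) for row in mm],
    )
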