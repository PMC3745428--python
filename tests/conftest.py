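import numpy as np
import pytest
from hypothesis import settings

from raydock import (
    build_grid,
    classify_grid,
    extract_shell_and_forbidden,
    mark_pocket,
)
from raydock.fixtures import FixtureSpec, make_planted_fixture, make_toy_receptor

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def planted():
    """Standard planted fixture: 500 pocket + 50 forbidden rays, D=12 Å, r=2 Å."""
    return make_planted_fixture(FixtureSpec())


@pytest.fixture(scope="session")
def small_planted():
    """Lean planted fixture for oracle loops: 200 pocket + 20 forbidden rays."""
    return make_planted_fixture(FixtureSpec(n_pocket_rays=200, n_forbidden_rays=20, seed=3))


@pytest.fixture(scope="session")
def toy_pit_pipeline():
    """Toy slab receptor with a 6 Å pit, run through the full grid pipeline."""
    prot = make_toy_receptor(pit_radius=6.0)
    grid = build_grid(prot, ("A", 1), spacing=0.5, extent=15.0)
    classify_grid(grid, prot)
    mark_pocket(grid)
    pocket = extract_shell_and_forbidden(grid)
    return prot, grid, pocket
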