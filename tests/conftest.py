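import numpy as np
import pytest

from gimmesub.gimme import run_gimme
from gimmesub.simulate import SimulationDesign, generate_panel


def small_design(seed: int = 1) -> SimulationDesign:
    """Two-subgroup, 24-individual scaled-down version of the default design."""
    return SimulationDesign(
        n_individuals=24,
        n_subgroups=2,
        n_timepoints=150,
        unique_paths=[(5, 0), (6, 1)],
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_run():
    """Panel, ground truth and fitted GIMME maps for the small design."""
    design = small_design()
    panel, truth = generate_panel(design)
    maps = run_gimme(panel)
    return design, panel, truth, maps


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
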