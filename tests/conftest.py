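import numpy as np
import pytest

from dendrodate import RingSeries, SyntheticScenario, generate_boards, study_scenario


@pytest.fixture
def simple_series():
    """A short hand-made series: widths in mm, years 1500-1511."""
    return RingSeries(
        series_id="TST",
        widths=np.array([1.0, 1.1, 1.2, 1.3, 1.4, 1.5, 1.6, 1.7, 1.8, 1.9, 2.0, 2.1]),
        last_ring_year=1511,
    )


@pytest.fixture(scope="session")
def study_boards():
    """Synthetic stand-ins for the three panels (two from one tree)."""
    boards, truth = generate_boards(study_scenario(seed=7))
    return {b.series_id: b for b in boards}, truth


def same_tree_pair(seed: int):
    """Two boards cut from one synthetic tree, plus the scenario truth."""
    scenario = SyntheticScenario(seed=seed, n_trees=1, boards_per_tree=2)
    (a, b), truth = generate_boards(scenario)
    return a, b, truth
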