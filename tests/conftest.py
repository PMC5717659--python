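import warnings

import pytest

from vocalappraisal import preprocessing as pp
from vocalappraisal.bayes import Grid
from vocalappraisal.predictions import DEFAULT_PREDICTIONS
from vocalappraisal.synthetic import StudyDesign, TruthProfile, generate_ratings


@pytest.fixture(scope="session")
def grid():
    return Grid()


@pytest.fixture(scope="session")
def coarse_grid():
    """601-node grid: cheap enough for exhaustive-window oracles."""
    return Grid(step=0.01)


@pytest.fixture(scope="session")
def small_design():
    """Reduced study: 2 emotions cut, fewer listeners, for fast unit tests."""
    return StudyDesign(n_listeners={"australia": 12, "india": 12}, seed=101)


@pytest.fixture(scope="session")
def effect_truth():
    return TruthProfile.from_directions(DEFAULT_PREDICTIONS, effect=0.8)


@pytest.fixture(scope="session")
def effect_ratings(small_design, effect_truth):
    return generate_ratings(small_design, effect_truth)


@pytest.fixture(scope="session")
def effect_cells(effect_ratings):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pp.preprocess(effect_ratings)
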