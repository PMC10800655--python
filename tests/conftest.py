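import numpy as np
import pytest

from emophysio.features import assemble
from emophysio.protocol import build_timeline, analysis_windows
from emophysio.synthetic import EffectModel, Rates, make_fixture_suite

FIXTURE_SEED = 11


@pytest.fixture(scope="session")
def effects():
    return EffectModel()


@pytest.fixture(scope="session")
def fixture_suite():
    """Two-subject cohort at reduced rates with a short pre-phase rest."""
    return make_fixture_suite(2, seed=FIXTURE_SEED, rates=Rates.fast(),
                              rest_pre_phase=20.0)


@pytest.fixture(scope="session")
def feature_table(fixture_suite):
    recs, _ = fixture_suite
    return assemble(recs)


@pytest.fixture(scope="session")
def one_window():
    """A 45 s labeled analysis window (A1 low-valence) with a short rest."""
    tl = build_timeline("S01", FIXTURE_SEED, rest_pre_phase=20.0)
    return analysis_windows(tl)[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(FIXTURE_SEED)
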