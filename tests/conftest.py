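import numpy as np
import pytest

from trainopt import (
    AthleteProfile,
    BanisterParameters,
    TrainingPlan,
    simulated_athlete,
)


@pytest.fixture
def athlete() -> AthleteProfile:
    """The simulated 35-year-old male cyclist (resting 51, FTHR 165, max 189)."""
    return simulated_athlete()


@pytest.fixture
def params() -> BanisterParameters:
    return BanisterParameters()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_plan(rng: np.random.Generator, athlete: AthleteProfile,
                n: int = 56, max_dur: float = 300.0) -> TrainingPlan:
    hrs = rng.uniform(athlete.resting_hr, athlete.max_hr, n)
    durs = rng.uniform(30.0, max_dur, n)
    return TrainingPlan.from_arrays(hrs, durs)


@pytest.fixture
def make_random_plan(rng, athlete):
    return lambda n=56, max_dur=300.0: random_plan(rng, athlete, n, max_dur)
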