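import numpy as np
import pytest

import switchweight as sw


@pytest.fixture
def four_patient_sample() -> sw.SurvivalSample:
    """Control deaths at 1 and 3; experimental death at 2, censored at 4."""
    return sw.SurvivalSample(
        time=np.array([1.0, 3.0, 2.0, 4.0]),
        event=np.array([True, True, True, False]),
        arm=np.array([0, 0, 1, 1]),
    )


@pytest.fixture
def default_medians() -> sw.ClinicalMedians:
    """The reference scenario anchors: medians 10/15 months OS, 2 months PFS."""
    return sw.ClinicalMedians(m0_os=10.0, m1_os=15.0, m0_pfs=2.0, p=1.0)


@pytest.fixture
def small_scenario() -> sw.ScenarioConfig:
    """A fast, down-scaled trial for engine-level tests."""
    return sw.ScenarioConfig(
        medians=sw.ClinicalMedians(10.0, 15.0, 2.0, p=0.5),
        n0=40,
        n1=60,
        accrual_months=6.0,
        target_deaths=70,
        n_sims=1,
        seed=9,
    )


def simulate_one(config: sw.ScenarioConfig, rep: int = 0) -> sw.TrialData:
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(rep,))
    )
    return sw.simulate_trial(config, rng)
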