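import numpy as np
import pytest

import sitseg

#: fixed master seed for the default synthetic cohort used by the
#: end-to-end and OOB acceptance checks
DEFAULT_COHORT_SEED = 1


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def quiet_params():
    """Noise-free, tremor-free generator settings for closed-form checks."""
    return sitseg.SimulationParams(acc_noise_sd_g=0.0, gyr_noise_sd_deg_s=0.0)


@pytest.fixture(scope="session")
def small_cohort():
    """Four subjects, one 3-minute trial each; cheap enough for unit tests."""
    return sitseg.generate_cohort(n_subjects=4, trial_durations=(180.0,),
                                  master_seed=7)


@pytest.fixture(scope="session")
def small_trials(small_cohort):
    return sitseg.featurize_cohort(small_cohort)


@pytest.fixture(scope="session")
def default_cohort_trials():
    """The full default cohort (20 subjects x 3/4/5 min), featurized once."""
    cohort = sitseg.generate_cohort(master_seed=DEFAULT_COHORT_SEED)
    return sitseg.featurize_cohort(cohort)


@pytest.fixture()
def single_trial(quiet_params):
    rng = np.random.default_rng(3)
    script = sitseg.make_script(180.0, quiet_params, rng)
    return sitseg.synthesize(script, quiet_params, rng,
                             subject_id="S01", trial_id="T180s")
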