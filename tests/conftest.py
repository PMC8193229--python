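import numpy as np
import pytest

from dsaflow import phantom


@pytest.fixture(scope="session")
def avm_case():
    """Noise-free AVM phantom: all five temporal features are 1."""
    sched = phantom.build_schedule("AVM", "low", 30, rng_seed=11)
    return phantom.render_case(sched, (96, 96), noise_sd=0.0, rng_seed=11)


@pytest.fixture(scope="session")
def normal_case():
    """Noise-free non-AVM phantom: all five temporal features are 0."""
    sched = phantom.build_schedule("non-AVM", "none", 30, rng_seed=11)
    return phantom.render_case(sched, (96, 96), noise_sd=0.0, rng_seed=11)


@pytest.fixture(scope="session")
def small_cohort_dir(tmp_path_factory):
    """A 12-case noisy phantom cohort on disk (6 AVM / 6 non-AVM)."""
    d = tmp_path_factory.mktemp("cohort")
    phantom.generate_cohort(
        12, avm_fraction=0.5, high_grade_fraction=0.5, rng_seed=5, out_dir=d
    )
    return d


@pytest.fixture(scope="session")
def diagnosis_cohort(tmp_path_factory):
    """120-case noisy phantom cohort, balanced AVM/non-AVM."""
    d = tmp_path_factory.mktemp("diag_cohort")
    phantom.generate_cohort(120, 0.5, 0.5, rng_seed=20, out_dir=d)
    return d


@pytest.fixture(scope="session")
def grading_cohort(tmp_path_factory):
    """100 AVM phantom cases, half high grade."""
    d = tmp_path_factory.mktemp("grade_cohort")
    phantom.generate_cohort(100, 1.0, 0.5, rng_seed=21, out_dir=d)
    return d


@pytest.fixture
def rng():
    return np.random.default_rng(0)
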