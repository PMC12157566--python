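import numpy as np
import pytest

import spineprint as sp


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """8 subjects, 28 regions, strong subject effect: fast and identifiable."""
    spec = sp.CohortSpec(
        n_subjects=8, n_regions=28, n_timepoints=150,
        alpha=0.6, gamma=0.1, noise_sd=0.3, seed=7,
    )
    return sp.generate_cohort(spec)


@pytest.fixture(scope="session")
def small_cohort_vectors(small_cohort):
    """FC vectors (run1, run2) for the small cohort, subjects in order."""

    def vecs(run):
        return np.vstack(
            [sp.vectorize_upper(sp.compute_fc(ts)).values for ts in run]
        )

    return vecs(small_cohort.run_matrix(0)), vecs(small_cohort.run_matrix(1))


@pytest.fixture(scope="session")
def spinal_scheme_3():
    return sp.build_spinal_scheme(["C4", "C5", "C6"])


def fc_vectors(run):
    return np.vstack([sp.vectorize_upper(sp.compute_fc(ts)).values for ts in run])
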