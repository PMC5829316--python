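import pytest

from tibclust.cohort import generate_cohort, study_cohort_spec, well_separated_blobs


@pytest.fixture(scope="session")
def study_cohort():
    """Table-exact synthetic cohort reproducing the study's published panels."""
    return generate_cohort(study_cohort_spec(seed=20260927))


@pytest.fixture(scope="session")
def blobs3():
    """Well-separated 3-cluster fixture with known centers and labels."""
    return well_separated_blobs(
        k=3, n_per_cluster=50, separation=10.0, noise_sd=0.5, p=2, seed=11
    )
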