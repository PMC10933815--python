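import pytest

from rsnamp.decompose import spatial_regress
from rsnamp.netmats import partial_correlation, summary_fc
from rsnamp.pipeline import compute_measures
from rsnamp.synthcohort import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def cohort_default():
    """Cohort at the default study conditions (N=400, K=6, T=490, S=200)."""
    return simulate_cohort(SimConfig(seed=20230101))


@pytest.fixture(scope="session")
def measures_default(cohort_default):
    return compute_measures(cohort_default)


@pytest.fixture(scope="session")
def cohort_small():
    """A lighter cohort for netmat / clustering / FC tests."""
    cfg = SimConfig(
        n_voxels=180,
        n_networks=6,
        n_timepoints=250,
        n_subjects=80,
        between_net_corr=0.3,
        seed=42,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def measures_small(cohort_small):
    return compute_measures(cohort_small)


@pytest.fixture(scope="session")
def summary_fc_small(cohort_small):
    """Per-subject partial-correlation summary FC for the small cohort."""
    out = []
    for run in cohort_small.runs:
        ts = spatial_regress(run, cohort_small.maps)
        out.append(summary_fc(partial_correlation(ts)))
    return out
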