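import numpy as np
import pytest
from hypothesis import settings

from mobilearn import pipeline, synthetic_data

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cluster4_session():
    """One noiseless cluster-4 (arm more increase) session, with the
    generating model trajectory for oracle comparisons."""
    arch = synthetic_data.ArchetypeSpec(
        cluster_id=4,
        omega0_range=(0.3, 0.8),
        noise_sd=0.0,
        baseline_level=None,  # 1:1 model-to-mm mapping
    )
    session, traj, scales = synthetic_data.generate_session(
        arch, "2mo", "right", seed=0, return_model=True
    )
    return session, traj, scales


@pytest.fixture(scope="session")
def tiny_cohort():
    """Eight low-noise sessions, two per archetype (ground truth known)."""
    spec = synthetic_data.CohortSpec(
        n_per_cluster=(2, 2, 2, 2), n_per_age=(4, 4), seed=7
    )
    archetypes = [
        synthetic_data.ArchetypeSpec(
            cluster_id=a.cluster_id,
            omega0_range=a.omega0_range,
            noise_sd=0.05,
            baseline_level=a.baseline_level,
            coupling_gain=a.coupling_gain,
        )
        for a in synthetic_data.default_archetypes()
    ]
    return synthetic_data.generate_cohort(spec, archetypes)


@pytest.fixture(scope="session")
def tiny_cohort_processed(tiny_cohort):
    return [pipeline.process_session(s) for s in tiny_cohort]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
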