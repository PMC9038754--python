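import numpy as np
import pytest

from connpredict.prediction import build_site_clusters, enumerate_folds
from connpredict.synthetic import CohortConfig, generate_cohort

TEST_MEASURES = {"cognition": 3, "personality": 3, "mental_health": 3}


@pytest.fixture(scope="session")
def cohort():
    """Default-scale synthetic cohort (400 participants, 60 regions,
    10 sites), trimmed to 3 measures per domain plus one noise measure."""
    cfg = CohortConfig(
        seed=7, measures_per_domain=dict(TEST_MEASURES), n_noise_measures=1
    )
    connectomes, behavior, meta, truth = generate_cohort(cfg)
    return dict(
        config=cfg, connectomes=connectomes, behavior=behavior, meta=meta, truth=truth
    )


@pytest.fixture(scope="session")
def cv_setup(cohort):
    clusters, site_map = build_site_clusters(
        cohort["meta"]["site"], n_clusters=10, min_size=1
    )
    folds = enumerate_folds(10, 3)
    confounds = cohort["meta"][["mean_fd", "mean_dvars"]].to_numpy()
    return dict(clusters=clusters, site_map=site_map, folds=folds, confounds=confounds)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def small_cohort(seed=0, **overrides):
    """Cheap cohort for oracle-style tests."""
    params = dict(
        n_participants=150,
        n_regions=24,
        n_networks=4,
        n_sites=6,
        measures_per_domain={"cognition": 2, "mental_health": 2},
        seed=seed,
    )
    params.update(overrides)
    return generate_cohort(CohortConfig(**params))
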