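import numpy as np
import pytest
from hypothesis import settings

from rehonorm import synthetic as syn

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


def make_regions(n_per_network=3, networks=("FPCN", "SMN"), slope=0.02):
    """Small hand-built region list for cheap unit tests."""
    specs = []
    rid = 1
    for net in networks:
        for j in range(n_per_network):
            kind = "increasing" if j % 2 == 0 else "decreasing"
            s = slope if kind == "increasing" else -slope
            specs.append(
                syn.RegionSpec(
                    region_id=rid,
                    network=net,
                    trajectory_kind=kind,
                    intercept=1.0 + 0.01 * rid,
                    slope_per_decade=s,
                    curvature=-0.001 * np.sign(s),
                    sex_offset=0.01,
                )
            )
            rid += 1
    return specs


@pytest.fixture(scope="session")
def regions246():
    return syn.generate_region_specs(seed=1)


@pytest.fixture(scope="session")
def mdd_default_deviations(regions246):
    """n=600 MDD deviation maps over 6 sites at the default planted effects."""
    cfg = syn.CohortConfig(n_hc=10, n_mdd=600, n_sites=6, seed=7)
    cohort, z = syn.generate_mdd_deviations(cfg, regions246)
    return cohort, z


@pytest.fixture(scope="session")
def hc_calibration_cv():
    """Held-out HC Z-scores and CV metrics: n=500, 4 regions, 10 folds.

    Site effects are off so the generative model matches the GP's
    assumptions (smooth trajectory + Gaussian noise).
    """
    from rehonorm import normative

    regions = syn.generate_region_specs(seed=4)[:4]
    cfg = syn.CohortConfig(
        n_hc=500,
        n_mdd=0,
        n_sites=1,
        site_location_sd=0.0,
        site_scale_range=(1.0, 1.0),
        seed=21,
    )
    cohort, feat = syn.generate_hc_cohort(cfg, regions)
    metrics, zmap = normative.crossval_metrics(
        feat, cohort[["age", "sex"]], k_folds=10, seed=0, n_restarts=0
    )
    return metrics, zmap
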