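import numpy as np
import pytest

import ordcar as oc
from ordcar.datasets import OrdinalDataset


@pytest.fixture(scope="session")
def small_study():
    """One small synthetic study shared by read-only tests."""
    cfg = oc.study_config(seed=11, n_counties=10, n_facilities=30, n_patients=300)
    dataset, adjacency, truth = oc.simulate_study(cfg)
    return dataset, adjacency, truth


@pytest.fixture(scope="session")
def small_fit(small_study):
    """A short convolution fit on the small study (shared, read-only)."""
    dataset, adjacency, _ = small_study
    model = oc.SpatialOrdinalModel(dataset, adjacency=adjacency, structure="convolution")
    return model.fit(oc.McmcConfig(n_draws=400, burnin=400, seed=7))


def random_dataset(rng, n=20, p=2, n_fac=4, n_cty=3, K=3):
    """Small random dataset for oracle comparisons."""
    X = rng.standard_normal((n, p))
    return OrdinalDataset(
        y=rng.integers(1, K + 1, size=n),
        X=X,
        columns=[f"x{j}" for j in range(p)],
        blocks={f"x{j}": "b" for j in range(p)},
        facility_index=1 + rng.integers(0, n_fac, size=n),
        county_index=1 + rng.integers(0, n_cty, size=n),
        n_categories=K,
        n_facilities=n_fac,
        n_counties=n_cty,
    )


def random_state(rng, p=2, n_fac=4, n_cty=3, K=3):
    kappa = np.sort(rng.normal(0, 1.5, size=K - 1))
    kappa += np.arange(K - 1) * 0.1 + 0.05  # guarantee strict ordering
    return oc.ParameterState(
        beta=rng.standard_normal(p),
        cutpoints=oc.CutpointSet.from_kappa(kappa),
        u=rng.standard_normal(n_cty) * 0.5,
        f=rng.standard_normal(n_fac) * 0.5,
        phi=(lambda v: v - v.mean())(rng.standard_normal(n_cty)),
        tau_h=1.0,
        tau_v=1.0,
        tau_c=1.0,
    )
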