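import numpy as np
import pytest

import nestpool as npl
from nestpool.nested_model import Family, ModelSpec
from nestpool.preprocess import DesignData


@pytest.fixture(scope="session")
def dmap():
    return npl.default_domain_map()


@pytest.fixture(scope="session")
def paper_cohort():
    """One paper_scale synthetic cohort (default sizes) plus its truth."""
    return npl.generate_cohort(npl.get_scenario("paper_scale", seed=11))


@pytest.fixture(scope="session")
def paper_design(paper_cohort, dmap):
    table, _ = paper_cohort
    return npl.orient_and_standardize(table, dmap)


@pytest.fixture(scope="session")
def small_group_fit(paper_design, dmap):
    """A deliberately short group-model fit shared across summary tests."""
    design, _ = paper_design
    spec = npl.build_group_model(design, dmap)
    draws = npl.run_mcmc(spec, n_samples=1200, thin=1, chains=4, seed=7, n_warmup=300)
    return spec, draws


def make_toy_design(y, n_outcomes=1, outcome_of_obs=None):
    """Minimal DesignData: one observation per subject, single wave/group."""
    y = np.asarray(y, dtype=float)
    n = y.size
    k = np.zeros(n, dtype=np.int64) if outcome_of_obs is None else np.asarray(outcome_of_obs)
    outcome_ids = tuple(f"y{i}" for i in range(n_outcomes))
    return DesignData(
        y=y,
        subject_idx=np.arange(n, dtype=np.int64),
        outcome_idx=k,
        domain_idx=np.zeros(n, dtype=np.int64),
        g=np.ones(n),
        t=np.zeros(n),
        subject_ids=np.array([f"s{i}" for i in range(n)]),
        subject_group=np.ones(n, dtype=np.int64),
        age_z=np.zeros(n),
        wtar_z=np.zeros(n),
        sex01=np.zeros(n),
        logloc_z=np.zeros(n),
        ageinj_z=np.zeros(n),
        outcome_ids=outcome_ids,
        domain_ids=("d",),
        domain_of_outcome=np.zeros(n_outcomes, dtype=np.int64),
    )


def make_conjugate_spec(y, prior_sd=100.0, sigma=1.0, nu=1000.0):
    """Single-effect normal-mean toy: y ~ t_nu(beta, sigma), beta ~ N(0, prior_sd^2)."""
    design = make_toy_design(y)
    return ModelSpec(
        variant="toy",
        design=design,
        families=[Family("effect", np.ones(design.n_obs), nested=False, prior_sd=prior_sd)],
        use_u=False,
        use_w=False,
        use_v=False,
        use_z=False,
        fix_sigma=sigma,
        fix_nu=nu,
    )
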