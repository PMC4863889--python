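import numpy as np
import pytest
import scipy.stats as st

import nestpool as npl
from nestpool.battery_schema import Domain, DomainMap
from nestpool.nested_model import (
    AGNOSTIC_PRIOR_SD,
    build_agnostic_model,
    build_exposure_model,
    build_group_model,
    log_posterior,
)

from conftest import make_conjugate_spec


class TestBuilders:
    def test_group_model_parameter_counts(self, paper_design, dmap):
        design, _ = paper_design
        spec = build_group_model(design, dmap)
        assert [f.name for f in spec.families] == [
            "intercept_control",
            "slope_control",
            "intercept_exposed",
            "slope_exposed",
        ]
        # per family: 1 overarching + 7 domain + 22 outcome locations (+2 SDs)
        for fam in spec.families:
            names = [n for n in spec.stored_param_names() if n.startswith(fam.name + "/")]
            assert sum("/mu" in n for n in names) == 1
            assert sum("/domain/" in n for n in names) == 7
            assert sum("/outcome/" in n for n in names) == 22
            assert sum("/tau_" in n for n in names) == 2

    def test_single_wave_design_rejected(self, paper_cohort, dmap):
        table, _ = paper_cohort
        base_only = table[table["wave"] == 0]
        design, _ = npl.orient_and_standardize(base_only, dmap)
        with pytest.raises(ValueError, match="wave"):
            build_group_model(design, dmap)

    def test_single_group_design_rejected(self, paper_cohort, dmap):
        table, _ = paper_cohort
        design, _ = npl.orient_and_standardize(table[table["group"] == "control"], dmap)
        with pytest.raises(ValueError, match="group"):
            build_group_model(design, dmap)

    def test_degenerate_one_domain_one_outcome_map(self):
        dm = DomainMap(domains=(Domain("d1", "solo", ("digit_span_total",)),))
        params = npl.CohortParams(n_exposed=10, n_control=20, seed=1, dmap=dm)
        table, _ = npl.generate_cohort(params)
        design, _ = npl.orient_and_standardize(table, dm)
        spec = build_group_model(design, dm)
        # hierarchy collapses but stays well-defined: beta = mu + two deviations
        p = np.zeros(spec.n_params)
        assert np.isfinite(_lp_interior(spec, p))

    def test_exposure_model_families(self, paper_cohort, dmap):
        table, _ = paper_cohort
        exposed = table[table["group"] == "exposed"]
        design, _ = npl.orient_and_standardize(exposed, dmap)
        spec = build_exposure_model(design, dmap)
        assert [f.name for f in spec.families] == [
            "effect_logloc",
            "effect_age_injury",
            "effect_time",
            "effect_age",
            "effect_wtar",
            "effect_sex",
        ]
        assert all(f.nested for f in spec.families)

    def test_exposure_model_rejects_controls(self, paper_design, dmap):
        design, _ = paper_design
        with pytest.raises(ValueError, match="exposed"):
            build_exposure_model(design, dmap)

    def test_constant_logloc_rejected(self, paper_cohort, dmap):
        table, _ = paper_cohort
        exposed = table[table["group"] == "exposed"].copy()
        exposed["loc_minutes"] = 10.0
        with pytest.raises(ValueError, match="zero variance exposure"):
            npl.orient_and_standardize(exposed, dmap)

    def test_agnostic_variant_structure(self, paper_design, dmap):
        design, _ = paper_design
        spec = build_agnostic_model(design, dmap, base="group")
        names = spec.stored_param_names()
        assert sum("/outcome/" in n for n in names) == 4 * 22
        assert not any("/domain/" in n or "/mu" in n or "/tau_" in n for n in names)
        # person-level random effects survive, person-by-domain ones do not
        assert spec.use_u and spec.use_w and not spec.use_v and not spec.use_z
        assert all(f.prior_sd == AGNOSTIC_PRIOR_SD for f in spec.families)


def _lp_interior(spec, loc_params):
    """Fill the support-constrained tail of the vector with interior values."""
    names = spec.param_names()
    p = np.array(loc_params, dtype=float)
    for i, n in enumerate(names):
        if "tau_" in n or n.startswith("re/") or "/sigma/" in n:
            p[i] = 1.0
        elif "/eta/" in n:
            p[i] = 0.1
    return log_posterior(spec, p)


class TestLogPosterior:
    def test_length_mismatch(self, small_group_fit):
        spec, _ = small_group_fit
        with pytest.raises(ValueError, match="length"):
            log_posterior(spec, np.zeros(3))

    def test_outside_support_is_minus_inf(self):
        rng = np.random.default_rng(0)
        spec = make_conjugate_spec(rng.normal(size=20))
        # free sigma/eta variant of the same toy
        spec.fix_sigma = None
        spec.fix_nu = None
        names = spec.param_names()
        base = np.zeros(len(names))
        base[names.index("resid/sigma/y0")] = 1.0
        base[names.index("resid/eta/y0")] = 0.1
        assert np.isfinite(log_posterior(spec, base))
        bad = base.copy()
        bad[names.index("resid/sigma/y0")] = -0.1
        assert log_posterior(spec, bad) == -np.inf
        bad = base.copy()
        bad[names.index("resid/eta/y0")] = 0.6
        assert log_posterior(spec, bad) == -np.inf

    def test_conjugate_differences_match_closed_form(self):
        rng = np.random.default_rng(1)
        y = rng.normal(0.4, 1.0, 30)
        spec = make_conjugate_spec(y, prior_sd=100.0, sigma=1.0, nu=1000.0)
        for b1, b2 in [(0.0, 0.5), (0.25, 1.0)]:
            got = log_posterior(spec, np.array([b1])) - log_posterior(spec, np.array([b2]))
            want = (
                st.norm.logpdf(b1, 0, 100.0)
                + st.t.logpdf(y - b1, df=1000.0).sum()
                - st.norm.logpdf(b2, 0, 100.0)
                - st.t.logpdf(y - b2, df=1000.0).sum()
            )
            assert got == pytest.approx(want, abs=1e-8)

    def test_missing_cells_never_enter_likelihood(self, dmap):
        table, _ = npl.null_cohort(seed=5)
        table = table.copy()
        full_design, _ = npl.orient_and_standardize(table, dmap)
        # blank one observed cell: the likelihood term count must drop by one
        table.loc[table.index[5], "bnt"] = np.nan
        less_design, _ = npl.orient_and_standardize(table, dmap)
        assert less_design.n_obs == full_design.n_obs - 1

    def test_agnostic_prior_is_diffuse_normal(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=15)
        spec = make_conjugate_spec(y, prior_sd=AGNOSTIC_PRIOR_SD, sigma=1.0, nu=1000.0)
        got = log_posterior(spec, np.array([0.0])) - log_posterior(spec, np.array([2.0]))
        want = (
            st.norm.logpdf(0.0, 0, 1000.0)
            + st.t.logpdf(y, df=1000.0).sum()
            - st.norm.logpdf(2.0, 0, 1000.0)
            - st.t.logpdf(y - 2.0, df=1000.0).sum()
        )
        assert got == pytest.approx(want, abs=1e-8)


def test_eta_prior_implies_nu_range(small_group_fit):
    """Sampled eta respects U(0.001, 0.5) exactly, so nu stays in (2, 1000)."""
    spec, draws = small_group_fit
    nus = np.concatenate([draws.flat(n) for n in draws.select("resid/nu/")])
    assert nus.min() > 2.0
    assert nus.max() < 1000.0
    sigmas = np.concatenate([draws.flat(n) for n in draws.select("resid/sigma/")])
    assert sigmas.min() > 0.0 and sigmas.max() < 10.0
    re_sds = np.concatenate([draws.flat(n) for n in draws.select("re/")])
    assert re_sds.min() > 0.0 and re_sds.max() < 10.0
    taus = np.concatenate(
        [draws.flat(n) for n in draws.names if "tau_" in n]
    )
    assert taus.min() > 0.0
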