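import numpy as np
import pandas as pd
import pytest

import nestpool as npl
from nestpool.synthetic_cohort import CohortParams, generate_cohort, get_scenario, null_cohort


class TestGenerateCohort:
    def test_default_cohort_composition(self, paper_cohort):
        table, _ = paper_cohort
        base = table[table["wave"] == 0]
        assert (base["group"] == "exposed").sum() == 53
        assert (base["group"] == "control").sum() == 104
        assert set(table["wave"]) <= {0, 1, 2}

    def test_same_seed_bit_identical(self):
        t1, tr1 = generate_cohort(CohortParams(seed=42))
        t2, tr2 = generate_cohort(CohortParams(seed=42))
        pd.testing.assert_frame_equal(t1, t2)
        assert np.array_equal(tr1.subject_u, tr2.subject_u)
        t3, _ = generate_cohort(CohortParams(seed=43))
        assert not t1.equals(t3)

    def test_monotone_wave_presence_under_defaults(self, paper_cohort):
        table, _ = paper_cohort
        for _, sub in table.groupby("subject_id"):
            waves = set(sub["wave"])
            assert 0 in waves
            if 2 in waves:
                assert 1 in waves  # nobody skips a middle wave under defaults

    def test_exposure_features_only_for_exposed(self, paper_cohort, dmap):
        table, _ = paper_cohort
        assert table.loc[table["group"] == "control", "loc_minutes"].isna().all()
        exposed = table[table["group"] == "exposed"]
        assert exposed["loc_minutes"].notna().all()
        assert exposed["loc_minutes"].min() >= 0.03
        assert exposed["loc_minutes"].max() <= 30240.0
        assert exposed["age_first_injury"].between(4, 67).all()

    def test_loc_distribution_matches_cohort_shape(self):
        # large-n check of the skewed LOC mixture: median ~10 min
        params = CohortParams(n_exposed=2000, n_control=10, seed=0)
        table, _ = generate_cohort(params)
        loc = table.loc[(table["wave"] == 0) & (table["group"] == "exposed"), "loc_minutes"]
        assert 5.0 < loc.median() < 20.0
        assert loc.max() > 1440.0  # tail reaches beyond a day

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(CohortParams(retention_control=(1.0, 1.2)))
        with pytest.raises(ValueError):
            generate_cohort(CohortParams(sigma_u=-1.0))
        with pytest.raises(ValueError):
            generate_cohort(CohortParams(nu_resid=1.5))
        with pytest.raises(ValueError):
            generate_cohort(CohortParams(contrast_intercept={"not_an_outcome": 0.2}))

    def test_within_domain_correlation_exceeds_between(self, dmap):
        """Person-by-domain effects induce extra correlation inside domains."""
        params = CohortParams(n_exposed=700, n_control=1300, seed=3)
        table, _ = generate_cohort(params)
        design, _ = npl.orient_and_standardize(table, dmap)
        base = table[table["wave"] == 0]
        z = np.column_stack(
            [
                dmap.orientation_of(oid) * base[oid].to_numpy(dtype=float)
                for oid in dmap.outcome_ids
            ]
        )
        corr = np.corrcoef(z, rowvar=False)
        dom = np.array([dmap.domain_index_of_outcome()[o] for o in dmap.outcome_ids])
        same = dom[:, None] == dom[None, :]
        off = ~np.eye(len(dom), dtype=bool)
        within = corr[same & off].mean()
        between = corr[~same].mean()
        assert within > between


class TestNullCohort:
    def test_truth_records_zero_contrasts(self):
        _, truth = null_cohort(seed=1)
        assert all(v == 0.0 for v in truth.contrast_intercept.values())
        assert all(v == 0.0 for v in truth.contrast_slope.values())
        assert all(v == 0.0 for v in truth.loc_effect.values())

    def test_group_means_differ_only_by_noise(self):
        # large-n version: baseline group mean difference within +/-3 SE
        params = CohortParams(n_exposed=1000, n_control=1000, seed=6)
        table, _ = generate_cohort(params)
        base = table[table["wave"] == 0]
        for oid in ("cvlt_recognition", "stroop_words", "bnt"):
            a = base.loc[base["group"] == "exposed", oid].to_numpy(dtype=float)
            b = base.loc[base["group"] == "control", oid].to_numpy(dtype=float)
            se = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
            assert abs(a.mean() - b.mean()) < 3 * se


class TestScenarioLibrary:
    def test_known_presets(self):
        lib = npl.scenario_library()
        assert set(lib) == {"null", "paper_scale", "strong", "heavy_tails", "severity"}

    def test_paper_scale_magnitudes(self):
        p = get_scenario("paper_scale")
        assert p.contrast_intercept["stroop_words"] == pytest.approx(0.24)
        assert p.contrast_intercept["cvlt_recognition"] == pytest.approx(0.21)
        assert p.contrast_slope["category_fluency"] == pytest.approx(0.11)

    def test_severity_magnitudes(self):
        p = get_scenario("severity")
        assert p.loc_effect["logical_memory_1"] == pytest.approx(-0.26)
        assert p.loc_effect["logical_memory_2"] == pytest.approx(-0.29)

    def test_heavy_tails_preset(self):
        p = get_scenario("heavy_tails")
        assert p.nu_resid_overrides["logical_memory_1"] == 3.0

    def test_unknown_preset_rejected(self):
        with pytest.raises(KeyError):
            get_scenario("nonexistent")
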