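import numpy as np
import pandas as pd
import pytest

import nestpool as npl
from nestpool.battery_schema import Domain, DomainMap
from nestpool.preprocess import log_loc, match_controls, orient_and_standardize, stroop_interference


def _mini_table(values, orientation=1, outcome="score"):
    rows = []
    for i, v in enumerate(values):
        rows.append(
            {
                "subject_id": f"s{i}",
                "group": "control",
                "wave": 0,
                "age_baseline": 70 + i,
                "sex": "F" if i % 2 else "M",
                "wtar_iq": 108 + i,
                "education_band": "15+",
                "apoe_e4": 0,
                outcome: v,
            }
        )
    return pd.DataFrame(rows), DomainMap(
        domains=(Domain("d1", "d", (outcome,)),),
        orientation={outcome: orientation} if orientation == -1 else {},
    )


class TestLogLoc:
    def test_median_ten_minutes(self):
        assert log_loc(10.0) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("minutes,expected", [(0.03, -1.5229), (30240.0, 4.4806)])
    def test_range_endpoints(self, minutes, expected):
        assert log_loc(minutes) == pytest.approx(expected, abs=1e-4)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            log_loc(0.0)
        with pytest.raises(ValueError):
            log_loc(-5.0)


class TestOrientAndStandardize:
    def test_simple_column(self):
        table, dm = _mini_table([1.0, 2.0, 3.0])
        design, scaling = orient_and_standardize(table, dm)
        assert np.allclose(np.sort(design.y), [-1.0, 0.0, 1.0])
        mean, sd, orient = scaling.outcomes["score"]
        assert (mean, sd, orient) == (2.0, 1.0, 1)

    def test_inverted_column_flips_order(self):
        # larger raw completion time must map to smaller standardized score
        table, dm = _mini_table([30.0, 20.0, 25.0], orientation=-1)
        design, _ = orient_and_standardize(table, dm)
        y_by_raw = dict(zip(table["score"], design.y))
        assert y_by_raw[30.0] < y_by_raw[20.0]

    def test_constant_column_error_names_outcome(self):
        table, dm = _mini_table([7.0, 7.0, 7.0])
        with pytest.raises(ValueError, match="zero variance.*score"):
            orient_and_standardize(table, dm)

    def test_standardized_outcomes_mean_zero_sd_one(self, paper_design):
        design, _ = paper_design
        for k in range(design.n_outcomes):
            yk = design.y[design.outcome_idx == k]
            assert abs(yk.mean()) < 1e-8
            assert abs(yk.std(ddof=1) - 1.0) < 1e-8

    def test_row_order_invariance(self, dmap):
        table, _ = npl.null_cohort(seed=2)
        shuffled = table.sample(frac=1.0, random_state=3).reset_index(drop=True)
        d1, s1 = orient_and_standardize(table, dmap)
        d2, s2 = orient_and_standardize(shuffled, dmap)
        assert s1.outcomes == s2.outcomes
        order1 = np.lexsort((d1.outcome_idx, d1.t, d1.subject_idx))
        order2 = np.lexsort((d2.outcome_idx, d2.t, d2.subject_idx))
        assert np.allclose(d1.y[order1], d2.y[order2])

    def test_inverse_transform_recovers_raw(self, dmap):
        table, _ = npl.null_cohort(seed=2)
        _, scaling = orient_and_standardize(table, dmap)
        for oid in dmap.outcome_ids:
            raw = table[oid].to_numpy(dtype=float)
            ok = np.isfinite(raw)
            back = scaling.raw_outcome(oid, scaling.standardize_outcome(oid, raw[ok]))
            assert np.allclose(back, raw[ok], rtol=1e-10, atol=1e-10)


class TestCodeDesign:
    def test_group_and_time_codes(self, paper_cohort, dmap):
        table, _ = paper_cohort
        design = npl.code_design(table, dmap)
        # control at baseline -> (0, 0); exposed at 36 months -> (1, 2)
        ctrl0 = (design.g == 0) & (design.t == 0)
        exp2 = (design.g == 1) & (design.t == 2)
        assert ctrl0.any() and exp2.any()
        assert set(np.unique(design.t)) <= {0.0, 1.0, 2.0}
        # g matches subject-level group everywhere
        assert np.array_equal(design.g, design.subject_group[design.subject_idx].astype(float))

    def test_covariates_standardized(self, paper_design):
        design, _ = paper_design
        for arr in (design.age_z, design.wtar_z):
            assert abs(arr.mean()) < 1e-8
            assert abs(arr.std(ddof=1) - 1.0) < 1e-8
        assert set(np.unique(design.sex01)) <= {0.0, 1.0}
        # exposure features standardized within exposed, absent for controls
        exp = design.subject_group == 1
        assert np.all(np.isnan(design.logloc_z[~exp]))
        assert abs(np.nanmean(design.logloc_z[exp])) < 1e-8


class TestMatchControls:
    @staticmethod
    def _subject(sid, group, age, wtar, sex="F", apoe=0, band="13-15"):
        return {
            "subject_id": sid,
            "group": group,
            "wave": 0,
            "age_baseline": age,
            "sex": sex,
            "wtar_iq": wtar,
            "education_band": band,
            "apoe_e4": apoe,
            "score": 1.0,
        }

    def test_nearest_neighbour_choice(self):
        # brute force over the two candidate assignments: age 69 beats age 75
        cases = pd.DataFrame([self._subject("case1", "exposed", 70, 110)])
        pool = pd.DataFrame(
            [
                self._subject("ctl_a", "control", 69, 110),
                self._subject("ctl_b", "control", 75, 110),
            ]
        )
        res = match_controls(pool, cases, ratio=1)
        assert list(res.log["control_id"]) == ["ctl_a"]
        assert not res.warnings

    def test_exact_categorical_keys_required(self):
        cases = pd.DataFrame([self._subject("case1", "exposed", 70, 110, sex="F")])
        pool = pd.DataFrame(
            [
                self._subject("ctl_m", "control", 70, 110, sex="M"),
                self._subject("ctl_f", "control", 80, 90, sex="F"),
            ]
        )
        res = match_controls(pool, cases, ratio=1)
        assert list(res.log["control_id"]) == ["ctl_f"]

    def test_where_possible_branch(self):
        cases = pd.DataFrame([self._subject("case1", "exposed", 70, 110)])
        pool = pd.DataFrame([self._subject("ctl_a", "control", 70, 111)])
        res = match_controls(pool, cases, ratio=2)
        assert len(res.log) == 1
        assert any("only 1 of 2" in w for w in res.warnings)

    def test_empty_eligible_set(self):
        cases = pd.DataFrame([self._subject("case1", "exposed", 70, 110, apoe=2)])
        pool = pd.DataFrame([self._subject("ctl_a", "control", 70, 110, apoe=0)])
        res = match_controls(pool, cases, ratio=2)
        assert len(res.log) == 0
        assert res.warnings

    def test_no_control_reuse_and_disjointness(self):
        table, _ = npl.null_cohort(seed=8)
        cases = table[table["group"] == "exposed"]
        pool = table[table["group"] == "control"]
        res = match_controls(pool, cases, ratio=2)
        assert res.log["control_id"].is_unique
        assert not set(res.log["control_id"]) & set(cases["subject_id"])
        with pytest.raises(ValueError, match="overlap"):
            match_controls(table, cases, ratio=1)


def test_stroop_interference_ratio():
    out = stroop_interference(np.array([30.0, 10.0]), np.array([20.0, 0.0]))
    assert out[0] == pytest.approx(1.5)
    assert np.isnan(out[1])
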