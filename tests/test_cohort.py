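"""Group summaries, Mann-Whitney engine, correlations, clinical table, sweep."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from skelburden.cohort import (
    CohortAnalyzer,
    group_summary,
    mann_whitney_u,
    pearson_r,
    threshold_sweep,
)
from skelburden.datasets import load_reference_cohort
from skelburden.synthetic import PhantomSpec, make_phantom

from oracles import mannwhitney_enumeration


class TestGroupSummary:
    def test_metastatic_group_ages(self):
        ages = load_reference_cohort().query("group == 'M'")["age"]
        s = group_summary(ages)
        assert round(s.mean, 1) == 66.2
        assert round(s.sd, 1) == 8.9  # population sd (divisor n)
        assert (s.min, s.max) == (54.0, 79.0)

    def test_control_group_ages(self):
        ages = load_reference_cohort().query("group == 'N'")["age"]
        assert round(group_summary(ages).mean, 1) == 68.5

    def test_constant_list(self):
        s = group_summary([7.0, 7.0, 7.0])
        assert s == (7.0, 0.0, 7.0, 7.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            group_summary([])


class TestMannWhitney:
    def test_identical_samples_give_p_one(self):
        with pytest.warns(RuntimeWarning, match="identical"):
            _, p = mann_whitney_u([2.0, 2.0], [2.0, 2.0])
        assert p == 1.0

    def test_separated_triples(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)  # 2/20 labelings as extreme

    def test_matches_enumeration_on_random_tie_free_samples(self):
        rng = np.random.default_rng(31)
        for _ in range(25):
            n1, n2 = rng.integers(2, 7, size=2)
            vals = rng.permutation(1000)[: n1 + n2].astype(float)
            a, b = vals[:n1], vals[n1:]
            u, p = mann_whitney_u(a, b)
            u_ref, p_ref = mannwhitney_enumeration(a, b)
            assert u == pytest.approx(u_ref, abs=1e-12)
            assert p == pytest.approx(p_ref, abs=1e-12)

    @given(
        a=st.lists(st.integers(0, 40), min_size=2, max_size=8),
        b=st.lists(st.integers(0, 40), min_size=2, max_size=8),
    )
    def test_symmetry_under_group_swap(self, a, b):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u_ab, p_ab = mann_whitney_u(a, b)
            u_ba, p_ba = mann_whitney_u(b, a)
        assert u_ab + u_ba == pytest.approx(len(a) * len(b))
        assert p_ab == pytest.approx(p_ba, rel=1e-9)

    def test_u_within_bounds(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=6), rng.normal(size=9)
        u, p = mann_whitney_u(a, b)
        assert 0 <= u <= len(a) * len(b)
        assert 0 < p <= 1


class TestPearson:
    def test_perfect_positive_affine(self):
        x = np.arange(5.0)
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.arange(4.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_fixed_table_matches_covariance_formula(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 7.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 9.0])
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = math.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert pearson_r(x, y) == pytest.approx(num / den, rel=1e-12)

    def test_zero_variance_is_undefined(self):
        assert math.isnan(pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))

    @given(
        scale=st.floats(0.1, 10.0), shift=st.floats(-50.0, 50.0)
    )
    def test_invariant_under_positive_affine_maps(self, scale, shift):
        rng = np.random.default_rng(37)
        x, y = rng.normal(size=8), rng.normal(size=8)
        base = pearson_r(x, y)
        assert pearson_r(scale * x + shift, y) == pytest.approx(base, rel=1e-9)


class TestReferenceCohortTable:
    def test_group_sizes(self):
        df = load_reference_cohort()
        assert (df["group"] == "M").sum() == 14
        assert (df["group"] == "N").sum() == 12

    def test_stage_and_psa_extremes(self):
        df = load_reference_cohort()
        assert df.query("group == 'M'")["t3_t4"].sum() == 9
        assert df.query("group == 'M'")["initial_psa"].max() == 968.0
        assert df.query("group == 'N'")["initial_psa"].min() == 0.3

    def test_censored_psa_flagged(self):
        df = load_reference_cohort()
        row = df[df["patient_id"] == "VII"].iloc[0]
        assert row["psa_at_pet_censored"]
        assert row["psa_at_pet"] == 0.05

    def test_missing_initial_psa_is_nan(self):
        df = load_reference_cohort()
        assert df.query("group == 'M'")["initial_psa"].isna().sum() == 2


class TestThresholdSweep:
    def test_plateau_lesion_vanishes_above_its_suv(self):
        # one lesion at SUV ~5: same volume at thresholds 3 and 4, zero at 6 and 10
        spec = PhantomSpec(
            grid_shape=(20, 20, 28), lesion_count=1, seed=41, concordance=1.0,
            lesion_psma_suv_median=5.0, lesion_suv_log_sigma=0.0,
            suv_noise_sd=0.0, lesion_radius_mm=(10.0, 10.0),
        )
        study, _ = make_phantom(spec)
        sweep = threshold_sweep([study], thresholds=(3.0, 4.0, 6.0, 10.0))
        vols = sweep.volumes.iloc[0]
        assert vols[3.0] == vols[4.0] > 0.0
        assert vols[6.0] == vols[10.0] == 0.0

    def test_threshold_above_global_max_gives_zero_and_undefined_r(self, small_phantom):
        study, _ = small_phantom
        sweep = threshold_sweep([study], thresholds=(1000.0,))
        assert (sweep.volumes[1000.0] == 0.0).all()
        assert math.isnan(sweep.pearson_r_m[1000.0])

    def test_volumes_non_increasing(self, default_phantom):
        study, _ = default_phantom
        sweep = threshold_sweep([study], thresholds=(3.0, 4.0, 6.0, 10.0))
        v = sweep.volumes.iloc[0].to_numpy()
        assert (np.diff(v) <= 0).all()

    def test_unsorted_thresholds_rejected(self, small_phantom):
        study, _ = small_phantom
        with pytest.raises(ValueError, match="ascending"):
            threshold_sweep([study], thresholds=(6.0, 3.0))


class TestCohortAnalyzer:
    def _table(self, n_m=6, n_n=5, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n_m + n_n):
            m = i < n_m
            vol = rng.lognormal(4.0, 0.8) if m else 0.0
            rows.append({
                "patient_id": f"p{i}", "group": "M" if m else "N",
                "psa": vol * 1.1 + rng.normal(0, 1) if m else rng.lognormal(1.5, 0.5),
                "volume_ml_PSMA_PET_3": vol,
                "volume_ml_NaF_PET_10": vol * 0.7,
                "volume_ml_Skeleton600": 1300 + rng.normal(0, 100),
                "pct_skeleton_PSMA_PET_3": vol / 90.0,
            })
        return pd.DataFrame(rows)

    def test_fitted_attributes_shapes(self):
        an = CohortAnalyzer().fit(self._table())
        assert set(an.summary_["group"]) == {"M", "N"}
        assert {"metric", "U", "p"} <= set(an.tests_.columns)
        assert (an.tests_["p"] > 0).all() and (an.tests_["p"] <= 1).all()
        assert {"metric", "group", "r", "n"} <= set(an.correlations_.columns)

    def test_single_patient_groups_skip_comparisons(self):
        an = CohortAnalyzer().fit(self._table(n_m=1, n_n=1))
        assert an.tests_.empty
        assert any("skipped" in n for n in an.notices_)

    def test_unknown_group_label_rejected(self):
        t = self._table()
        t.loc[0, "group"] = "X"
        with pytest.raises(ValueError, match="group"):
            CohortAnalyzer().fit(t)

    def test_ratio_of_means_only_for_percentages(self):
        an = CohortAnalyzer().fit(self._table())
        assert set(an.ratio_of_means_.index) == {"pct_skeleton_PSMA_PET_3"}
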