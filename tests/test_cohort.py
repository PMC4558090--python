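"""Group assignment, cohort summaries and nonparametric comparisons."""

import numpy as np
import pandas as pd
import pytest

import mammodense as md
from mammodense.cohort import analyze_cohort, records_to_frame


@pytest.fixture(scope="module")
def flat_cohort():
    """15 subjects, no gradient, no entry-exit shift, truth-route analysis."""
    p = md.SyntheticParams(image_height_px=144, image_width_px=108,
                           corr_length=8.0, anterior_weight=0.0)
    subj = md.generate_cohort(n_subjects=15, seed=5, params=p,
                              exit_shift=md.ExitShift(0.0, 1.0))
    return analyze_cohort(subj, from_truth=True)


class TestAssignGroup:
    @pytest.mark.parametrize("pd_val,group", [
        (11.69, "G1"),   # group-1 left-exit mean
        (33.14, "G2"),
        (48.92, "G3"),
        (65.46, "G4"),   # group-4 left-exit mean
        (0.0, "G1"), (20.0, "G2"), (40.0, "G3"), (60.0, "G4"), (100.0, "G4"),
    ])
    def test_bins(self, pd_val, group):
        assert md.assign_group(pd_val) == group

    def test_out_of_range(self):
        for v in (-0.1, 100.1):
            with pytest.raises(ValueError):
                md.assign_group(v)

    def test_partition(self, flat_cohort):
        assert all(r.group in md.cohort.GROUPS for r in flat_cohort)


class TestCohortSummary:
    def test_single_subject(self, flat_cohort):
        t = md.cohort_summary(flat_cohort[:1])
        row = t.density.query("slot == 'left_exit' and metric == 'overall_pd' "
                              "and group == 'All'").iloc[0]
        a = flat_cohort[0].analyses["left_exit"].segmentation
        assert row["mean"] == pytest.approx(a.overall_pd) and row["sd"] == 0.0

    def test_counts_sum_to_cohort(self, flat_cohort):
        t = md.cohort_summary(flat_cohort)
        assert sum(t.group_counts.values()) == len(flat_cohort)

    def test_matches_independent_aggregation(self, flat_cohort):
        """Summary table equals a brute-force recomputation from the
        per-subject long frame."""
        t = md.cohort_summary(flat_cohort)
        frame = records_to_frame(flat_cohort)
        for _, row in t.density.sample(10, random_state=0).iterrows():
            sub = frame[frame["slot"] == row["slot"]]
            if row["group"] != "All":
                sub = sub[sub["group"] == row["group"]]
            vals = sub[row["metric"]].to_numpy()
            if len(vals) == 0:
                assert np.isnan(row["mean"])
            else:
                assert row["mean"] == pytest.approx(vals.mean())
                if len(vals) > 1:
                    assert row["sd"] == pytest.approx(vals.std(ddof=1))


class TestZonalTests:
    def test_identical_zones_no_signal(self, flat_cohort):
        recs = flat_cohort[:5]
        frame = records_to_frame(recs)
        # constant zonal PDs: degenerate Friedman reports p = 1, post hocs skipped
        import copy
        clones = copy.deepcopy(recs)
        for r in clones:
            for a in r.analyses.values():
                a.zones.posterior = a.zones.middle = a.zones.anterior = 30.0
        zt = md.zonal_tests(clones, by_group=False)
        assert zt.iloc[0]["friedman_p"] == 1.0
        assert np.isnan(zt.iloc[0]["wilcoxon_post_ant"])

    def test_anterior_gradient_detected(self):
        subj = md.generate_cohort(n_subjects=15, seed=0,
                                  exit_shift=md.ExitShift(0.0, 1.0))
        zt = md.zonal_tests(analyze_cohort(subj, from_truth=True), by_group=False)
        row = zt.iloc[0]
        assert row["friedman_p"] < 0.05
        assert row["mean_anterior"] > row["mean_middle"] > row["mean_posterior"]

    def test_reversed_gradient_flips_ordering(self):
        p = md.SyntheticParams(anterior_weight=-1.6)
        subj = md.generate_cohort(n_subjects=15, seed=0, params=p,
                                  exit_shift=md.ExitShift(0.0, 1.0))
        zt = md.zonal_tests(analyze_cohort(subj, from_truth=True), by_group=False)
        row = zt.iloc[0]
        assert row["mean_anterior"] < row["mean_middle"] < row["mean_posterior"]

    def test_small_group_flagged(self, flat_cohort):
        zt = md.zonal_tests(flat_cohort[:2], by_group=False)
        assert np.isnan(zt.iloc[0]["friedman_p"])


class TestLongitudinalTests:
    def test_mirrored_right_no_difference(self, flat_cohort):
        lt = md.longitudinal_tests(flat_cohort, by_group=False)
        lr = lt[lt["comparison"] == "pd_left_vs_right"].iloc[0]
        assert lr["median_diff"] == 0.0 and np.isnan(lr["p"])

    def test_identical_entry_exit_no_signal(self, flat_cohort):
        import copy
        clones = copy.deepcopy(flat_cohort)
        for r in clones:
            r.analyses["left_entry"] = r.analyses["left_exit"]
        lt = md.longitudinal_tests(clones, by_group=False)
        row = lt[lt["comparison"] == "moran_entry_vs_exit"].iloc[0]
        assert np.isnan(row["p"])

    def test_shortened_exit_correlation_detected(self):
        subj = md.generate_cohort(n_subjects=30, seed=4,
                                  exit_shift=md.ExitShift(0.0, 0.5))
        lt = md.longitudinal_tests(analyze_cohort(subj, from_truth=True),
                                   by_group=False)
        row = lt[lt["comparison"] == "moran_entry_vs_exit"].iloc[0]
        assert row["median_diff"] > 0  # exit I below entry I
        assert row["p"] < 0.05


class TestCorrelationTests:
    def test_monotone_extremes(self, flat_cohort):
        import copy
        clones = copy.deepcopy(flat_cohort[:8])
        for k, r in enumerate(clones):
            a = r.analyses["left_exit"]
            a.segmentation.breast_px = 1000 + k  # strictly increasing
            a.segmentation.breast_area_cm2 = float(10 + k)
            a.segmentation.overall_pd = float(10 + 2 * k)
        ct = md.correlation_tests(clones)
        r_up = ct.query("slot == 'left_exit' and pair == 'breast_area_vs_pd'").iloc[0]
        assert r_up["spearman_r"] == pytest.approx(1.0)
        for r in clones:
            a = r.analyses["left_exit"]
            a.segmentation.overall_pd = 100.0 - a.segmentation.overall_pd
        ct = md.correlation_tests(clones)
        r_dn = ct.query("slot == 'left_exit' and pair == 'breast_area_vs_pd'").iloc[0]
        assert r_dn["spearman_r"] == pytest.approx(-1.0)

    def test_size_density_coupling_gives_negative_r(self, flat_cohort):
        ct = md.correlation_tests(flat_cohort)
        row = ct.query("slot == 'left_exit' and pair == 'breast_area_vs_pd'").iloc[0]
        assert row["spearman_r"] < 0

    def test_constant_input_flagged(self, flat_cohort):
        import copy
        clones = copy.deepcopy(flat_cohort[:5])
        for r in clones:
            r.analyses["left_exit"].segmentation.breast_area_cm2 = 100.0
        ct = md.correlation_tests(clones)
        row = ct.query("slot == 'left_exit' and pair == 'breast_area_vs_pd'").iloc[0]
        assert np.isnan(row["spearman_r"])
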