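import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tojreplay.exceptions import InsufficientDataError
from tojreplay.metrics import (
    clip_rt_contrast,
    compression_factor,
    inverse_efficiency,
    rt_span_from_table,
    sliding_accuracy,
    trial_type_anova,
)
from tojreplay.trial_data import TrialTable

from .test_trial_data import make_trial


def subject_condition_table(spec):
    """spec: list of (subject, boundary_condition, rt, correct, n) cell definitions."""
    rows = []
    geometry = {
        "within_clip1": (40, 80),
        "within_clip2": (130, 170),
        "across": (100, 130),
    }
    for subject, cond, rt, correct, n in spec:
        early, late = geometry[cond]
        for k in range(n):
            chosen = early if correct else late
            rows.append(
                make_trial(
                    subject_id=subject,
                    trial_index=k + 1,
                    boundary_frame=125,
                    probe_early_frame=early,
                    probe_late_frame=late,
                    chosen_frame=chosen,
                    correct=correct,
                    rt_s=rt,
                    boundary_condition=cond,
                ).__dict__
            )
    return TrialTable(pd.DataFrame(rows))


class TestCompressionFactor:
    def test_reported_arithmetic(self):
        scan, factor = compression_factor(0.942, 10.0)
        assert scan == pytest.approx(94.2)
        assert factor == pytest.approx(10.61, abs=0.01)

    def test_real_time_replay(self):
        _, factor = compression_factor(10.0, 10.0)
        assert factor == 1.0

    def test_direct_arithmetic(self):
        scan, factor = compression_factor(0.5, 10.0)
        assert (scan, factor) == (50.0, 20.0)

    def test_inverse_identity(self):
        for span in (0.3, 0.942, 2.5):
            _, factor = compression_factor(span, 10.0)
            assert factor * span == pytest.approx(10.0, rel=1e-12)

    def test_nonpositive_span_rejected(self):
        with pytest.raises(ValueError):
            compression_factor(0.0)

    def test_span_estimate_tracks_generator_scan_rate(self, filtered_table):
        # mean RT grows by scan_rate * duration across the video; promptness
        # noise inflates the measured mean-RT span somewhat (Jensen), so the
        # regression span sits above the generative 0.942 s but on its scale
        span = rt_span_from_table(filtered_table)
        assert 0.8 < span < 1.5


class TestClipContrast:
    def test_null_case(self):
        spec = []
        for s in ("A", "B", "C"):
            spec += [(s, "within_clip1", 1.5, True, 20), (s, "within_clip2", 1.5, True, 20)]
        c = clip_rt_contrast(subject_condition_table(spec), with_log=False)
        assert c.t == pytest.approx(0.0, abs=1e-9)
        assert c.p == pytest.approx(0.5, abs=0.01)

    def test_hand_computed_three_subject_toy(self):
        diffs = {"A": -0.1, "B": -0.2, "C": -0.3}
        spec = []
        for s, d in diffs.items():
            spec += [(s, "within_clip1", 1.5 + d, True, 10), (s, "within_clip2", 1.5, True, 10)]
        c = clip_rt_contrast(subject_condition_table(spec), with_log=False)
        assert c.t == pytest.approx(-3.464, abs=1e-3)
        assert c.df == 2
        assert c.cohens_d == pytest.approx(-0.2 / 0.1, rel=1e-6)

    def test_matches_scipy_oracle(self, strict_cohort):
        c = clip_rt_contrast(strict_cohort)
        per = c.per_subject.set_index("subject_id")
        t, p = stats.ttest_rel(per[1], per[2], alternative="less")
        assert c.t == pytest.approx(t, rel=1e-8)
        assert c.p == pytest.approx(p, rel=1e-8)

    def test_forward_replay_direction_on_cohort(self, strict_cohort):
        c = clip_rt_contrast(strict_cohort)
        assert c.mean_rt_clip1 < c.mean_rt_clip2
        assert c.p < 0.05
        assert c.log_rt is not None and c.log_rt.p < 0.05

    def test_subject_missing_clip_excluded(self):
        spec = [("A", "within_clip1", 1.4, True, 10), ("A", "within_clip2", 1.6, True, 10),
                ("B", "within_clip1", 1.3, True, 10), ("B", "within_clip2", 1.7, True, 10),
                ("C", "within_clip1", 1.5, True, 10)]
        c = clip_rt_contrast(subject_condition_table(spec), with_log=False)
        assert c.excluded_subjects == ["C"]
        assert c.df == 1


class TestTrialTypeAnova:
    def test_equal_means_give_near_zero_f(self):
        spec = []
        for s in ("A", "B", "C"):
            for cond in ("across", "within_clip1", "within_clip2"):
                spec += [(s, cond, 1.5, True, 10)]
        res = trial_type_anova(subject_condition_table(spec))
        assert res["F"] == pytest.approx(0.0, abs=1e-12)

    def test_textbook_separated_groups(self, rng):
        spec = []
        means = {"across": 1.0, "within_clip1": 2.0, "within_clip2": 3.0}
        for i in range(6):
            for cond, mu in means.items():
                spec += [(f"S{i}", cond, mu + rng.normal(0, 0.05), True, 5)]
        res = trial_type_anova(subject_condition_table(spec))
        assert res["p"] < 1e-6

    def test_df_layout_matches_six_subject_design(self, strict_cohort):
        res = trial_type_anova(strict_cohort)
        assert (res["df_between"], res["df_within"]) == (2, 15)

    def test_matches_scipy_oracle(self, strict_cohort):
        res = trial_type_anova(strict_cohort)
        per = strict_cohort.df.groupby(["subject_id", "boundary_condition"])["rt_s"].mean().unstack()
        f, p = stats.f_oneway(per["across"], per["within_clip1"], per["within_clip2"])
        assert res["F"] == pytest.approx(f, rel=1e-10)


class TestSlidingWindows:
    def test_constant_accuracy_flat_at_one(self):
        spec = [("A", "within_clip1", 1.5, True, 50)]
        out = sliding_accuracy(subject_condition_table(spec))
        assert np.nanmax(out["mean"]) == 1.0 and np.nanmin(out["mean"]) == 1.0

    def test_huge_window_recovers_global_accuracy(self):
        spec = [("A", "within_clip1", 1.5, True, 30), ("A", "within_clip1", 1.5, False, 10)]
        table = subject_condition_table(spec)
        out = sliding_accuracy(table, window_frames=10_000)
        np.testing.assert_allclose(out["mean"], 0.75)

    def test_boundary_boost_shows_in_curve(self):
        # accuracy 1.0 for targets near the boundary, 0.6 far from it
        rows = []
        for i, early in enumerate(range(10, 230, 5)):
            near = abs(early - 125) < 25
            for k in range(6):
                correct = True if near else (k < 3)
                rows.append(
                    make_trial(
                        trial_index=len(rows) + 1,
                        boundary_frame=125,
                        probe_early_frame=early,
                        probe_late_frame=early + 10,
                        chosen_frame=early if correct else early + 10,
                        correct=correct,
                        rt_s=1.5,
                        boundary_condition="across" if early < 125 <= early + 10 else
                        ("within_clip1" if early + 10 < 125 else "within_clip2"),
                    ).__dict__
                )
        out = sliding_accuracy(TrialTable(pd.DataFrame(rows)), window_frames=15)
        curve = out.set_index("center_frame")["mean"]
        assert curve.loc[120:130].mean() > curve.loc[:80].mean()
        assert out.attrs["chance"] == 0.5

    def test_promptness_curve_decreases_for_strict_forward(self, filtered_table):
        out = sliding_accuracy(filtered_table.within_context(), measure="promptness",
                               window_frames=50, step_frames=10)
        valid = out.dropna()
        early = valid[valid["center_frame"] < 75]["mean"].mean()
        late = valid[valid["center_frame"] > 175]["mean"].mean()
        assert early > late


class TestInverseEfficiency:
    def test_direct_formula(self):
        spec = [("A", "within_clip1", 1.5, True, 3), ("A", "within_clip1", 1.5, False, 1)]
        res = inverse_efficiency(subject_condition_table(spec), n_segments=2)
        row = res["ies"]
        cell = row[(row["subject_id"] == "A")].iloc[0]
        assert cell["ies"] == pytest.approx(1500.0 / 75.0)

    def test_flat_profile_yields_near_zero_f(self):
        rows = []
        for s in ("A", "B", "C"):
            for early in (20, 80, 150, 210):
                for k in range(10):
                    correct = k < 8
                    rows.append(
                        make_trial(
                            subject_id=s, trial_index=len(rows) + 1, boundary_frame=125,
                            probe_early_frame=early, probe_late_frame=early + 10,
                            chosen_frame=early if correct else early + 10,
                            correct=correct, rt_s=1.5,
                            boundary_condition="within_clip1" if early + 10 < 125 else "within_clip2",
                        ).__dict__
                    )
        res = inverse_efficiency(TrialTable(pd.DataFrame(rows)))
        assert res["F"] == pytest.approx(0.0, abs=1e-9)

    def test_df_layout_for_six_subjects(self, strict_cohort):
        res = inverse_efficiency(strict_cohort)
        assert (res["df_between"], res["df_within"]) == (3, 20)

    def test_units_ms_over_percent(self, strict_cohort):
        res = inverse_efficiency(strict_cohort)
        cell = res["ies"].iloc[0]
        assert cell["ies"] == pytest.approx(cell["rt_ms"] / cell["pct_correct"], rel=1e-12)
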