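import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from tojreplay.exceptions import EmptySegmentError
from tojreplay.rsa import (
    RDM,
    ReplayModelSpec,
    ReplayRSA,
    argmax_offsets,
    compare_models,
    fdr_adjust,
    global_compression_spec,
    model_rdm,
    model_rt_pattern,
    offset_model_family,
    rdm_from_profile,
    segment_profile,
    spearman_model_fit,
    strict_forward_spec,
)
from tojreplay.trial_data import TrialTable

from .test_trial_data import make_trial


def table_from_segment_rts(segment_rts, n_per_segment=5, subject_id="S1"):
    """Table whose within-context trials put constant RTs into each of 8 bins."""
    n_seg = len(segment_rts)
    rows = []
    n_frames, boundary = 250, 249  # all trials within clip 1
    for seg, rt in enumerate(segment_rts):
        for k in range(n_per_segment):
            frame = int((seg + 0.5) * (n_frames - 1) / n_seg)
            rows.append(
                make_trial(
                    subject_id=subject_id,
                    boundary_frame=boundary,
                    probe_early_frame=frame,
                    probe_late_frame=frame + 1,
                    chosen_frame=frame,
                    rt_s=rt,
                    boundary_condition="within_clip1",
                ).__dict__
            )
    return TrialTable(pd.DataFrame(rows))


class TestRdmConstruction:
    def test_hand_computed_three_segment_case(self):
        rdm = rdm_from_profile(np.array([1.0, 2.0, 4.0]))
        # raw distances {d12=1, d13=3, d23=2} -> ranks {1,3,2} -> scaled {0,1,.5}
        expected = np.array([[0, 0, 1], [0, 0, 0.5], [1, 0.5, 0]])
        np.testing.assert_allclose(rdm.values, expected)
        assert not rdm.degenerate

    def test_all_tied_profile_degenerates_to_half(self):
        rdm = rdm_from_profile(np.full(8, 1.5))
        assert rdm.degenerate
        off = rdm.upper()
        np.testing.assert_allclose(off, 0.5)
        np.testing.assert_allclose(np.diag(rdm.values), 0.0)

    @settings(deadline=None, max_examples=50)
    @given(
        means=st.lists(st.floats(0.5, 5.0, allow_nan=False), min_size=3, max_size=10)
    )
    def test_structural_invariants(self, means):
        rdm = rdm_from_profile(np.array(means))
        v = rdm.values
        np.testing.assert_allclose(v, v.T)
        np.testing.assert_allclose(np.diag(v), 0.0)
        off = rdm.upper()
        assert off.min() >= 0.0 and off.max() <= 1.0
        if not rdm.degenerate:
            assert off.min() == 0.0 and off.max() == 1.0

    def test_rank_scale_preserves_order(self):
        means = np.array([1.0, 1.7, 2.1, 4.0])
        raw = np.abs(means[:, None] - means[None, :])
        rdm = rdm_from_profile(means)
        iu = np.triu_indices(4, k=1)
        assert stats.spearmanr(raw[iu], rdm.values[iu]).statistic == pytest.approx(1.0)

    def test_spearman_invariant_to_affine_means_and_monotone_distances(self):
        # |m_i - m_j| ranks survive affine maps of the means and any strictly
        # increasing map of the distances themselves
        means = np.array([1.03, 1.41, 1.97, 2.24, 2.86, 3.19, 3.92, 4.28])
        model = model_rdm(strict_forward_spec(), 8)
        r1 = stats.spearmanr(rdm_from_profile(means).upper(), model.upper()).statistic
        r2 = stats.spearmanr(
            rdm_from_profile(3.0 * means + 7.0).upper(), model.upper()
        ).statistic
        assert r1 == pytest.approx(r2)
        iu = np.triu_indices(8, k=1)
        raw = np.abs(means[:, None] - means[None, :])[iu]
        r3 = stats.spearmanr(np.sqrt(raw), model.upper()).statistic
        assert r1 == pytest.approx(r3)


class TestSegmentProfile:
    def test_constant_rt(self):
        profile = segment_profile(table_from_segment_rts([1.5] * 8))
        np.testing.assert_allclose(profile.means, 1.5)
        assert profile.counts.sum() == 40

    def test_monotone_profile_from_strict_forward_data(self, filtered_table):
        profile = segment_profile(filtered_table)
        assert profile.n_segments == 8
        assert (np.diff(profile.means) > 0).all()

    def test_empty_segment_error_names_bin(self):
        table = table_from_segment_rts([1.0, 2.0, 3.0], n_per_segment=1)
        with pytest.raises(EmptySegmentError):
            segment_profile(table, n_segments=8)


class TestModelFamily:
    def test_strict_forward_pattern_is_linear(self):
        np.testing.assert_allclose(
            model_rt_pattern(strict_forward_spec(), 8), np.arange(1, 9)
        )

    def test_full_reset_is_sawtooth(self):
        np.testing.assert_allclose(
            model_rt_pattern(global_compression_spec(), 8),
            [1, 2, 3, 4, 1, 2, 3, 4],
        )

    def test_intermediate_offset(self):
        spec = ReplayModelSpec(offset=-2.0)
        np.testing.assert_allclose(
            model_rt_pattern(spec, 8), [1, 2, 3, 4, 3, 4, 5, 6]
        )

    def test_family_grid_and_centre(self):
        family = offset_model_family()
        offsets = [s.offset for s, _ in family]
        assert len(family) == 11
        assert offsets[0] == -4.0 and offsets[5] == 0.0 and offsets[-1] == 4.0
        np.testing.assert_allclose(np.diff(offsets), 0.8)
        centre_rdm = family[5][1]
        np.testing.assert_allclose(
            centre_rdm.values, model_rdm(strict_forward_spec(), 8).values
        )

    def test_even_model_count_rejected(self):
        with pytest.raises(ValueError):
            offset_model_family(n_models=10)

    def test_family_is_locally_monotone(self):
        family = offset_model_family()
        rs = np.array(
            [
                stats.spearmanr(a.upper(), b.upper()).statistic
                for (_, a), (_, b) in zip(family, family[1:])
            ]
        )
        # adjacent models correlate at least as well as two-step-apart models
        rs2 = np.array(
            [
                stats.spearmanr(a.upper(), b.upper()).statistic
                for (_, a), (_, b) in zip(family, family[2:])
            ]
        )
        assert (rs[:-1] >= rs2 - 1e-9).all()


class TestSpearmanModelFit:
    def test_noise_free_self_correlation(self):
        pattern = model_rt_pattern(strict_forward_spec(), 8)
        table = table_from_segment_rts(pattern, n_per_segment=10)
        model = model_rdm(strict_forward_spec(), 8)
        mean_r, sem, rs = spearman_model_fit(table, model, n_iter=20, rng=0)
        np.testing.assert_allclose(rs, 1.0)
        assert sem == 0.0

    def test_strict_forward_data_prefers_strict_forward_model(self, filtered_table):
        strict = model_rdm(strict_forward_spec(), 8)
        reset = model_rdm(global_compression_spec(), 8)
        r_strict, _, _ = spearman_model_fit(filtered_table, strict, n_iter=50, rng=1)
        r_reset, _, _ = spearman_model_fit(filtered_table, reset, n_iter=50, rng=1)
        assert r_strict > r_reset

    def test_null_calibration_with_shuffled_profile(self, rng):
        # random segment means carry no replay structure: r should straddle 0
        rs_all = []
        for i in range(20):
            means = rng.permutation(8).astype(float)
            r = stats.spearmanr(
                rdm_from_profile(means).upper(),
                model_rdm(strict_forward_spec(), 8).upper(),
            ).statistic
            rs_all.append(r)
        mean_r = np.mean(rs_all)
        sem = np.std(rs_all, ddof=1) / np.sqrt(len(rs_all))
        assert abs(mean_r) < 2.5 * sem + 0.1


class TestCompareModels:
    def test_identical_vectors_degenerate_to_one(self):
        rs = np.linspace(0, 1, 100)
        assert compare_models(rs, rs.copy()) == 1.0

    def test_constant_difference_is_decisive(self, rng):
        rs_b = rng.uniform(0, 0.4, size=100)
        p = compare_models(rs_b + 0.5, rs_b)
        assert p < 1e-10

    def test_bh_adjustment_matches_standard_procedure(self):
        adj = fdr_adjust([0.01, 0.04, 0.03])
        # step-up BH: sorted {0.01,0.03,0.04} -> {0.03, 0.045, 0.04} -> cummin
        # from the largest gives {0.03, 0.04, 0.04}
        np.testing.assert_allclose(adj, [0.03, 0.04, 0.04])

    def test_bh_against_brute_force_oracle(self, rng):
        p = rng.uniform(0, 1, size=9)
        order = np.argsort(p)
        n = len(p)
        stepped = p[order] * n / np.arange(1, n + 1)
        monotone = np.minimum.accumulate(stepped[::-1])[::-1]
        expected = np.empty(n)
        expected[order] = np.minimum(monotone, 1.0)
        np.testing.assert_allclose(fdr_adjust(p), expected, rtol=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_models([0.1, 0.2], [0.1])


class TestReplayRSAApi:
    def test_fit_reports_both_models_and_contrast(self, strict_cohort):
        fit = ReplayRSA(strict_cohort).fit(n_iter=30, seed=0)
        assert fit.mean_r["strict_forward"] > fit.mean_r["global_compression"]
        table = fit.pairwise_table()
        assert (table["p_fdr"] < 0.05).all()
        assert "strict_forward" in fit.summary()

    def test_offset_sweep_peaks_at_zero_for_strict_data(self, filtered_table):
        sweep = ReplayRSA(filtered_table).offset_sweep()
        best = argmax_offsets(sweep)
        assert np.min(np.abs(best)) <= 0.8 + 1e-9

    def test_segment_count_variants_agree(self, filtered_table):
        for n_seg in (10, 14):
            rsa = ReplayRSA(filtered_table, n_segments=n_seg)
            sweep = rsa.offset_sweep()
            best = argmax_offsets(sweep)
            step = np.diff(sweep["offset"])[0]
            assert np.min(np.abs(best)) <= step + 1e-9
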