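"""Circular patch calling, centre/edge quantification, group statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cupquant.errors import EmptyDistribution, InsufficientData, ProfileError
from cupquant.membrane import MembraneProfile
from cupquant.patches import (
    call_patches,
    compare_groups,
    holm_correction,
    measure_center_edge,
    patch_size_stats,
)
from cupquant.segment import CytosolStats
from cupquant.synth import truth_index_set


def make_profile(values, spacing=0.5):
    values = np.asarray(values, dtype=float)
    return MembraneProfile(
        raw={"patch": values}, norm={"patch": values / 100.0},
        arc_positions_um=np.arange(values.size) * spacing,
        arc_spacing_um=spacing, band_width_um=0.5)


def make_cyto(mean=100.0, sd=10.0):
    return CytosolStats(mean=np.array([mean]), sd=np.array([sd]),
                        n_pixels=10_000, erosion_margin_um=1.0)


class TestCallPatches:
    def test_hand_worked_threshold_example(self):
        """Cytosol 100 +/- 10, k=1 -> threshold 110; a plateau of 120 over
        indices 10..19 is one patch [10, 20) with centre 14 (tie -> lower)."""
        values = np.full(100, 100.0)
        values[10:20] = 120.0
        call = call_patches(make_profile(values), make_cyto(), "patch",
                            channel_index=0, k_sd=1.0)
        assert call.threshold_value == pytest.approx(110.0)
        assert call.n_patches == 1
        iv = call.intervals[0]
        assert (iv.start_idx, iv.end_idx, iv.center_idx) == (10, 20, 14)
        assert iv.arc_length_um == pytest.approx(10 * 0.5)

    def test_profile_at_cytosol_mean_calls_nothing(self):
        call = call_patches(make_profile(np.full(100, 100.0)), make_cyto(),
                            "patch", channel_index=0)
        assert call.n_patches == 0

    def test_value_exactly_at_threshold_excluded(self):
        values = np.full(100, 100.0)
        values[30:40] = 110.0  # exactly mean + 1 SD: "greater than" is strict
        call = call_patches(make_profile(values), make_cyto(), "patch",
                            channel_index=0)
        assert call.n_patches == 0

    def test_wraparound_run_is_one_patch(self):
        values = np.full(100, 100.0)
        values[95:] = 130.0
        values[:5] = 130.0
        call = call_patches(make_profile(values), make_cyto(), "patch",
                            channel_index=0)
        assert call.n_patches == 1
        iv = call.intervals[0]
        assert (iv.start_idx, iv.end_idx, iv.length) == (95, 5, 10)

    def test_everything_above_threshold_is_single_full_circle(self):
        call = call_patches(make_profile(np.full(100, 150.0)), make_cyto(),
                            "patch", channel_index=0)
        assert call.n_patches == 1
        assert call.intervals[0].length == 100

    def test_runs_shorter_than_minimum_discarded(self):
        values = np.full(100, 100.0)
        values[10:12] = 130.0
        call = call_patches(make_profile(values), make_cyto(), "patch",
                            channel_index=0, min_patch_points=3)
        assert call.n_patches == 0

    def test_too_coarse_profile_rejected(self):
        with pytest.raises(ProfileError):
            call_patches(make_profile(np.full(5, 100.0)), make_cyto(),
                         "patch", channel_index=0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(shift=st.integers(min_value=0, max_value=99),
           seed=st.integers(min_value=0, max_value=10))
    def test_rotation_equivariance(self, shift, seed):
        rng = np.random.default_rng(seed)
        values = 100.0 + 5.0 * rng.standard_normal(100)
        values[20:33] += 40.0
        values[60:70] += 35.0
        base = call_patches(make_profile(values), make_cyto(), "patch",
                            channel_index=0)
        rotated = call_patches(make_profile(np.roll(values, shift)),
                               make_cyto(), "patch", channel_index=0)
        expect = {(iv.start_idx + shift) % 100 for iv in base.intervals}
        assert {iv.start_idx for iv in rotated.intervals} == expect

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(min_value=0, max_value=20))
    def test_total_called_length_monotone_in_k_sd(self, seed):
        rng = np.random.default_rng(seed)
        values = 100.0 + 15.0 * rng.standard_normal(100)
        lengths = []
        for k in (0.5, 1.0, 2.0, 3.0):
            call = call_patches(make_profile(values), make_cyto(), "patch",
                                channel_index=0, k_sd=k, min_patch_points=1)
            lengths.append(sum(iv.length for iv in call.intervals))
        assert lengths == sorted(lengths, reverse=True)

    def test_threshold_identity_under_constant_offset(self):
        rng = np.random.default_rng(3)
        values = 100.0 + 12.0 * rng.standard_normal(100)
        c = 55.0
        base = call_patches(make_profile(values), make_cyto(100.0), "patch",
                            channel_index=0)
        shifted = call_patches(make_profile(values + c), make_cyto(100.0 + c),
                               "patch", channel_index=0)
        assert [(iv.start_idx, iv.length) for iv in base.intervals] == \
               [(iv.start_idx, iv.length) for iv in shifted.intervals]

    def test_recovery_against_ground_truth(self, default_movie):
        """Mean per-frame Jaccard between called and truth point sets."""
        dm = default_movie
        jac = []
        for call, t in zip(dm.calls, dm.good):
            called = call.called_index_set()
            tru = truth_index_set(dm.truth, t, dm.contours[t])
            if called or tru:
                jac.append(len(called & tru) / len(called | tru))
        assert np.mean(jac) >= 0.8


class TestCenterEdge:
    def test_symmetric_odd_patch_center_equidistant(self):
        values = np.full(100, 100.0)
        values[40:47] = 130.0  # length 7, centre 43
        call = call_patches(make_profile(values), make_cyto(), "patch",
                            channel_index=0)
        iv = call.intervals[0]
        assert iv.center_idx - iv.start_idx == (iv.start_idx + iv.length - 1) \
            - iv.center_idx

    def test_same_channel_center_above_threshold(self):
        values = np.full(100, 100.0)
        values[40:50] = 130.0
        prof = make_profile(values)
        call = call_patches(prof, make_cyto(), "patch", channel_index=0)
        ms = measure_center_edge(call, prof, make_cyto(), "patch")
        assert ms[0].i_center * 100.0 > call.threshold_value

    def test_short_patches_skipped_with_warning(self):
        values = np.full(100, 100.0)
        values[40:42] = 130.0
        prof = make_profile(values)
        call = call_patches(prof, make_cyto(), "patch", channel_index=0,
                            min_patch_points=1)
        with pytest.warns(UserWarning):
            ms = measure_center_edge(call, prof, make_cyto(), "patch")
        assert ms == []

    def test_ring_channel_edge_enriched_center_at_background(self, default_movie):
        """On synthetic movies the second reporter is enriched at patch
        edges but indistinguishable from cytosol at patch centres."""
        ms = default_movie.measurements
        assert len(ms) >= 17
        centers = np.array([m.i_center for m in ms])
        edges = np.array([m.i_edge for m in ms])
        t_edge = compare_groups(edges, np.ones_like(edges), paired=True)
        t_center = compare_groups(centers, np.ones_like(centers), paired=True)
        assert edges.mean() > 1.3 and t_edge.p_value < 0.01
        assert abs(centers.mean() - 1.0) < 0.1
        assert t_center.p_value > 0.05


class TestSizeStats:
    def test_arc_length_arithmetic(self):
        values = np.full(100, 100.0)
        values[10:20] = 130.0
        call = call_patches(make_profile(values, spacing=0.2), make_cyto(),
                            "patch", channel_index=0)
        st_ = patch_size_stats([call])
        assert st_.sizes_um == [pytest.approx(2.0)]
        assert st_.n == 1

    def test_no_patches_raises_empty_distribution(self):
        call = call_patches(make_profile(np.full(100, 100.0)), make_cyto(),
                            "patch", channel_index=0)
        with pytest.raises(EmptyDistribution):
            patch_size_stats([call])

    def test_wider_truth_gives_larger_measured_sizes(self):
        from cupquant import PipelineConfig, SynthConfig, analyse_movie, make_cell_movie
        sizes = {}
        for label, width in (("narrow", 40.0), ("wide", 80.0)):
            cfg = SynthConfig(seed=6, n_frames=15, patch_width_deg_mean=width,
                              patch_width_deg_sd=6.0, initial_patches=2,
                              patch_birth_rate=0.05)
            stack, _ = make_cell_movie(cfg)
            ana = analyse_movie(stack, PipelineConfig())
            sizes[label] = patch_size_stats(ana.calls).mean_um
        assert sizes["wide"] > sizes["narrow"]


class TestCompareGroups:
    def test_identical_paired_groups(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = compare_groups(a, a.copy(), paired=True)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_paired_requires_equal_n(self):
        with pytest.raises(InsufficientData):
            compare_groups([1, 2, 3], [1, 2], paired=True)

    def test_insufficient_data_rejected(self):
        with pytest.raises(InsufficientData):
            compare_groups([1.0], [1.0, 2.0])

    def test_separated_groups_detected_in_every_replicate(self):
        """Normal(1, 0.3) vs Normal(2, 0.3), n=30: Welch p < 0.01 in >= 99%
        of seeded replicates."""
        rng = np.random.default_rng(0)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            a = rng.normal(1.0, 0.3, 30)
            b = rng.normal(2.0, 0.3, 30)
            hits += compare_groups(a, b).p_value < 0.01
        assert hits >= 0.99 * n_rep

    def test_null_p_values_uniform(self):
        """Identical generating distributions: the p-value distribution is
        uniform (KS vs U(0,1) at alpha = 0.01 over 1000 replicates)."""
        rng = np.random.default_rng(1)
        ps = [compare_groups(rng.normal(1.0, 0.3, 30),
                             rng.normal(1.0, 0.3, 30)).p_value
              for _ in range(1000)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_holm_correction_matches_hand_computation():
    # p = (0.01, 0.04, 0.03) -> ordered (0.01, 0.03, 0.04):
    # adj = (3*0.01, max(.03, 2*0.03), max(...,1*0.04)) = (0.03, 0.06, 0.06)
    adj = holm_correction([0.01, 0.04, 0.03])
    assert adj == pytest.approx([0.03, 0.06, 0.06])
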