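"""Contour correspondence, membrane speed, kymographs, patch tracking."""

import dataclasses

import numpy as np
import pytest

from cupquant import PipelineConfig, SynthConfig, analyse_movie, make_cell_movie
from cupquant.dynamics import (
    build_edge_kymograph,
    build_membrane_kymograph,
    cumulative_offsets,
    edge_mean_timeseries,
    local_speed,
    match_origins,
    register_contours,
    speed_intensity_analysis,
    speed_map,
    track_patches,
)
from cupquant.errors import TrackingLost
from cupquant.membrane import MembraneProfile
from cupquant.patches import PatchCall, PatchInterval
from cupquant.segment import Contour
from cupquant.synth import make_radius_ramp_movie, wrap_angle

PX = 0.1


def circle_contour(radius, center=(12.8, 12.8), n=100, phase=0.0):
    theta = 2 * np.pi * np.arange(n) / n + phase
    pts = np.stack([center[0] + radius * np.cos(theta),
                    center[1] + radius * np.sin(theta)], axis=1)
    return Contour(points=pts, arc_spacing_um=2 * np.pi * radius / n,
                   centroid=np.array(center), perimeter_um=2 * np.pi * radius)


def synthetic_profile(values, spacing=0.5, frame=0):
    values = np.asarray(values, dtype=float)
    return MembraneProfile(
        raw={"patch": values}, norm={"patch": values},
        arc_positions_um=np.arange(values.size) * spacing,
        arc_spacing_um=spacing, band_width_um=0.5, frame_index=frame)


def synthetic_call(intervals, n=100, frame=0):
    return PatchCall(
        frame_index=frame, channel="patch",
        intervals=[PatchInterval(start_idx=s, length=l, n_total=n,
                                 arc_length_um=l * 0.5)
                   for s, l in intervals],
        threshold_value=110.0, k_sd=1.0, n_points=n, arc_spacing_um=0.5)


class TestRegisterContours:
    def test_identical_contours_map_to_identity(self):
        c = circle_contour(8.0)
        corr = register_contours(c, c)
        assert corr.offset == 0
        assert np.allclose(corr.displacement, 0.0, atol=1e-9)
        assert np.array_equal(corr.mapping, np.arange(100))

    def test_index_rotation_recovered(self):
        # material point i moves to index i+10: the recovered offset is 10
        c0 = circle_contour(8.0)
        rotated = dataclasses.replace(c0, points=np.roll(c0.points, 10, axis=0))
        corr = register_contours(c0, rotated)
        assert corr.offset % 100 == 10
        assert np.allclose(np.linalg.norm(corr.displacement, axis=1), 0.0,
                           atol=1e-9)

    def test_pure_translation_displacement_is_normal_projection(self):
        """Nearest-point refinement recovers the normal component of a rigid
        translation: d·n at each point, magnitude |d| at front and rear."""
        c0 = circle_contour(8.0)
        d = np.array([0.3, 0.0])  # within the small-displacement regime
        c1 = dataclasses.replace(c0, points=c0.points + d,
                                 centroid=c0.centroid + d)
        corr = register_contours(c0, c1)
        normals = c0.normals()
        expected = (normals @ d)[:, None] * normals
        assert np.allclose(corr.displacement, expected, atol=0.05)
        assert np.max(np.linalg.norm(corr.displacement, axis=1)) == \
            pytest.approx(0.3, rel=0.05)

    def test_large_centroid_jump_raises(self):
        c0 = circle_contour(4.0, center=(10.0, 10.0))
        c1 = circle_contour(4.0, center=(16.0, 10.0))
        with pytest.raises(TrackingLost):
            register_contours(c0, c1)


class TestLocalSpeed:
    def test_static_cell_has_zero_speed(self):
        c = circle_contour(8.0)
        corr = register_contours(c, c)
        assert np.allclose(local_speed(corr, c, 1.0), 0.0, atol=1e-9)

    def test_expanding_circle_matches_analytic_rate(self):
        v = 0.1
        c0 = circle_contour(8.0)
        c1 = circle_contour(8.0 + v)
        corr = register_contours(c0, c1)
        speeds = local_speed(corr, c0, 1.0)
        assert np.all(speeds > 0)
        assert speeds.mean() == pytest.approx(v, rel=0.1)

    def test_translation_mean_signed_speed_near_zero(self):
        c0 = circle_contour(8.0)
        c1 = dataclasses.replace(
            c0, points=c0.points + np.array([0.3, 0.0]),
            centroid=c0.centroid + np.array([0.3, 0.0]))
        corr = register_contours(c0, c1)
        speeds = local_speed(corr, c0, 1.0)
        assert abs(speeds.mean()) < 0.03  # front positive, rear negative
        assert speeds.max() > 0.2 and speeds.min() < -0.2

    def test_affine_motions_match_analytic_normal_velocity(self):
        """Translation + expansion: RMS error < 10% of the field maximum."""
        c0 = circle_contour(8.0)
        shift = np.array([0.4, 0.2])
        growth = 0.3
        theta = np.arctan2(c0.points[:, 1] - c0.centroid[1],
                           c0.points[:, 0] - c0.centroid[0])
        c1 = dataclasses.replace(
            c0,
            points=(c0.centroid + shift)[None, :] + (8.0 + growth)
            * np.stack([np.cos(theta), np.sin(theta)], axis=1),
            centroid=c0.centroid + shift)
        corr = register_contours(c0, c1)
        speeds = local_speed(corr, c0, 1.0)
        normal = np.stack([np.cos(theta), np.sin(theta)], axis=1)
        analytic = growth + normal @ shift
        rms = np.sqrt(np.mean((speeds - analytic) ** 2))
        assert rms < 0.1 * np.abs(analytic).max()

    def test_rendered_radius_ramp_recovers_expansion_speed(self):
        cfg = SynthConfig(seed=5, n_frames=8, noise_poisson_scale=0,
                          noise_gauss_sd=0, drift_speed_um_s=0.0,
                          protrusion_amp_um=0.0)
        stack, _ = make_radius_ramp_movie(cfg, 0.1)
        ana = analyse_movie(stack, PipelineConfig())
        speeds = []
        for a, b in zip(ana.good[:-1], ana.good[1:]):
            corr = register_contours(ana.contours[a], ana.contours[b])
            speeds.append(local_speed(corr, ana.contours[a], 1.0))
        mean_speed = np.mean(speeds)
        assert mean_speed == pytest.approx(0.1, rel=0.1)


class TestSpeedIntensity:
    def test_protrusions_at_ring_segments_give_positive_correlation(self):
        cfg = SynthConfig(seed=6, protrusion_mode="patch",
                          protrusion_amp_um=0.4, drift_speed_um_s=0.0,
                          patch_lifetime_frames_mean=500, patch_birth_rate=0.3,
                          initial_patches=1, split_probability=0.0,
                          noise_poisson_scale=0, noise_gauss_sd=0)
        stack, _ = make_cell_movie(cfg)
        ana = analyse_movie(stack, PipelineConfig())
        corrs = [register_contours(ana.contours[a], ana.contours[b])
                 for a, b in zip(ana.good[:-1], ana.good[1:])]
        sm = speed_map([ana.contours[t] for t in ana.good], corrs, 1.0)
        hist = speed_intensity_analysis(sm, [ana.profiles[t] for t in ana.good],
                                        "ring")
        assert hist.pearson_r > 0

        # shuffling destroys the association
        rng = np.random.default_rng(0)
        v = sm.speeds.ravel()
        i = np.concatenate([ana.profiles[t].norm["ring"]
                            for t in ana.good[:-1]])
        from cupquant.membrane import joint_histogram
        shuffled = joint_histogram(rng.permutation(v), i)
        assert abs(shuffled.pearson_r) < 0.1

    def test_zero_motion_correlation_flagged_undefined(self):
        c = circle_contour(8.0)
        corr = register_contours(c, c)
        sm = speed_map([c, c], [corr], 1.0)
        prof = synthetic_profile(np.random.default_rng(0).uniform(1, 2, 100))
        hist = speed_intensity_analysis(sm, [prof], "patch")
        assert hist.degenerate and np.isnan(hist.pearson_r)


class TestMembraneKymograph:
    def test_static_patch_is_horizontal_stripe(self):
        values = np.ones(100)
        values[30:45] = 3.0
        profiles = [synthetic_profile(values, frame=t) for t in range(10)]
        c = circle_contour(8.0)
        corrs = [register_contours(c, c) for _ in range(9)]
        kym = build_membrane_kymograph(profiles, corrs, "patch")
        assert kym.data.shape == (100, 10)
        assert np.all(kym.data[35, :] == 3.0)
        assert np.all(kym.data[10, :] == 1.0)

    def test_rotating_pattern_straightened_by_alignment(self):
        """A pattern rotating with the contour slants without alignment and
        becomes horizontal with it."""
        n, T, step = 100, 12, 3
        base = np.ones(n)
        base[20:35] = 3.0
        # material rotation: a fixed asymmetric outline whose point indices
        # (and the material-bound intensity pattern) roll by `step` per frame
        theta = 2 * np.pi * np.arange(n) / n
        r = 8.0 + 1.5 * np.cos(theta)
        pts0 = np.stack([12.8 + r * np.cos(theta), 12.8 + r * np.sin(theta)],
                        axis=1)
        contours = []
        profiles = []
        for t in range(T):
            contours.append(Contour(points=np.roll(pts0, step * t, axis=0),
                                    arc_spacing_um=0.5,
                                    centroid=np.array([12.8, 12.8])))
            profiles.append(synthetic_profile(np.roll(base, step * t), frame=t))
        corrs = [register_contours(a, b)
                 for a, b in zip(contours[:-1], contours[1:])]
        offsets = cumulative_offsets(corrs)
        assert [o % n for o in offsets] == [(step * t) % n for t in range(T)]
        aligned = build_membrane_kymograph(profiles, corrs, "patch")
        raw = build_membrane_kymograph(profiles, corrs, "patch", align=False)
        # aligned: material rows constant; unaligned: the stripe moves
        assert np.all(aligned.data[25, :] == 3.0)
        assert not np.all(raw.data[25, :] == 3.0)

    def test_columns_conserve_profile_content(self):
        rng = np.random.default_rng(2)
        profiles = [synthetic_profile(rng.uniform(1, 3, 100), frame=t)
                    for t in range(5)]
        theta = 2 * np.pi * np.arange(100) / 100
        contours = []
        for t in range(5):
            r = 8.0 + 1.0 * np.cos(3 * theta + 0.3 * t)
            pts = np.stack([12.8 + r * np.cos(theta), 12.8 + r * np.sin(theta)],
                           axis=1)
            contours.append(Contour(points=pts, arc_spacing_um=0.5,
                                    centroid=np.array([12.8, 12.8])))
        corrs = [register_contours(a, b)
                 for a, b in zip(contours[:-1], contours[1:])]
        kym = build_membrane_kymograph(profiles, corrs, "patch")
        for t in range(5):
            assert kym.data[:, t].sum() == pytest.approx(
                profiles[t].norm["patch"].sum())

    def test_truth_patch_lifetime_spans_kymograph_columns(self, static_movie):
        """A truth patch born at frame b and closed at frame c produces an
        elevated kymograph band over columns b..c (within one column)."""
        sm = static_movie
        kym = build_membrane_kymograph(
            [sm.profiles[t] for t in sm.good], sm.correspondences, "patch")
        from cupquant.synth import truth_index_set
        checked = 0
        for e in sm.truth.births(1):
            if e["origin"] != "de_novo":
                continue  # a split child's row is lit by its parent before birth
            b, last, closed = sm.truth.lineage_span(e["lineage"])
            if not closed or last - b < 8 or last >= sm.stack.n_frames - 1:
                continue
            pm = [p for p in sm.truth.patches[b]
                  if p.lineage_id == e["lineage"]][0]
            ctr = sm.truth.centroids_um[b]
            th = np.arctan2(sm.contours[b].points[:, 1] - ctr[1],
                            sm.contours[b].points[:, 0] - ctr[0])
            row = int(np.argmin(np.abs(
                np.mod(th - pm.theta_center + np.pi, 2 * np.pi) - np.pi)))
            # elevated through the lifetime (one column of slack at each end)
            assert np.all(kym.data[row, b + 1:last] > 1.5)
            # dark just outside the lifetime unless another patch covers the row
            for t_out in (b - 2, last + 2):
                if 0 <= t_out < sm.stack.n_frames and \
                        row not in truth_index_set(sm.truth, t_out,
                                                   sm.contours[t_out]):
                    assert kym.data[row, t_out] < 1.5
            checked += 1
        assert checked >= 1


class TestEdgeKymograph:
    def test_static_edge_constant_intensity(self, static_movie):
        sm = static_movie
        # line through a fixed membrane point of a long-lived patch
        e = next(e for e in sm.truth.births(0)
                 if sm.truth.lineage_span(e["lineage"])[1]
                 - sm.truth.lineage_span(e["lineage"])[0] >= 10)
        b, last, _ = sm.truth.lineage_span(e["lineage"])
        ring_theta = sm.synth_cfg.ring_width_um / sm.synth_cfg.cell_radius_um
        pts, dirs = [], []
        for t in range(b, last + 1):
            p = [p for p in sm.truth.patches[t]
                 if p.lineage_id == e["lineage"]][0]
            ang = wrap_angle(p.theta_start + p.width + 0.5 * ring_theta)
            xy = sm.truth.membrane_point(ang, t)
            pts.append(xy)
            dirs.append(sm.truth.centroids_um[t] - xy)
        kym = build_edge_kymograph(sm.stack, np.array(pts), np.array(dirs),
                                   4.0, "ring", frames=range(b, last + 1))
        assert kym.data.shape[1] == last - b + 1
        series = edge_mean_timeseries(kym, 0.5)
        # the flanking ring keeps the membrane-proximal signal above cytosol
        assert np.all(series > 1.2 * sm.synth_cfg.cyto_mean[1])

    def test_line_exiting_image_flagged_clipped(self, static_movie):
        sm = static_movie
        pts = np.array([[1.0, 1.0]] * 3)
        dirs = np.array([[-1.0, -1.0]] * 3)
        kym = build_edge_kymograph(sm.stack, pts, dirs, 5.0, "ring",
                                   frames=range(3))
        assert kym.clipped


class TestTrackPatches:
    def test_single_persistent_patch_is_one_de_novo_track(self):
        calls = [synthetic_call([(30, 15)], frame=t) for t in range(10)]
        ts = track_patches(calls, None)
        assert ts.n_tracks == 1
        tr = ts.tracks[0]
        assert tr.origin == "de_novo" and tr.end == "censored"
        assert (tr.first_frame, tr.last_frame) == (0, 9)

    def test_flicker_bridged_by_gap_tolerance(self):
        calls = []
        for t in range(10):
            ivs = [(30, 15)] if t % 2 == 0 else []
            calls.append(synthetic_call(ivs, frame=t))
        ts = track_patches(calls, None, gap_tolerance=1)
        assert ts.n_tracks == 1
        ts0 = track_patches(calls, None, gap_tolerance=0)
        assert ts0.n_tracks == 5

    def test_split_overlap_rule(self):
        calls = [synthetic_call([(30, 30)], frame=0),
                 synthetic_call([(30, 12), (48, 12)], frame=1),
                 synthetic_call([(30, 12), (48, 12)], frame=2)]
        ts = track_patches(calls, None)
        assert ts.n_tracks == 2
        origins = sorted(t.origin for t in ts.tracks)
        assert origins == ["de_novo", "split"]
        child = [t for t in ts.tracks if t.origin == "split"][0]
        assert child.parent is not None

    def test_noise_free_origins_classified_exactly(self, noise_free_movie):
        nf = noise_free_movie
        ts = nf.tracks()
        m = match_origins(nf.truth, ts, nf.contours)
        assert m["n_events"] > 0
        assert m["n_matched"] == m["n_events"]
        assert m["n_origin_correct"] == m["n_events"]

    def test_recovered_split_fraction_within_binomial_ci_of_truth(
            self, noise_free_movie):
        from scipy import stats
        nf = noise_free_movie
        summary = nf.tracks().summary()
        n = len(nf.truth.births())
        truth_frac = nf.truth.realized_split_fraction()
        lo = stats.binom.ppf(0.025, n, max(truth_frac, 1e-9)) / n
        hi = stats.binom.ppf(0.975, n, max(truth_frac, 1e-9)) / n
        assert lo <= summary["split_fraction"] <= hi

    def test_tracks_serialise_to_json(self, tmp_path):
        calls = [synthetic_call([(30, 15)], frame=t) for t in range(4)]
        ts = track_patches(calls, None)
        ts.to_json(tmp_path / "tracks.json")
        import json
        payload = json.loads((tmp_path / "tracks.json").read_text())
        assert payload["summary"]["n_tracks"] == 1
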