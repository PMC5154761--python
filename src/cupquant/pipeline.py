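"""End-to-end orchestration: segment → profile → call → measure → dynamics
→ report, with all artifacts persisted and a deterministic JSON report.

Every number in the report is computed from stage outputs that are also
written to disk, and identical config + seed produces a byte-identical
``report.json`` (the provenance block contains the config hash, the seed
and the package version — no timestamps).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .config import (
    PipelineConfig,
    config_hash,
    save_yaml,
)
from .dynamics import (
    build_membrane_kymograph,
    register_contours,
    speed_intensity_analysis,
    speed_map,
    track_patches,
)
from .edges import extract_edge_profiles, merge_edge_profile_sets
from .errors import (
    ComparisonError,
    CupquantError,
    EmptyProfileSet,
    PipelineError,
)
from .membrane import joint_histogram, membrane_profile, profiles_to_csv
from .patches import (
    call_patches,
    calls_to_csv,
    compare_groups,
    holm_correction,
    measure_center_edge,
)
from .segment import (
    contours_to_csv,
    cytosol_stats,
    extract_contour,
    segment_cell,
)
from .synth import load_movie, make_cell_movie, save_movie

logger = logging.getLogger("cupquant")


def _np_default(obj):
    """JSON encoder hook for numpy scalars."""
    if isinstance(obj, np.generic):
        return obj.item()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _ttest_vs_constant(values: np.ndarray, constant: float) -> dict:
    """Paired two-tailed t-test of per-patch values against a reference level."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        return {"statistic": float("nan"), "p_value": float("nan"),
                "n": int(values.size)}
    res = compare_groups(values, np.full(values.size, constant), paired=True)
    return {"statistic": res.statistic, "p_value": res.p_value,
            "n": int(values.size)}


@dataclasses.dataclass
class MovieAnalysis:
    """Per-frame stage outputs of one movie (None where a frame failed)."""

    stack: object
    masks: list
    contours: list
    cytos: list
    profiles: list
    calls: list  # aligned with ``good`` frames
    measurements: list
    good: list  # analysable frame indices
    failed_frames: list

    def call_for_frame(self, t: int):
        return self.calls[self.good.index(t)]


def analyse_movie(stack, cfg: PipelineConfig) -> MovieAnalysis:
    """Segment, profile, call and measure every frame of a movie.

    This is the per-frame core shared by :func:`run_pipeline`, the tests
    and the acceptance script; it performs no file I/O.
    """
    px = stack.pixel_size_um
    name_patch = stack.channel_names[cfg.patch_channel]
    name_ring = stack.channel_names[cfg.ring_channel]
    masks, contours, cytos, profiles = [], [], [], []
    failed_frames = []
    for t in range(stack.n_frames):
        try:
            cell = segment_cell(
                stack.pixels[t, cfg.patch_channel], pixel_size_um=px,
                smooth_sigma_um=cfg.smooth_sigma_um,
                threshold_method=cfg.threshold_method,
                min_area_px=cfg.min_area_px, frame_index=t)
            contour = extract_contour(
                cell, cfg.n_contour_points, pixel_size_um=px)
            cyto = cytosol_stats(
                stack.pixels[t], cell, cfg.erosion_margin_um,
                pixel_size_um=px)
            prof = membrane_profile(
                stack.pixels[t], contour, cyto, cfg.band_width_um,
                channel_names=stack.channel_names, pixel_size_um=px,
                mode=cfg.band_mode, cell=cell,
                band_inset_um=cfg.band_inset_um)
        except CupquantError as exc:
            logger.warning("frame %d failed: %s", t, exc)
            failed_frames.append({"frame": t, "stage": type(exc).__name__,
                                  "message": str(exc)})
            masks.append(None); contours.append(None)
            cytos.append(None); profiles.append(None)
            continue
        masks.append(cell); contours.append(contour)
        cytos.append(cyto); profiles.append(prof)

    good = [t for t in range(stack.n_frames) if profiles[t] is not None]
    calls = []
    measurements = []
    for t in good:
        call = call_patches(profiles[t], cytos[t], name_patch,
                            channel_index=cfg.patch_channel, k_sd=cfg.k_sd,
                            min_patch_points=cfg.min_patch_points)
        calls.append(call)
        measurements.extend(measure_center_edge(
            call, profiles[t], cytos[t], name_ring))
    return MovieAnalysis(
        stack=stack, masks=masks, contours=contours, cytos=cytos,
        profiles=profiles, calls=calls, measurements=measurements,
        good=good, failed_frames=failed_frames)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the report dict.

    Artifacts written to ``config.outdir``: movie + truth (generate mode),
    masks, contours, cytosol stats, profiles, calls, centre/edge table,
    edge profiles, speeds, kymographs, tracks, and ``report.json``.
    """
    cfg = config.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    save_yaml(cfg, out / "config.yaml")

    # ---- input -----------------------------------------------------------
    truth = None
    if cfg.generate:
        synth_cfg = cfg.synth.replace(seed=cfg.seed)
        stack, truth = make_cell_movie(synth_cfg)
        save_movie(stack, out / "movie.tif")
        truth.save_json(out / "truth.json")
    else:
        stack = load_movie(cfg.movie_path)
    px = stack.pixel_size_um
    n_frames = stack.n_frames
    ch_patch = cfg.patch_channel
    ch_ring = cfg.ring_channel
    name_patch = stack.channel_names[ch_patch]
    name_ring = stack.channel_names[ch_ring]

    ana = analyse_movie(stack, cfg)
    masks, contours = ana.masks, ana.contours
    cytos, profiles = ana.cytos, ana.profiles
    failed_frames = ana.failed_frames
    good = ana.good
    if len(good) < max(1, n_frames // 2):
        raise PipelineError(
            f"segmentation failed on {n_frames - len(good)}/{n_frames} frames "
            "(NoCellFound on more than half)")

    tifffile.imwrite(out / "masks.tif", np.stack(
        [(masks[t].mask if masks[t] else np.zeros(stack.pixels.shape[-2:], bool))
         for t in range(n_frames)]).astype(np.uint8))
    contours_to_csv([contours[t] for t in good], out / "contours.csv")
    pd.DataFrame([
        {"frame": t, "channel": name,
         "cyto_mean": cytos[t].mean[ci], "cyto_sd": cytos[t].sd[ci],
         "n_pixels": cytos[t].n_pixels}
        for t in good for ci, name in enumerate(stack.channel_names)
    ]).to_csv(out / "cytosol.csv", index=False)
    profiles_to_csv([profiles[t] for t in good], out / "profiles.csv")

    # ---- patch calling + centre/edge -------------------------------------
    calls = ana.calls
    measurements = ana.measurements
    calls_to_csv(calls, out / "calls.csv")
    pd.DataFrame([dataclasses.asdict(m) for m in measurements]).to_csv(
        out / "center_edge.csv", index=False)

    sizes = [iv.arc_length_um for c in calls for iv in c.intervals]
    intensities = [iv.mean_norm_intensity for c in calls for iv in c.intervals]
    counts = [c.n_patches for c in calls]

    # ---- edge profiles / sharpness ---------------------------------------
    edge_sets = []
    for t, call in zip(good, calls):
        try:
            edge_sets.append(extract_edge_profiles(
                profiles[t], call, cfg.half_width_points))
        except EmptyProfileSet:
            pass
    edge_set = None
    if edge_sets:
        edge_set = merge_edge_profile_sets(edge_sets)
        from .edges import edge_profiles_to_csv
        edge_profiles_to_csv(edge_set, out / "edge_profiles.csv")

    # ---- dynamics ---------------------------------------------------------
    contiguous = _longest_contiguous(good)
    speeds = None
    correlations = {}
    kym = None
    track_sizes: list = []
    track_intensities: list = []
    track_summary = {"n_tracks": 0, "n_births": 0, "n_split": 0,
                     "n_de_novo": 0, "split_fraction": float("nan")}
    if len(contiguous) >= 2:
        seq = contiguous
        corrs = [register_contours(contours[a], contours[b])
                 for a, b in zip(seq[:-1], seq[1:])]
        speeds = speed_map([contours[t] for t in seq], corrs,
                           stack.frame_interval_s)
        pd.DataFrame(speeds.speeds).to_csv(out / "speeds.csv", index=False)
        seq_profiles = [profiles[t] for t in seq]
        for name in (name_patch, name_ring):
            kym_c = build_membrane_kymograph(seq_profiles, corrs, name)
            np.savetxt(out / f"kymograph_{name}.csv", kym_c.data, delimiter=",")
            tifffile.imwrite(out / f"kymograph_{name}.tif",
                             kym_c.data.astype(np.float32))
            if name == name_patch:
                kym = kym_c
        sv_hist = speed_intensity_analysis(speeds, seq_profiles, name_ring)
        correlations["speed_vs_ring"] = {
            "pearson_r": sv_hist.pearson_r, "spearman_rho": sv_hist.spearman_rho,
            "n": sv_hist.n_points, "degenerate": sv_hist.degenerate}
        seq_calls = [calls[good.index(t)] for t in seq]
        tracks = track_patches(seq_calls, corrs, gap_tolerance=cfg.gap_tolerance)
        tracks.to_json(out / "tracks.json")
        track_summary = tracks.summary()
        # per-lineage aggregates: repeated sightings of one patch are not
        # independent observations, so between-condition tests use these
        lookup = {}
        for call, t in zip(seq_calls, seq):
            for iv in call.intervals:
                lookup[(t, iv.start_idx)] = iv
        for tr in tracks.tracks:
            ivs = [lookup[(seq[col], s)]
                   for col, (s, _length) in tr.intervals.items()
                   if (seq[col], s) in lookup]
            if not ivs:
                continue
            track_sizes.append(float(np.mean([iv.arc_length_um for iv in ivs])))
            track_intensities.append(
                float(np.mean([iv.mean_norm_intensity for iv in ivs])))

    # ---- pooled channel correlation --------------------------------------
    pooled_patch = np.concatenate([profiles[t].norm[name_patch] for t in good])
    pooled_ring = np.concatenate([profiles[t].norm[name_ring] for t in good])
    ch_hist = joint_histogram(pooled_patch, pooled_ring)
    np.savetxt(out / "joint_histogram.csv", ch_hist.counts, delimiter=",")
    correlations["patch_vs_ring"] = {
        "pearson_r": ch_hist.pearson_r, "spearman_rho": ch_hist.spearman_rho,
        "n": ch_hist.n_points, "degenerate": ch_hist.degenerate}

    # ---- statistics -------------------------------------------------------
    center_vals = np.array([m.i_center for m in measurements])
    edge_vals = np.array([m.i_edge for m in measurements])
    center_edge = {
        "n_measurements": len(measurements),
        "center_mean": float(center_vals.mean()) if len(measurements) else float("nan"),
        "center_sd": float(center_vals.std(ddof=1)) if len(measurements) > 1 else float("nan"),
        "edge_mean": float(edge_vals.mean()) if len(measurements) else float("nan"),
        "edge_sd": float(edge_vals.std(ddof=1)) if len(measurements) > 1 else float("nan"),
        "cytosol_level": 1.0,
        "t_center_vs_cytosol": _ttest_vs_constant(center_vals, 1.0),
        "t_edge_vs_cytosol": _ttest_vs_constant(edge_vals, 1.0),
        "measurement_channel": name_ring,
    }

    report = {
        "provenance": {
            "config_hash": config_hash(cfg),
            "seed": cfg.seed,
            "version": __version__,
            "n_frames": n_frames,
            "n_frames_analysed": len(good),
            "failed_frames": failed_frames,
        },
        "threshold_rule": f"mean + {cfg.k_sd:g}*SD",
        "calling_channel": name_patch,
        "patch_stats": {
            "n_patches": len(sizes),
            "mean_size_um": float(np.mean(sizes)) if sizes else float("nan"),
            "sd_size_um": float(np.std(sizes, ddof=1)) if len(sizes) > 1 else float("nan"),
            "mean_norm_intensity": float(np.mean(intensities)) if intensities else float("nan"),
            "mean_count_per_frame": float(np.mean(counts)) if counts else 0.0,
            "sizes_um": [float(s) for s in sizes],
            "intensities": [float(v) for v in intensities],
            "counts_per_frame": [int(c) for c in counts],
            "track_sizes_um": track_sizes,
            "track_intensities": track_intensities,
        },
        "center_edge": center_edge,
        "correlations": correlations,
        "sharpness": {
            "n_edges": edge_set.n_edges if edge_set else 0,
            "n_skipped": edge_set.n_skipped if edge_set else 0,
            "mean_d90_10_um": edge_set.mean_d90_10_um if edge_set else float("nan"),
        },
        "tracking": track_summary,
        "speed": {
            "mean_abs_um_s": (float(np.mean(np.abs(speeds.speeds)))
                              if speeds is not None else float("nan")),
            "rms_um_s": (float(np.sqrt(np.mean(speeds.speeds ** 2)))
                         if speeds is not None else float("nan")),
        },
    }
    (out / "report.json").write_text(
        json.dumps(report, sort_keys=True, indent=1, default=_np_default))

    if cfg.figures:
        from .plotting import save_report_figures
        save_report_figures(out, kym, ch_hist)
    return report


def _longest_contiguous(frames: list) -> list:
    """Longest run of consecutive frame indices (dynamics needs continuity)."""
    if not frames:
        return []
    best, cur = [frames[0]], [frames[0]]
    for a, b in zip(frames[:-1], frames[1:]):
        cur = cur + [b] if b == a + 1 else [b]
        if len(cur) > len(best):
            best = cur
    return best


# ---------------------------------------------------------------------------
# between-condition comparison
# ---------------------------------------------------------------------------

# sizes and intensities are compared per tracked lineage: per-frame
# re-sightings of one patch are not independent observations
_COMPARED_METRICS = (
    ("patch_size_um", "track_sizes_um"),
    ("patches_per_frame", "counts_per_frame"),
    ("patch_norm_intensity", "track_intensities"),
)


def compare_conditions(report_a: dict, report_b: dict) -> dict:
    """Unpaired two-tailed tests between two runs' patch statistics.

    Compares per-patch sizes, per-frame patch counts and per-patch mean
    normalised intensities; Holm correction is applied across the family.
    """
    results = {}
    raw_p = []
    keys = []
    for metric, field_name in _COMPARED_METRICS:
        try:
            a = report_a["patch_stats"][field_name]
            b = report_b["patch_stats"][field_name]
        except KeyError as exc:
            raise ComparisonError(f"metric {metric} missing from report") from exc
        if len(a) < 2 or len(b) < 2:
            results[metric] = {"error": "insufficient data",
                               "n_a": len(a), "n_b": len(b)}
            continue
        res = compare_groups(a, b, paired=False)
        results[metric] = {
            "statistic": res.statistic, "p_value": res.p_value,
            "test_name": res.test_name, "n_a": res.n_a, "n_b": res.n_b,
            "mean_a": res.mean_a, "mean_b": res.mean_b,
            "cohen_d": res.cohen_d, "degenerate": res.degenerate,
        }
        raw_p.append(res.p_value)
        keys.append(metric)
    if len(raw_p) > 2:
        adjusted = holm_correction(raw_p)
        for k, p_adj in zip(keys, adjusted):
            results[k]["p_holm"] = p_adj
    return results
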