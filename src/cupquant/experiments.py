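"""Canonical synthetic experiments and their summary statistics.

Each function builds (or accepts) a fully analysed synthetic movie under
the package's standard study conditions and reduces it to the headline
quantities of the corresponding analysis: patch-recovery overlap,
centre/edge enrichment, channel anti-correlation, the membrane-speed
oracle, edge sharpness, patch-size discrimination, origin classification,
and lifetime kymographs.  The test suite and the reproduction script both
run these, so the numbers they report come from one code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import erf

from .config import PipelineConfig, SynthConfig
from .dynamics import (
    build_edge_kymograph,
    build_membrane_kymograph,
    edge_mean_timeseries,
    local_speed,
    match_origins,
    register_contours,
    speed_map,
    track_patches,
)
from .edges import extract_edge_profiles, merge_edge_profile_sets
from .errors import EmptyProfileSet
from .membrane import MembraneProfile, joint_histogram
from .patches import call_patches, compare_groups
from .pipeline import analyse_movie, run_pipeline
from .segment import CytosolStats
from .synth import (
    make_cell_movie,
    make_radius_ramp_movie,
    sample_patch_widths_um,
    truth_index_set,
    wrap_angle,
)


# ---------------------------------------------------------------------------
# canonical study conditions
# ---------------------------------------------------------------------------


def default_config(seed: int) -> SynthConfig:
    """The reference imaging conditions: noisy, motile cell, 50 frames."""
    return SynthConfig(seed=seed)


def static_config(seed: int, n_frames: int = 60) -> SynthConfig:
    """Motion-suppressed analogue (no drift, no protrusions)."""
    return SynthConfig(seed=seed, n_frames=n_frames, drift_speed_um_s=0.0,
                       protrusion_amp_um=0.0, patch_birth_rate=0.2,
                       patch_lifetime_frames_mean=18)


def noise_free_config(seed: int, n_frames: int = 100) -> SynthConfig:
    """Noise-free movie with births, splits and closures."""
    return SynthConfig(seed=seed, n_frames=n_frames, noise_poisson_scale=0,
                       noise_gauss_sd=0, patch_birth_rate=0.15,
                       patch_lifetime_frames_mean=16, patch_width_deg_mean=70,
                       initial_patches=2, drift_speed_um_s=0.02,
                       split_probability=0.6)


def origin_movie_config(seed: int, n_frames: int = 260) -> SynthConfig:
    """Noisy movie accumulating >= 50 patch births for origin statistics."""
    return SynthConfig(seed=seed, n_frames=n_frames, patch_birth_rate=0.3,
                       patch_lifetime_frames_mean=14, patch_width_deg_mean=70,
                       initial_patches=2, drift_speed_um_s=0.005,
                       split_probability=0.6)


def sharpness_config(seed: int, motile: bool, n_frames: int = 80) -> SynthConfig:
    if motile:
        return SynthConfig(seed=seed, n_frames=n_frames, drift_speed_um_s=0.03)
    return SynthConfig(seed=seed, n_frames=n_frames, drift_speed_um_s=0.0,
                       protrusion_amp_um=0.0)


# ---------------------------------------------------------------------------
# analysed-movie bundle
# ---------------------------------------------------------------------------


@dataclass
class Bundle:
    """A generated movie plus every per-frame stage output."""

    synth_cfg: SynthConfig
    pipe_cfg: PipelineConfig
    stack: object
    truth: object
    ana: object
    correspondences: list = field(default_factory=list)

    # convenience views -----------------------------------------------------
    @property
    def good(self):
        return self.ana.good

    @property
    def contours(self):
        return self.ana.contours

    @property
    def profiles(self):
        return self.ana.profiles

    @property
    def cytos(self):
        return self.ana.cytos

    @property
    def calls(self):
        return self.ana.calls

    @property
    def measurements(self):
        return self.ana.measurements

    @property
    def speeds(self):
        return speed_map([self.contours[t] for t in self.good],
                         self.correspondences,
                         self.stack.frame_interval_s)

    def tracks(self, gap_tolerance: int = 1):
        return track_patches(self.calls, self.correspondences,
                             gap_tolerance=gap_tolerance)

    def pooled_norm(self, channel: str) -> np.ndarray:
        return np.concatenate([self.profiles[t].norm[channel]
                               for t in self.good])


def build_bundle(synth_cfg: SynthConfig,
                 pipe_cfg: PipelineConfig | None = None) -> Bundle:
    pipe_cfg = pipe_cfg or PipelineConfig()
    stack, truth = make_cell_movie(synth_cfg)
    ana = analyse_movie(stack, pipe_cfg)
    corrs = [register_contours(ana.contours[a], ana.contours[b])
             for a, b in zip(ana.good[:-1], ana.good[1:])]
    return Bundle(synth_cfg=synth_cfg, pipe_cfg=pipe_cfg, stack=stack,
                  truth=truth, ana=ana, correspondences=corrs)


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------


def patch_recovery(bundle: Bundle) -> dict:
    """Mean per-frame Jaccard overlap between called and truth point sets."""
    jac = []
    for call, t in zip(bundle.calls, bundle.good):
        called = call.called_index_set()
        tru = truth_index_set(bundle.truth, t, bundle.contours[t])
        if called or tru:
            jac.append(len(called & tru) / len(called | tru))
    return {"mean_jaccard": float(np.mean(jac)), "n_frames": len(jac)}


def center_edge_stats(*bundles: Bundle) -> dict:
    """Second-channel enrichment at patch edges vs centres, against cytosol.

    Measurements are aggregated per tracked patch before testing: the same
    patch re-sighted on consecutive frames is one observation, not many —
    repeated sightings share position-specific measurement quirks, and
    treating them as independent would make the tests anticonservative.
    Several movies (cells) may be pooled, as the per-patch quantities are
    already cytosol-normalised.
    """
    centers, edges = [], []
    n_sightings = 0
    for bundle in bundles:
        by_key = {(m.frame_index, m.patch_start_idx): m
                  for m in bundle.measurements}
        n_sightings += len(bundle.measurements)
        for tr in bundle.tracks().tracks:
            ms = [by_key[(bundle.good[col], s)]
                  for col, (s, _length) in tr.intervals.items()
                  if (bundle.good[col], s) in by_key]
            if not ms:
                continue
            centers.append(np.mean([m.i_center for m in ms]))
            edges.append(np.mean([m.i_edge for m in ms]))
    centers = np.asarray(centers)
    edges = np.asarray(edges)
    t_edge = compare_groups(edges, np.ones_like(edges), paired=True)
    t_center = compare_groups(centers, np.ones_like(centers), paired=True)
    return {
        "n_patches": len(centers),
        "n_sightings": n_sightings,
        "edge_mean": float(edges.mean()),
        "edge_p": t_edge.p_value,
        "center_mean": float(centers.mean()),
        "center_p": t_center.p_value,
        "center_rel_dev": float(abs(centers.mean() - 1.0)),
    }


def channel_correlation(bundle: Bundle) -> dict:
    """Pooled membrane-point Pearson r between the two channels."""
    hist = joint_histogram(bundle.pooled_norm("patch"),
                           bundle.pooled_norm("ring"))
    return {"pearson_r": hist.pearson_r, "n_points": hist.n_points}


def speed_oracle(seed: int, rate_um_s: float = 0.1) -> dict:
    """Signed-speed estimator on an isotropically expanding and a static cell."""
    base = SynthConfig(seed=seed, n_frames=8, noise_poisson_scale=0,
                       noise_gauss_sd=0, drift_speed_um_s=0.0,
                       protrusion_amp_um=0.0)
    stack, _ = make_radius_ramp_movie(base, rate_um_s)
    pipe = PipelineConfig()
    ana = analyse_movie(stack, pipe)
    ramp_speeds = []
    for a, b in zip(ana.good[:-1], ana.good[1:]):
        corr = register_contours(ana.contours[a], ana.contours[b])
        ramp_speeds.append(local_speed(corr, ana.contours[a],
                                       stack.frame_interval_s))
    static_stack, _ = make_cell_movie(base.replace(
        patch_birth_rate=0.0, initial_patches=0))
    ana_s = analyse_movie(static_stack, pipe)
    static_speeds = []
    for a, b in zip(ana_s.good[:-1], ana_s.good[1:]):
        corr = register_contours(ana_s.contours[a], ana_s.contours[b])
        static_speeds.append(local_speed(corr, ana_s.contours[a], 1.0))
    return {
        "expansion_speed_um_s": float(np.mean(ramp_speeds)),
        "expansion_target_um_s": rate_um_s,
        "static_rms_um_s": float(np.sqrt(np.mean(np.square(static_speeds)))),
        "n_points": int(np.size(ramp_speeds)),
    }


def erf_sharpness(sigma_um: float = 0.8, n: int = 256,
                  spacing_um: float = 0.25, contrast: float = 2.0) -> dict:
    """d90-10 of Gaussian-blurred patch edges vs the analytic 2.563 sigma."""
    pos = np.arange(n) * spacing_um
    vals = 1 + 0.5 * contrast * (erf((pos - 20) / (sigma_um * np.sqrt(2)))
                                 - erf((pos - 40) / (sigma_um * np.sqrt(2))))
    prof = MembraneProfile(
        raw={"patch": vals}, norm={"patch": vals},
        arc_positions_um=pos, arc_spacing_um=spacing_um, band_width_um=0.5)
    cyto = CytosolStats(mean=np.array([1.0]), sd=np.array([0.5 * contrast]),
                        n_pixels=1000, erosion_margin_um=1.0)
    call = call_patches(prof, cyto, "patch", channel_index=0)
    es = extract_edge_profiles(prof, call, half_width_points=14)
    return {
        "d90_10_um": es.mean_d90_10_um,
        "analytic_um": 2.563 * sigma_um,
        "n_edges": es.n_edges,
    }


def pooled_sharpness(bundle: Bundle, half_width_points: int = 8) -> dict:
    sets = []
    for t, call in zip(bundle.good, bundle.calls):
        try:
            sets.append(extract_edge_profiles(bundle.profiles[t], call,
                                              half_width_points))
        except EmptyProfileSet:
            continue
    merged = merge_edge_profile_sets(sets)
    return {"mean_d90_10_um": merged.mean_d90_10_um, "n_edges": merged.n_edges}


def motion_sharpness(seed: int) -> dict:
    """Edge sharpness of a motile vs a motion-suppressed cell, equal blur."""
    motile = pooled_sharpness(build_bundle(sharpness_config(seed, motile=True)))
    static = pooled_sharpness(build_bundle(sharpness_config(seed, motile=False)))
    rel = abs(motile["mean_d90_10_um"] - static["mean_d90_10_um"]) \
        / static["mean_d90_10_um"]
    return {"motile_um": motile["mean_d90_10_um"],
            "static_um": static["mean_d90_10_um"],
            "rel_diff": float(rel),
            "n_edges": motile["n_edges"] + static["n_edges"]}


def size_detection(seed: int, n_rep: int = 100, n_null: int = 1000) -> dict:
    """Power and calibration of the patch-size comparison.

    Truth widths are drawn from the generator's width distribution for two
    conditions with 1.0 vs 2.0 µm mean arc width (SD 0.3 µm), n = 30
    patches per group; the null calibration redraws both groups from the
    same 1.0 µm condition.
    """
    radius = 8.0
    deg = 180.0 / np.pi / radius  # µm -> degrees of arc at this radius
    cfg_a = SynthConfig(seed=seed, patch_width_deg_mean=1.0 * deg,
                        patch_width_deg_sd=0.3 * deg, cell_radius_um=radius)
    cfg_b = cfg_a.replace(patch_width_deg_mean=2.0 * deg)
    rng = np.random.default_rng([seed, 404])
    hits = 0
    for _ in range(n_rep):
        a = sample_patch_widths_um(cfg_a, 30, rng)
        b = sample_patch_widths_um(cfg_b, 30, rng)
        hits += compare_groups(a, b).p_value < 0.01
    null_p = []
    for _ in range(n_null):
        a = sample_patch_widths_um(cfg_a, 30, rng)
        b = sample_patch_widths_um(cfg_a, 30, rng)
        null_p.append(compare_groups(a, b).p_value)
    ks = stats.kstest(null_p, "uniform")
    return {
        "power": hits / n_rep,
        "n_replicates": n_rep,
        "null_ks_p": float(ks.pvalue),
        "n_null": n_null,
    }


def origin_recovery(bundle: Bundle) -> dict:
    """Recovered vs realised split fraction, with the exact binomial CI."""
    summary = bundle.tracks().summary()
    n = len(bundle.truth.births())
    truth_frac = bundle.truth.realized_split_fraction()
    p = max(min(truth_frac, 1.0), 1e-9)
    lo = float(stats.binom.ppf(0.025, n, p)) / n
    hi = float(stats.binom.ppf(0.975, n, p)) / n
    return {
        "recovered_split_fraction": summary["split_fraction"],
        "truth_split_fraction": truth_frac,
        "n_births": n,
        "ci_low": lo,
        "ci_high": hi,
        "within_ci": bool(lo <= summary["split_fraction"] <= hi),
    }


def origin_exactness(bundle: Bundle) -> dict:
    """Event-by-event origin classification on a noise-free movie."""
    m = match_origins(bundle.truth, bundle.tracks(), bundle.contours)
    frac = (m["n_origin_correct"] / m["n_events"]) if m["n_events"] else float("nan")
    return {**m, "fraction_correct": frac}


def _isolated_closed_lineages(bundle: Bundle, min_life: int = 8):
    """De novo lineages that close within the movie and whose chosen edge's
    flanking ring segment never touches another patch (rings are suppressed
    inside patches, so an abutting neighbour would darken the edge signal)."""
    truth = bundle.truth
    cfg = bundle.synth_cfg
    ring_theta = cfg.ring_width_um / cfg.cell_radius_um
    split_parents = {ev["parent"] for ev in truth.events
                     if ev["type"] == "split"}
    out = []
    for e in truth.births(1):
        if e["origin"] != "de_novo" or e["lineage"] in split_parents:
            continue  # splitting re-centres the parent interval mid-life
        b, last, closed = truth.lineage_span(e["lineage"])
        if not closed or last - b < min_life or last >= truth.n_frames - 1:
            continue
        for side in ("start", "end"):
            clean = True
            for t in range(b, last + 1):
                p = next(p for p in truth.patches[t]
                         if p.lineage_id == e["lineage"])
                if side == "start":
                    seg = (wrap_angle(p.theta_start - ring_theta), ring_theta)
                else:
                    seg = (wrap_angle(p.theta_start + p.width), ring_theta)
                for q in truth.patches[t]:
                    if q.lineage_id == e["lineage"]:
                        continue
                    qs = np.linspace(seg[0], seg[0] + seg[1], 9)
                    if q.contains(qs).any():
                        clean = False
                        break
                if not clean:
                    break
            if clean:
                out.append((e["lineage"], b, last, side))
                break
    return out


def kymograph_lifetime(bundle: Bundle, elevation: float = 1.5) -> dict:
    """Kymograph span of truth patch lifetimes, and edge-line signal.

    For every isolated de novo lineage: the membrane-kymograph row through
    the patch centre must be elevated from birth to closure (within one
    column at each end), and the ring-channel line scan through the tracked
    patch edge must stay above cytosol for the full span.
    """
    kym = build_membrane_kymograph(
        [bundle.profiles[t] for t in bundle.good],
        bundle.correspondences, "patch")
    truth = bundle.truth
    cfg = bundle.synth_cfg
    ring_theta = cfg.ring_width_um / cfg.cell_radius_um
    ring_ci = bundle.stack.channel_index("ring")
    cyto_ring = float(np.mean([bundle.cytos[t].mean[ring_ci]
                               for t in bundle.good]))
    span_errors = []
    edge_ratios = []
    for lid, b, last, side in _isolated_closed_lineages(bundle):
        p0 = next(p for p in truth.patches[b] if p.lineage_id == lid)
        ctr = truth.centroids_um[b]
        th = np.arctan2(bundle.contours[b].points[:, 1] - ctr[1],
                        bundle.contours[b].points[:, 0] - ctr[0])
        row = int(np.argmin(np.abs(
            np.mod(th - p0.theta_center + np.pi, 2 * np.pi) - np.pi)))
        vals = kym.data[row, :]
        inside = np.flatnonzero(vals > elevation)
        inside = inside[(inside >= b - 1) & (inside <= last + 1)]
        if inside.size == 0:
            span_errors.append(float(last - b))
        else:
            span_errors.append(float(max(abs(int(inside.min()) - b),
                                         abs(int(inside.max()) - last))))
        # ring-channel line scan through the tracked edge
        pts, dirs = [], []
        for t in range(b, last + 1):
            p = next(p for p in truth.patches[t] if p.lineage_id == lid)
            ang = (wrap_angle(p.theta_start - 0.5 * ring_theta)
                   if side == "start"
                   else wrap_angle(p.theta_start + p.width + 0.5 * ring_theta))
            xy = truth.membrane_point(ang, t)
            pts.append(xy)
            dirs.append(truth.centroids_um[t] - xy)
        ek = build_edge_kymograph(bundle.stack, np.array(pts), np.array(dirs),
                                  4.0, "ring", frames=range(b, last + 1))
        series = edge_mean_timeseries(ek, 0.5)
        edge_ratios.append(float(series.min() / cyto_ring))
    return {
        "n_events": len(span_errors),
        "max_span_error_frames": float(np.max(span_errors)) if span_errors else float("nan"),
        "min_edge_over_cytosol": float(np.min(edge_ratios)) if edge_ratios else float("nan"),
    }


def determinism(seed: int, outdir) -> dict:
    """Byte-identity of report.json across two runs of the same config."""
    from pathlib import Path
    outdir = Path(outdir)
    cfg = SynthConfig(seed=seed, n_frames=12, image_size_px=(192, 192),
                      cell_radius_um=6.0, drift_speed_um_s=0.02)
    blobs = []
    for sub in ("a", "b"):
        pipe = PipelineConfig(synth=cfg, seed=seed, outdir=str(outdir / sub))
        run_pipeline(pipe)
        blobs.append((outdir / sub / "report.json").read_bytes())
    return {"identical": blobs[0] == blobs[1],
            "n_bytes": len(blobs[0])}
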