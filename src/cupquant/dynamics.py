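"""Contour correspondence, local membrane speed, kymographs, patch tracking.

Frame-to-frame correspondence is a rigid circular index offset (chosen to
minimise summed squared point distances) followed by a nearest-point
refinement against the next contour's polyline.  Signed normal speed is the
refined displacement projected on the outward normal, positive outward
(protrusion).  The membrane kymograph aligns rows using only the cumulative
rigid offsets, so each column is a row-permutation of that frame's profile.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import InsufficientData, TrackingLost
from .membrane import JointHistogram, MembraneProfile, joint_histogram
from .patches import PatchCall
from .segment import Contour
from .synth import FrameStack

_DENSIFY = 8  # sub-samples per contour segment for nearest-point refinement


@dataclass
class Correspondence:
    """Mapping of contour points from frame t to frame t+1."""

    offset: int  # rigid circular index offset
    mapping: np.ndarray  # (N,) index into the next contour
    displacement: np.ndarray  # (N, 2) µm, refined per point

    @property
    def n_points(self) -> int:
        return self.mapping.size


def register_contours(c_t: Contour, c_next: Contour) -> Correspondence:
    """Rigid circular offset + nearest-point refinement; deterministic."""
    if c_t.n_points != c_next.n_points:
        raise InsufficientData("contours must have equal point counts")
    mean_radius = float(np.mean(np.linalg.norm(
        c_t.points - c_t.centroid[None, :], axis=1)))
    jump = float(np.linalg.norm(c_next.centroid - c_t.centroid))
    if jump > mean_radius:
        raise TrackingLost(
            f"centroid jump {jump:.2f} um exceeds cell radius {mean_radius:.2f} um")
    n = c_t.n_points
    p0 = c_t.points
    p1 = c_next.points
    costs = np.empty(n)
    for k in range(n):
        d = p0 - np.roll(p1, -k, axis=0)
        costs[k] = np.einsum("ij,ij->", d, d)
    offset = int(np.argmin(costs))
    # refine: nearest point on the next contour's polyline
    seg_next = np.roll(p1, -1, axis=0) - p1
    fracs = np.arange(_DENSIFY) / _DENSIFY
    dense = (p1[:, None, :] + fracs[None, :, None] * seg_next[:, None, :]
             ).reshape(-1, 2)
    tree = cKDTree(dense)
    _, nearest = tree.query(p0)
    displacement = dense[nearest] - p0
    mapping = np.round(nearest / _DENSIFY).astype(int) % n
    return Correspondence(offset=offset, mapping=mapping,
                          displacement=displacement)


@dataclass
class SpeedMap:
    """Signed normal speeds (µm/s), one row per frame pair, positive outward."""

    speeds: np.ndarray  # (T-1, N); speed of pair t→t+1 is assigned to frame t
    frame_interval_s: float

    @property
    def n_pairs(self) -> int:
        return self.speeds.shape[0]


def local_speed(
    corr: Correspondence, c_t: Contour, frame_interval_s: float
) -> np.ndarray:
    """Signed normal speed per point for one frame pair (µm/s)."""
    normals = c_t.normals()
    return np.einsum("ij,ij->i", corr.displacement, normals) / frame_interval_s


def speed_map(
    contours: list[Contour],
    correspondences: list[Correspondence],
    frame_interval_s: float,
) -> SpeedMap:
    rows = [
        local_speed(corr, c, frame_interval_s)
        for corr, c in zip(correspondences, contours[:-1])
    ]
    return SpeedMap(speeds=np.stack(rows), frame_interval_s=frame_interval_s)


def speed_intensity_analysis(
    speeds: SpeedMap,
    profiles: list[MembraneProfile],
    channel: str,
    bins: int = 40,
) -> JointHistogram:
    """Pooled joint distribution of per-point speed vs normalised intensity.

    Speed of pair t→t+1 is paired with the intensity of frame t.  Constant
    speed (e.g. a static movie) leaves the correlation flagged undefined.
    """
    v = speeds.speeds.ravel()
    i = np.concatenate([profiles[t].norm[channel]
                        for t in range(speeds.n_pairs)])
    return joint_histogram(v, i, bins=bins)


@dataclass
class Kymograph:
    """Position × time intensity matrix with axis calibration."""

    data: np.ndarray  # (rows, frames)
    row_spacing_um: float
    frame_interval_s: float
    offsets: list = field(default_factory=list)  # cumulative row offset per frame
    kind: str = "membrane"  # membrane | edge_line
    closure_frame: int | None = None
    clipped: bool = False

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]


def cumulative_offsets(correspondences: list[Correspondence]) -> list[int]:
    """Cumulative rigid offset K_t: material row r is index (r+K_t) in frame t."""
    out = [0]
    for corr in correspondences:
        out.append(out[-1] + corr.offset)
    return out


def build_membrane_kymograph(
    profiles: list[MembraneProfile],
    correspondences: list[Correspondence] | None,
    channel: str,
    align: bool = True,
) -> Kymograph:
    """Column t = frame t's profile, row-aligned by cumulative rigid offsets."""
    if len(profiles) < 2:
        raise InsufficientData("need at least 2 frames for a kymograph")
    n = profiles[0].n_points
    if align and correspondences is not None:
        offs = cumulative_offsets(correspondences)
    else:
        offs = [0] * len(profiles)
    cols = []
    for t, p in enumerate(profiles):
        idx = (np.arange(n) + offs[t]) % n
        cols.append(p.norm[channel][idx])
    return Kymograph(
        data=np.stack(cols, axis=1),
        row_spacing_um=profiles[0].arc_spacing_um,
        frame_interval_s=float("nan"),
        offsets=offs,
        kind="membrane",
    )


def build_edge_kymograph(
    stack: FrameStack,
    edge_points_um: np.ndarray,
    inward_dirs: np.ndarray,
    line_length_um: float,
    channel: str | int,
    frames: range | None = None,
    closure_frame: int | None = None,
    samples_per_um: float = 10.0,
) -> Kymograph:
    """Line-scan kymograph through a tracked patch-edge point.

    Per frame, intensity is sampled along a line starting at the edge point
    and extending ``line_length_um`` along ``inward_dirs`` (towards the
    cytosol); the columns are concatenated.  Lines exiting the image are
    clipped (values repeat the border) and flagged.
    """
    ci = stack.channel_index(channel) if isinstance(channel, str) else channel
    frames = frames if frames is not None else range(stack.n_frames)
    n_s = max(2, int(round(line_length_um * samples_per_um)))
    s = np.linspace(0.0, line_length_um, n_s)
    px = stack.pixel_size_um
    cols = []
    clipped = False
    for j, t in enumerate(frames):
        p = np.asarray(edge_points_um[j], dtype=float)
        d = np.asarray(inward_dirs[j], dtype=float)
        d = d / max(np.linalg.norm(d), 1e-12)
        pos = p[None, :] + s[:, None] * d[None, :]
        rows_px = pos[:, 1] / px
        cols_px = pos[:, 0] / px
        h, w = stack.pixels.shape[-2:]
        if (rows_px.min() < 0 or cols_px.min() < 0
                or rows_px.max() > h - 1 or cols_px.max() > w - 1):
            clipped = True
        cols.append(ndimage.map_coordinates(
            np.asarray(stack.pixels[t, ci], dtype=float),
            [rows_px, cols_px], order=1, mode="nearest"))
    return Kymograph(
        data=np.stack(cols, axis=1),
        row_spacing_um=line_length_um / (n_s - 1),
        frame_interval_s=stack.frame_interval_s,
        kind="edge_line",
        closure_frame=closure_frame,
        clipped=clipped,
    )


def edge_mean_timeseries(kym: Kymograph, depth_um: float) -> np.ndarray:
    """Per-frame mean of the membrane-proximal ``depth_um`` of an edge line."""
    k = max(1, int(round(depth_um / kym.row_spacing_um)))
    return kym.data[:k, :].mean(axis=0)


# ---------------------------------------------------------------------------
# patch tracking and origin classification
# ---------------------------------------------------------------------------


@dataclass
class Track:
    lineage_id: int
    origin: str  # "de_novo" | "split"
    first_frame: int
    last_frame: int
    intervals: dict  # frame → (start_idx, length) in that frame's indexing
    end: str = "censored"  # closed | censored
    parent: int | None = None


@dataclass
class PatchTrackSet:
    tracks: list
    gap_tolerance: int

    @property
    def n_tracks(self) -> int:
        return len(self.tracks)

    def summary(self, min_birth_frame: int = 1) -> dict:
        """Origin statistics over tracks born at/after ``min_birth_frame``.

        Frame-0 tracks are patches already present when the movie starts;
        their origin is not observable, so they are excluded by default.
        """
        births = [t for t in self.tracks if t.first_frame >= min_birth_frame]
        n_split = sum(t.origin == "split" for t in births)
        n_de_novo = sum(t.origin == "de_novo" for t in births)
        total = n_split + n_de_novo
        return {
            "n_tracks": self.n_tracks,
            "n_births": total,
            "n_split": n_split,
            "n_de_novo": n_de_novo,
            "split_fraction": (n_split / total) if total else float("nan"),
        }

    def to_json(self, path: str | Path) -> None:
        payload = {
            "gap_tolerance": self.gap_tolerance,
            "tracks": [
                {
                    "lineage_id": t.lineage_id, "origin": t.origin,
                    "first_frame": t.first_frame, "last_frame": t.last_frame,
                    "end": t.end, "parent": t.parent,
                    "intervals": {str(k): list(v) for k, v in t.intervals.items()},
                }
                for t in self.tracks
            ],
            "summary": self.summary(),
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True))


def match_origins(truth, trackset: "PatchTrackSet", contours,
                  horizon: int = 5, max_delay: int = 4) -> dict:
    """Match recovered tracks to ground-truth births, origin by origin.

    Only truth births with at least ``horizon`` frames of subsequent
    footage are scored: a patch born on the movie's final frames never
    reaches the calling resolution, so no method can classify it.  A truth
    birth matches the recovered track (born within ``max_delay`` frames)
    whose first interval overlaps the truth lineage's interval most.
    Returns counts of events, matches and correct origins.
    """
    from .synth import truth_lineage_index_set

    events = [e for e in truth.births(1)
              if e["frame"] <= truth.n_frames - 1 - horizon]
    candidates = [t for t in trackset.tracks if t.first_frame >= 1]
    used: set[int] = set()
    n_matched = 0
    n_correct = 0
    for e in events:
        best = None
        best_key = None
        for tr in candidates:
            if tr.lineage_id in used:
                continue
            if not e["frame"] <= tr.first_frame <= e["frame"] + max_delay:
                continue
            f = tr.first_frame
            if contours[f] is None:
                continue
            tset = truth_lineage_index_set(truth, f, contours[f], e["lineage"])
            if e["origin"] == "split" and e.get("parent") is not None:
                # which sibling keeps the parent's track identity is
                # arbitrary; accept anything within the parent's footprint,
                # including its pre-split extent (a parent may shed several
                # daughters in one frame)
                tset |= truth_lineage_index_set(truth, f, contours[f],
                                                e["parent"])
                if f > 0:
                    tset |= truth_lineage_index_set(truth, f - 1, contours[f],
                                                    e["parent"])
            s, length = tr.intervals[f]
            n = contours[f].n_points
            rset = set(((s + np.arange(length)) % n).tolist())
            ov = len(tset & rset)
            if ov < 1:
                continue
            # the true track appears at (or just after) the birth frame, so
            # temporal proximity outranks raw overlap
            key = (tr.first_frame - e["frame"], -ov)
            if best_key is None or key < best_key:
                best_key = key
                best = tr
        if best is not None:
            used.add(best.lineage_id)
            n_matched += 1
            if best.origin == e["origin"]:
                n_correct += 1
    return {"n_events": len(events), "n_matched": n_matched,
            "n_origin_correct": n_correct}


def _circular_overlap(a_start, a_len, b_start, b_len, n) -> int:
    ia = set(((a_start + np.arange(a_len)) % n).tolist())
    ib = set(((b_start + np.arange(b_len)) % n).tolist())
    return len(ia & ib)


def track_patches(
    calls: list[PatchCall],
    correspondences: list[Correspondence] | None = None,
    gap_tolerance: int = 1,
    min_overlap: int = 1,
) -> PatchTrackSet:
    """Greedy interval-overlap linking of per-frame patch calls.

    Intervals are index-aligned across frames using the rigid circular
    offsets.  A called interval that continues an existing track (largest
    overlap wins, one-to-one) extends it; a new interval that overlaps a
    live track's previous interval is a ``split`` birth, otherwise
    ``de_novo``.  Tracks unmatched for more than ``gap_tolerance``
    consecutive frames are closed at their last seen frame.
    """
    if not calls:
        return PatchTrackSet(tracks=[], gap_tolerance=gap_tolerance)
    n = calls[0].n_points
    offs = (cumulative_offsets(correspondences)
            if correspondences is not None else [0] * len(calls))

    next_id = 0
    live: list[dict] = []  # state: track, last (start,length) in material rows
    done: list[Track] = []

    def material(iv, t):
        # convert frame-t interval to material-row indexing
        return ((iv.start_idx - offs[t]) % n, iv.length)

    for t, call in enumerate(calls):
        current = [material(iv, t) for iv in call.intervals]
        # score all (live track, current interval) pairs by overlap
        pairs = []
        for a, state in enumerate(live):
            s0, l0 = state["last"]
            for b, (s1, l1) in enumerate(current):
                ov = _circular_overlap(s0, l0, s1, l1, n)
                if ov >= min_overlap:
                    pairs.append((ov, a, b))
        pairs.sort(key=lambda x: (-x[0], x[1], x[2]))
        taken_a: set[int] = set()
        taken_b: set[int] = set()
        for ov, a, b in pairs:
            if a in taken_a or b in taken_b:
                continue
            taken_a.add(a)
            taken_b.add(b)
            state = live[a]
            state["last"] = current[b]
            state["misses"] = 0
            tr = state["track"]
            tr.last_frame = t
            tr.intervals[t] = (call.intervals[b].start_idx, call.intervals[b].length)
        # unmatched current intervals → new tracks
        for b, (s1, l1) in enumerate(current):
            if b in taken_b:
                continue
            origin = "de_novo"
            parent = None
            best_ov = 0
            for a, state in enumerate(live):
                s0, l0 = state["prev"] if state["misses"] == 0 else state["last"]
                ov = _circular_overlap(s0, l0, s1, l1, n)
                if ov > best_ov:
                    best_ov = ov
                    parent = state["track"].lineage_id
            if best_ov >= min_overlap:
                origin = "split"
            else:
                parent = None
            tr = Track(
                lineage_id=next_id, origin=origin, first_frame=t, last_frame=t,
                intervals={t: (call.intervals[b].start_idx,
                               call.intervals[b].length)},
                parent=parent,
            )
            next_id += 1
            live.append({"track": tr, "last": (s1, l1), "prev": (s1, l1),
                         "misses": 0})
        # age out unmatched tracks
        survivors = []
        for a, state in enumerate(live):
            if a in taken_a or state["track"].first_frame == t:
                state["prev"] = state["last"]
                survivors.append(state)
                continue
            state["misses"] += 1
            if state["misses"] > gap_tolerance:
                state["track"].end = "closed"
                done.append(state["track"])
            else:
                survivors.append(state)
        live = survivors

    for state in live:
        state["track"].end = "censored"
        done.append(state["track"])
    done.sort(key=lambda tr: (tr.first_frame, tr.lineage_id))
    return PatchTrackSet(tracks=done, gap_tolerance=gap_tolerance)
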