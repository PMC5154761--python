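"""Patch calling on the circular membrane profile, and patch statistics.

A patch is a maximal circular run of contour points whose *raw* calling-
channel intensity is strictly greater than the cytosol mean plus
``k_sd``·SD (default k = 1).  Wrap-around runs are merged into a single
interval; runs shorter than ``min_patch_points`` are discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyDistribution, InsufficientData, ProfileError
from .membrane import MembraneProfile
from .segment import CytosolStats


@dataclass
class PatchInterval:
    """Half-open circular interval [start_idx, end_idx) of contour points."""

    start_idx: int
    length: int
    n_total: int  # contour size N
    arc_length_um: float = 0.0
    mean_norm_intensity: float = 0.0
    peak_norm_intensity: float = 0.0

    @property
    def end_idx(self) -> int:
        return (self.start_idx + self.length) % self.n_total

    @property
    def center_idx(self) -> int:
        # even length ties break to the lower index
        return (self.start_idx + (self.length - 1) // 2) % self.n_total

    @property
    def edge_indices(self) -> tuple[int, int]:
        return self.start_idx, self.end_idx

    def indices(self) -> np.ndarray:
        return (self.start_idx + np.arange(self.length)) % self.n_total

    def index_set(self) -> set:
        return set(self.indices().tolist())


@dataclass
class PatchCall:
    frame_index: int
    channel: str
    intervals: list
    threshold_value: float
    k_sd: float
    n_points: int
    arc_spacing_um: float

    @property
    def n_patches(self) -> int:
        return len(self.intervals)

    def called_index_set(self) -> set:
        out: set[int] = set()
        for iv in self.intervals:
            out |= iv.index_set()
        return out


def _circular_runs(above: np.ndarray) -> list[tuple[int, int]]:
    """Maximal circular runs of True as (start, length)."""
    n = above.size
    if above.all():
        return [(0, n)]
    if not above.any():
        return []
    # rotate so position 0 is False, find linear runs, rotate back
    first_false = int(np.argmin(above))
    rot = np.roll(above, -first_false)
    edges = np.flatnonzero(np.diff(rot.astype(int)))
    starts = edges[::2] + 1  # rot[0] is False → runs start after a rise
    ends = np.append(edges[1::2] + 1, rot.size)[: len(starts)]
    return [(int((s + first_false) % n), int(e - s)) for s, e in zip(starts, ends)]


def call_patches(
    profile: MembraneProfile,
    cyto: CytosolStats,
    channel: str,
    channel_index: int | None = None,
    k_sd: float = 1.0,
    min_patch_points: int = 3,
) -> PatchCall:
    """Threshold rule: raw intensity strictly above cytosol mean + k·SD."""
    raw = profile.raw[channel]
    n = raw.size
    if n < 8:
        raise ProfileError("profile too coarse for patch calling (N < 8)")
    ci = channel_index if channel_index is not None else list(profile.raw).index(channel)
    threshold = float(cyto.mean[ci] + k_sd * cyto.sd[ci])
    above = raw > threshold  # strictly above: ties at the threshold excluded
    norm = profile.norm[channel]
    intervals = []
    for start, length in _circular_runs(above):
        if length < min_patch_points:
            continue
        idx = (start + np.arange(length)) % n
        # plateau intensity: trim the partially-covered boundary points so
        # the value does not depend on patch size through edge dilution
        core = idx[2:-2] if length > 6 else idx
        intervals.append(PatchInterval(
            start_idx=start, length=length, n_total=n,
            arc_length_um=length * profile.arc_spacing_um,
            mean_norm_intensity=float(norm[core].mean()),
            peak_norm_intensity=float(norm[idx].max()),
        ))
    intervals.sort(key=lambda iv: iv.start_idx)
    return PatchCall(
        frame_index=profile.frame_index, channel=channel,
        intervals=intervals, threshold_value=threshold, k_sd=k_sd,
        n_points=n, arc_spacing_um=profile.arc_spacing_um,
    )


@dataclass
class CenterEdgeMeasurement:
    """Second-channel intensity at a patch's centre vs its edges.

    All values are normalised to the measurement channel's cytosol mean, so
    ``i_cytosol`` is 1.0 by construction and deviations read as fold
    enrichment over the cytosolic background.
    """

    frame_index: int
    patch_start_idx: int
    patch_length: int
    i_center: float
    i_edge: float
    i_cytosol: float
    channel: str


def measure_center_edge(
    call: PatchCall,
    measurement_profile: MembraneProfile,
    cyto: CytosolStats,
    channel: str,
    edge_mode: str = "inside_outside_mean",
) -> list[CenterEdgeMeasurement]:
    """Quantify a (possibly different) channel at patch centres and edges.

    ``edge_mode`` "inside_outside_mean" (default) averages, at each of the
    two boundaries, the boundary point just inside the interval and its
    immediate outside neighbour; "boundary_only" uses just the two inside
    boundary points.  Patches shorter than 3 points are skipped.
    """
    norm = measurement_profile.norm[channel]
    n = norm.size
    out = []
    skipped = 0
    for iv in call.intervals:
        if iv.length < 3:
            skipped += 1
            continue
        in_start = iv.start_idx % n
        out_start = (iv.start_idx - 1) % n
        in_end = (iv.start_idx + iv.length - 1) % n
        out_end = (iv.start_idx + iv.length) % n
        if edge_mode == "inside_outside_mean":
            edge_vals = [norm[in_start], norm[out_start], norm[in_end], norm[out_end]]
        elif edge_mode == "boundary_only":
            edge_vals = [norm[in_start], norm[in_end]]
        else:
            raise ValueError(f"unknown edge_mode {edge_mode!r}")
        out.append(CenterEdgeMeasurement(
            frame_index=call.frame_index,
            patch_start_idx=iv.start_idx,
            patch_length=iv.length,
            i_center=float(norm[iv.center_idx]),
            i_edge=float(np.mean(edge_vals)),
            i_cytosol=1.0,
            channel=channel,
        ))
    if skipped:
        warnings.warn(f"skipped {skipped} patches shorter than 3 points",
                      stacklevel=2)
    return out


@dataclass
class PatchSizeStats:
    sizes_um: list
    mean_um: float
    sd_um: float
    n: int


def patch_size_stats(calls: list[PatchCall]) -> PatchSizeStats:
    """Arc-length distribution of every called patch across frames."""
    sizes = [iv.arc_length_um for c in calls for iv in c.intervals]
    if not sizes:
        raise EmptyDistribution("no patches called")
    arr = np.asarray(sizes)
    return PatchSizeStats(
        sizes_um=sizes,
        mean_um=float(arr.mean()),
        sd_um=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        n=arr.size,
    )


@dataclass
class GroupTest:
    statistic: float
    p_value: float
    test_name: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    cohen_d: float
    degenerate: bool = False


def compare_groups(sizes_a, sizes_b, paired: bool = False) -> GroupTest:
    """Two-tailed t-test between groups (paired, or Welch when unpaired)."""
    a = np.asarray(sizes_a, dtype=float)
    b = np.asarray(sizes_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientData("need at least 2 observations per group")
    if paired and a.size != b.size:
        raise InsufficientData("paired comparison requires equal group sizes")
    degenerate = False
    if paired:
        diffs = a - b
        if np.all(diffs == diffs[0]) and diffs[0] == 0:
            stat, p = 0.0, 1.0
            degenerate = True
        else:
            res = stats.ttest_rel(a, b)
            stat, p = float(res.statistic), float(res.pvalue)
        name = "paired two-tailed t-test"
        pooled_sd = float(np.std(diffs, ddof=1)) or float("nan")
        d = float(np.mean(diffs) / pooled_sd) if pooled_sd == pooled_sd else 0.0
    else:
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            if a[0] == b[0]:
                stat, p = 0.0, 1.0
            else:
                stat, p = float("inf"), 0.0
            degenerate = True
        else:
            res = stats.ttest_ind(a, b, equal_var=False)
            stat, p = float(res.statistic), float(res.pvalue)
        name = "Welch two-tailed t-test"
        sp = np.sqrt(0.5 * (np.var(a, ddof=1) + np.var(b, ddof=1)))
        d = float((a.mean() - b.mean()) / sp) if sp > 0 else 0.0
    return GroupTest(
        statistic=stat, p_value=p, test_name=name,
        n_a=int(a.size), n_b=int(b.size),
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        cohen_d=d, degenerate=degenerate,
    )


def holm_correction(p_values) -> list:
    """Holm step-down adjusted p-values (used when >2 tests are reported)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def calls_to_csv(calls: list[PatchCall], path) -> None:
    rows = []
    for c in calls:
        for iv in c.intervals:
            rows.append({
                "frame": c.frame_index, "channel": c.channel,
                "start_idx": iv.start_idx, "end_idx": iv.end_idx,
                "length": iv.length, "center_idx": iv.center_idx,
                "arc_length_um": iv.arc_length_um,
                "mean_norm_intensity": iv.mean_norm_intensity,
                "peak_norm_intensity": iv.peak_norm_intensity,
                "threshold": c.threshold_value, "n_points": c.n_points,
                "arc_spacing_um": c.arc_spacing_um, "k_sd": c.k_sd,
            })
    pd.DataFrame(rows, columns=[
        "frame", "channel", "start_idx", "end_idx", "length", "center_idx",
        "arc_length_um", "mean_norm_intensity", "peak_norm_intensity",
        "threshold", "n_points", "arc_spacing_um", "k_sd",
    ]).to_csv(path, index=False)


def calls_from_csv(path, n_frames: int | None = None) -> list[PatchCall]:
    df = pd.read_csv(path)
    calls = {}
    for _, row in df.iterrows():
        key = int(row["frame"])
        if key not in calls:
            calls[key] = PatchCall(
                frame_index=key, channel=str(row["channel"]), intervals=[],
                threshold_value=float(row["threshold"]), k_sd=float(row["k_sd"]),
                n_points=int(row["n_points"]),
                arc_spacing_um=float(row["arc_spacing_um"]),
            )
        calls[key].intervals.append(PatchInterval(
            start_idx=int(row["start_idx"]), length=int(row["length"]),
            n_total=int(row["n_points"]),
            arc_length_um=float(row["arc_length_um"]),
            mean_norm_intensity=float(row["mean_norm_intensity"]),
            peak_norm_intensity=float(row["peak_norm_intensity"]),
        ))
    return [calls[k] for k in sorted(calls)]
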