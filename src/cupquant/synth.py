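"""Synthetic two-channel single-cell movies with known ground truth.

The generator emulates the statistical structure of single-cell membrane
imaging: a star-convex cell (radius function r(θ) around a drifting
centroid) whose membrane rim carries intense "patches" in one channel and
narrow flanking "ring" accumulations in a second channel, on top of a
cytosolic pool.  Patches are angular intervals that are born (de novo or by
splitting an existing patch), grow from sub-resolution width to a sampled
target width, persist, and close abruptly.  Shot noise (Poisson) and read
noise (Gaussian) are applied last.

Angles are measured from the +x axis at the centroid and increase
counter-clockwise in image coordinates (x = column·pixel, y = row·pixel,
origin top-left); intervals are half-open ``[theta_start, theta_end)`` on
the circle.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .config import CHANNEL_NAMES, SynthConfig
from .errors import GeometryError, InvalidConfigError

TWO_PI = 2.0 * math.pi

# Internal dynamics constants (radians / frames).  These are fixed features
# of the patch life-cycle model, not exposed parameters: newborn width, the
# number of frames a newborn takes to reach its target width, the gap opened
# by a split and how fast it widens, and the narrowest patch kept alive.
BIRTH_WIDTH_RAD = math.radians(6.0)
GROWTH_FRAMES = 3
SPLIT_GAP_INITIAL_RAD = math.radians(8.0)
SPLIT_GAP_FINAL_RAD = math.radians(12.0)
SPLIT_GAP_FRAMES = 2
MIN_LIVE_WIDTH_RAD = math.radians(2.0)
MIN_SPLIT_WIDTH_RAD = math.radians(40.0)
MIN_CHILD_WIDTH_RAD = math.radians(14.0)  # split children stay resolvable
MAX_CHILD_WIDTH_RAD = math.radians(26.0)
PLACEMENT_MARGIN_RAD = math.radians(6.0)
PLACEMENT_TRIES = 25
GLOBAL_PROTRUSION_MODE = 3  # angular lobes of the "global" deformation


def wrap_angle(theta):
    """Map angle(s) to [0, 2π)."""
    return np.mod(theta, TWO_PI)


def angular_distance(a, b):
    """Smallest absolute angular difference."""
    d = np.mod(a - b, TWO_PI)
    return np.minimum(d, TWO_PI - d)


def interval_contains(theta_start: float, width: float, theta) -> np.ndarray:
    """Membership of ``theta`` in the circular half-open interval."""
    return np.mod(np.asarray(theta) - theta_start, TWO_PI) < width


@dataclass
class TruthPatch:
    """One ground-truth patch on one frame (a circular angular interval)."""

    lineage_id: int
    theta_start: float  # [0, 2π)
    width: float  # radians in (0, 2π)
    origin: str  # "de_novo" | "split"
    closed: bool = False  # True on the final frame of a closing patch
    fold: float = 1.0  # per-patch intensity multiplier (x config patch_fold)

    @property
    def theta_end(self) -> float:
        return wrap_angle(self.theta_start + self.width)

    @property
    def theta_center(self) -> float:
        return wrap_angle(self.theta_start + 0.5 * self.width)

    def contains(self, theta) -> np.ndarray:
        return interval_contains(self.theta_start, self.width, theta)


@dataclass
class GroundTruthSet:
    """Per-frame truth intervals, motion parameters and the event log."""

    config: SynthConfig
    centroids_um: np.ndarray  # (T, 2) as (x, y)
    patches: list  # list over frames of list[TruthPatch]
    events: list  # dicts: birth / split / closure with frame indices
    protrusion_phase: float = 0.0

    @property
    def n_frames(self) -> int:
        return len(self.patches)

    # -- geometry ----------------------------------------------------------
    def radius_at(self, theta, frame: int) -> np.ndarray:
        """Cell radius r(θ) in µm for one frame (vectorised over θ)."""
        cfg = self.config
        theta = np.asarray(theta, dtype=float)
        r = np.full(theta.shape, cfg.cell_radius_um, dtype=float)
        amp = cfg.protrusion_amp_um
        if amp <= 0 or cfg.protrusion_mode == "none":
            return r
        if cfg.protrusion_mode == "global":
            r += amp * np.cos(
                GLOBAL_PROTRUSION_MODE * theta + self.protrusion_phase
            ) * math.sin(TWO_PI * cfg.protrusion_freq * frame)
            return r
        # "patch" mode: smooth radial bumps over each patch's flanking ring
        # segments, scaled by how far the patch has grown.
        ring_theta = cfg.ring_width_um / cfg.cell_radius_um
        typical = math.radians(cfg.patch_width_deg_mean)
        for p in self.patches[frame]:
            # bump amplitude tracks patch growth so the membrane moves
            # outward at ring positions while the rings are present
            scale = min(1.0, p.width / typical)
            for center in (
                wrap_angle(p.theta_start - 0.5 * ring_theta),
                wrap_angle(p.theta_start + p.width + 0.5 * ring_theta),
            ):
                d = angular_distance(theta, center)
                span = ring_theta
                inside = d < span
                r[inside] += amp * scale * np.cos(0.5 * math.pi * d[inside] / span) ** 2
        return r

    def cell_area_um2(self, frame: int, n: int = 2048) -> float:
        """Area enclosed by r(θ) via ½∫r²dθ (to the outer membrane edge)."""
        theta = np.linspace(0.0, TWO_PI, n, endpoint=False)
        r = self.radius_at(theta, frame) + 0.5 * self.config.membrane_band_um
        return float(0.5 * np.sum(r**2) * TWO_PI / n)

    def membrane_point(self, theta: float, frame: int) -> np.ndarray:
        """(x, y) µm of the membrane midline at angle θ."""
        r = float(self.radius_at(np.array([theta]), frame)[0])
        c = self.centroids_um[frame]
        return np.array([c[0] + r * math.cos(theta), c[1] + r * math.sin(theta)])

    # -- bookkeeping -------------------------------------------------------
    def births(self, min_frame: int = 1) -> list:
        return [
            e for e in self.events
            if e["type"] == "birth" and e["frame"] >= min_frame
        ]

    def realized_split_fraction(self, min_frame: int = 1) -> float:
        b = self.births(min_frame)
        if not b:
            return float("nan")
        return sum(e["origin"] == "split" for e in b) / len(b)

    def lineage_span(self, lineage_id: int) -> tuple[int, int, bool]:
        """(birth_frame, last_frame, closed) for one lineage."""
        frames = [
            t for t, pats in enumerate(self.patches)
            if any(p.lineage_id == lineage_id for p in pats)
        ]
        closed = any(
            e["type"] == "closure" and e["lineage"] == lineage_id
            for e in self.events
        )
        return frames[0], frames[-1], closed

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "centroids_um": np.asarray(self.centroids_um).tolist(),
            "protrusion_phase": self.protrusion_phase,
            "patches": [
                [
                    {
                        "lineage_id": p.lineage_id,
                        "theta_start": p.theta_start,
                        "theta_end": p.theta_end,
                        "width": p.width,
                        "origin": p.origin,
                        "closed": p.closed,
                        "fold": p.fold,
                    }
                    for p in pats
                ]
                for pats in self.patches
            ],
            "events": self.events,
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthSet":
        patches = [
            [
                TruthPatch(
                    lineage_id=int(p["lineage_id"]),
                    theta_start=float(p["theta_start"]),
                    width=float(p["width"]),
                    origin=p["origin"],
                    closed=bool(p["closed"]),
                    fold=float(p.get("fold", 1.0)),
                )
                for p in pats
            ]
            for pats in d["patches"]
        ]
        return cls(
            config=SynthConfig.from_dict(d["config"]),
            centroids_um=np.asarray(d["centroids_um"], dtype=float),
            patches=patches,
            events=list(d["events"]),
            protrusion_phase=float(d.get("protrusion_phase", 0.0)),
        )

    @classmethod
    def load_json(cls, path: str | Path) -> "GroundTruthSet":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class FrameStack:
    """A two-channel movie with physical calibration.

    ``pixels`` has shape (frames, channels, rows, cols); channel order is
    (patch, ring).
    """

    pixels: np.ndarray
    channel_names: tuple = CHANNEL_NAMES
    pixel_size_um: float = 0.1
    frame_interval_s: float = 1.0

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    def frame(self, t: int) -> np.ndarray:
        return self.pixels[t]

    def channel_index(self, name: str) -> int:
        return self.channel_names.index(name)


# ---------------------------------------------------------------------------
# patch schedule
# ---------------------------------------------------------------------------


@dataclass
class _Lineage:
    lineage_id: int
    center: float  # θ of the (initial) interval centre
    target_width: float
    birth_frame: int
    death_frame: int  # first frame the patch is gone
    origin: str
    grown: bool  # skip the newborn growth ramp (initial / split children)
    fold: float = 1.0  # per-patch reporter intensity multiplier
    # split retraction of each edge: (start_frame, initial, final) half-gaps
    retract_low: tuple | None = None
    retract_high: tuple | None = None

    def _retraction(self, spec, frame: int) -> float:
        if spec is None:
            return 0.0
        t0, g0, g1 = spec
        f = min(1.0, (frame - t0) / SPLIT_GAP_FRAMES) if SPLIT_GAP_FRAMES else 1.0
        return g0 + f * (g1 - g0)

    def interval(self, frame: int) -> tuple[float, float] | None:
        """(theta_start, width) at ``frame``, or None if not visible."""
        if not (self.birth_frame <= frame < self.death_frame):
            return None
        if self.grown:
            w = self.target_width
        else:
            age = frame - self.birth_frame
            f = min(1.0, (age + 1) / (GROWTH_FRAMES + 1))
            w = max(BIRTH_WIDTH_RAD, f * self.target_width)
        start = self.center - 0.5 * w
        end = self.center + 0.5 * w
        start += self._retraction(self.retract_low, frame)
        end -= self._retraction(self.retract_high, frame)
        width = end - start
        if width < MIN_LIVE_WIDTH_RAD:
            return None
        return wrap_angle(start), width


REFRACTORY_FRAMES = 3  # closed patch territory stays unavailable briefly


def _occupied_intervals(lineages, frame, cfg) -> list:
    """(start, width) footprints blocking de-novo placement at ``frame``.

    Each lineage reserves its full target footprint inflated by its ring
    segments plus a margin, from birth until ``REFRACTORY_FRAMES`` after
    closure — so a new patch is never born exactly where one just closed,
    which would be indistinguishable from a continuation of it.
    """
    # rings may interleave between neighbouring patches (they are clipped at
    # patch boundaries when rendering), so the placement margin only needs
    # to keep the *patch* intervals separable at the calling resolution
    pad = PLACEMENT_MARGIN_RAD
    out = []
    for lin in lineages:
        if not lin.birth_frame <= frame < lin.death_frame + REFRACTORY_FRAMES:
            continue
        width = lin.target_width
        start = wrap_angle(lin.center - 0.5 * width)
        out.append((wrap_angle(start - pad), width + 2 * pad))
    return out


def _fits(center: float, width: float, occupied) -> bool:
    half = 0.5 * width
    for start, owidth in occupied:
        # overlap of [center-half, center+half) with occupied interval
        d = wrap_angle(center - start)
        if d < owidth + half or d > TWO_PI - half:
            return False
    return True


def _sample_width_rad(cfg: SynthConfig, rng: np.random.Generator) -> float:
    """Draw one target patch width (radians) from the configured normal,
    clipped to stay physical (at least 2 degrees, below a half-circle plus)."""
    mean = math.radians(cfg.patch_width_deg_mean)
    w = rng.normal(mean, math.radians(cfg.patch_width_deg_sd))
    lo = max(math.radians(2.0), 0.1 * mean)
    return float(np.clip(w, lo, math.radians(150.0)))


def sample_patch_widths_um(config: SynthConfig, n: int,
                           rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw ``n`` ground-truth patch widths as membrane arc lengths (µm).

    These are the target widths the schedule assigns at birth — the truth
    distribution behind any measured patch-size comparison.
    """
    cfg = config.validate()
    if rng is None:
        rng = np.random.default_rng([cfg.seed, 303])
    return np.array([_sample_width_rad(cfg, rng) for _ in range(n)]) \
        * cfg.cell_radius_um


def make_patch_schedule(config: SynthConfig) -> GroundTruthSet:
    """Simulate patch birth / growth / split / closure dynamics.

    Deterministic given ``config.seed``.  Births follow a Poisson process
    from frame 1; each successful birth is a split of a live patch with
    probability ``split_probability`` (falling back to de novo when no live
    patch is wide enough to split), otherwise de novo.  Split replaces the
    parent interval by two sub-intervals separated by a gap that widens over
    the next frames; the parent lineage keeps the lower sub-interval and a
    new lineage takes the upper one.
    """
    cfg = config.validate()
    if cfg.n_frames <= 0 or cfg.patch_birth_rate < 0:
        raise InvalidConfigError("n_frames must be > 0 and patch_birth_rate >= 0")
    rng = np.random.default_rng([cfg.seed, 101])

    lineages: list[_Lineage] = []
    events: list[dict] = []
    next_id = 0

    def sample_width() -> float:
        return _sample_width_rad(cfg, rng)

    def sample_lifetime() -> int:
        return int(max(5, rng.poisson(cfg.patch_lifetime_frames_mean)))

    def live_at(frame):
        return [lin for lin in lineages if lin.interval(frame) is not None]

    def place_de_novo(frame: int, grown: bool, origin: str) -> bool:
        nonlocal next_id
        width = sample_width()
        occupied = _occupied_intervals(lineages, frame, cfg)
        for _ in range(PLACEMENT_TRIES):
            center = rng.uniform(0.0, TWO_PI)
            if _fits(center, width, occupied):
                break
        else:
            return False
        if frame == 0 and grown:
            # seeded steady-state patch: age is unknown, so its remaining
            # lifetime is a staggered residual rather than a full lifetime
            death = 1 + int(max(4, rng.uniform(0.2, 1.2)
                                * cfg.patch_lifetime_frames_mean))
        else:
            death = frame + sample_lifetime()
        lineages.append(_Lineage(
            lineage_id=next_id, center=center, target_width=width,
            birth_frame=frame, death_frame=death,
            origin=origin, grown=grown,
            fold=float(np.exp(rng.normal(0.0, cfg.patch_fold_cv)))))
        events.append({"type": "birth", "frame": frame, "lineage": next_id,
                       "origin": origin, "initial": frame == 0})
        next_id += 1
        return True

    def do_split(frame: int) -> bool:
        nonlocal next_id
        candidates = []
        for lin in live_at(frame):
            if not lin.grown and frame - lin.birth_frame <= GROWTH_FRAMES:
                continue  # only fully grown patches split
            iv = lin.interval(frame)
            if iv is not None and iv[1] >= MIN_SPLIT_WIDTH_RAD:
                candidates.append((lin, iv))
        if not candidates:
            return False
        lin, (start, width) = candidates[rng.integers(len(candidates))]
        end = start + width
        gap = SPLIT_GAP_FINAL_RAD
        # asymmetric split: a small daughter detaches from one end of the
        # parent, leaving the parent wide enough to split again later
        hi = width - gap - MIN_CHILD_WIDTH_RAD
        if hi <= MIN_CHILD_WIDTH_RAD:
            return False
        child_width = float(rng.uniform(
            MIN_CHILD_WIDTH_RAD, min(MAX_CHILD_WIDTH_RAD, hi)))
        parent_width = width - child_width - gap
        if parent_width < MIN_CHILD_WIDTH_RAD:
            return False
        # the gap's inner edges start (final-initial)/2 beyond their final
        # position and retract to it over SPLIT_GAP_FRAMES frames
        relax = 0.5 * (SPLIT_GAP_FINAL_RAD - SPLIT_GAP_INITIAL_RAD)
        side_high = bool(rng.uniform() < 0.5)  # which end detaches
        if side_high:
            parent_lo, parent_hi = start, start + parent_width
            child_lo, child_hi = end - child_width, end
            lin.retract_high = (frame, -relax, 0.0)
            child_retract = {"retract_low": (frame, -relax, 0.0)}
        else:
            parent_lo, parent_hi = end - parent_width, end
            child_lo, child_hi = start, start + child_width
            lin.retract_low = (frame, -relax, 0.0)
            child_retract = {"retract_high": (frame, -relax, 0.0)}
        lin.center = wrap_angle(0.5 * (parent_lo + parent_hi))
        lin.target_width = parent_width
        lin.grown = True
        child = _Lineage(
            lineage_id=next_id,
            center=wrap_angle(0.5 * (child_lo + child_hi)),
            target_width=child_width,
            birth_frame=frame,
            death_frame=frame + sample_lifetime(),
            origin="split",
            grown=True,
            fold=lin.fold,  # a detached daughter shares its parent's intensity
            **child_retract,
        )
        lineages.append(child)
        events.append({"type": "birth", "frame": frame, "lineage": child.lineage_id,
                       "origin": "split", "initial": False,
                       "parent": lin.lineage_id})
        events.append({"type": "split", "frame": frame, "parent": lin.lineage_id,
                       "children": [lin.lineage_id, child.lineage_id]})
        next_id += 1
        return True

    # Simulate frame by frame, snapshotting intervals *before* later events
    # can mutate lineage state (splits reshape the parent in place, which
    # must not rewrite already-recorded frames).  Births whose origin cannot
    # be realised yet (no splittable parent / no free membrane) are deferred
    # to the next frame rather than converted, so the realised origin mix
    # stays Bernoulli(split_probability).
    patches: list[list[TruthPatch]] = []
    pending: list[list] = []  # [intent, age in frames]
    for frame in range(cfg.n_frames):
        if frame == 0:
            # seeded steady-state patches (full width; the movie does not
            # show how they arose, so they carry no observable origin)
            for _ in range(cfg.initial_patches):
                place_de_novo(0, grown=True, origin="de_novo")
        else:
            for _ in range(rng.poisson(cfg.patch_birth_rate)):
                pending.append([
                    "split" if rng.uniform() < cfg.split_probability
                    else "de_novo", 0])
            still = []
            for intent in pending:
                kind = intent[0]
                if kind == "split" and intent[1] > cfg.split_patience_frames:
                    # no splittable parent appeared in time; the patch forms
                    # de novo instead (prevents extinction when every patch
                    # has closed and split intents would wait forever)
                    kind = "de_novo"
                ok = (do_split(frame) if kind == "split"
                      else place_de_novo(frame, grown=False, origin="de_novo"))
                if not ok:
                    intent[1] += 1
                    still.append(intent)
            pending = still
        frame_patches = []
        for lin in lineages:
            iv = lin.interval(frame)
            if iv is None:
                continue
            frame_patches.append(TruthPatch(
                lineage_id=lin.lineage_id, theta_start=iv[0], width=iv[1],
                origin=lin.origin, fold=lin.fold))
        frame_patches.sort(key=lambda p: p.theta_start)
        patches.append(frame_patches)

    # closure events + closed flags on each closing lineage's last frame
    last_seen: dict[int, int] = {}
    for frame, pats in enumerate(patches):
        for p in pats:
            last_seen[p.lineage_id] = frame
    for lin in lineages:
        if lin.death_frame <= cfg.n_frames and lin.lineage_id in last_seen:
            last = last_seen[lin.lineage_id]
            for p in patches[last]:
                if p.lineage_id == lin.lineage_id:
                    p.closed = True
            events.append({"type": "closure", "frame": last,
                           "lineage": lin.lineage_id})

    # drifting centroid
    h, w = cfg.image_size_px
    center0 = np.array([0.5 * w * cfg.pixel_size_um, 0.5 * h * cfg.pixel_size_um])
    drift_angle = rng.uniform(0.0, TWO_PI)
    drift = cfg.drift_speed_um_s * cfg.frame_interval_s * np.array(
        [math.cos(drift_angle), math.sin(drift_angle)])
    t = np.arange(cfg.n_frames)[:, None]
    centroids = center0[None, :] + drift[None, :] * t

    return GroundTruthSet(
        config=cfg,
        centroids_um=centroids,
        patches=patches,
        events=sorted(events, key=lambda e: (e["frame"], e["type"], e.get("lineage", -1))),
        protrusion_phase=float(rng.uniform(0.0, TWO_PI)),
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _ring_segments(p: TruthPatch, ring_theta: float, placement: str) -> list:
    """(start, width) circular intervals carrying the ring-channel fold."""
    if placement == "coincident":
        return [(p.theta_start, p.width)]
    rw = min(ring_theta, 0.5 * p.width) if placement == "interior" else ring_theta
    if placement == "interior":
        return [
            (p.theta_start, rw),
            (wrap_angle(p.theta_start + p.width - rw), rw),
        ]
    return [  # exterior: abutting the boundary, outside the interval
        (wrap_angle(p.theta_start - rw), rw),
        (wrap_angle(p.theta_start + p.width), rw),
    ]


def render_frame(
    truth: GroundTruthSet,
    frame_index: int,
    config: SynthConfig | None = None,
    rng: np.random.Generator | None = None,
    noise: bool = True,
) -> np.ndarray:
    """Render one (2, H, W) frame from the ground truth.

    The noiseless image is a piecewise-constant function of the truth
    geometry: cytosol at ``cyto_mean``, membrane band at
    ``baseline_membrane_fold``·cyto, multiplied by ``patch_fold`` inside
    patch intervals (patch channel) and by ``ring_fold`` inside ring
    segments (ring channel).  Poisson then Gaussian noise is applied last;
    with both noise parameters zero the render is deterministic.
    """
    cfg = config or truth.config
    if not 0 <= frame_index < truth.n_frames:
        raise IndexError(f"frame_index {frame_index} out of range")
    h, w = cfg.image_size_px
    px = cfg.pixel_size_um
    cx, cy = truth.centroids_um[frame_index]

    yy, xx = np.mgrid[0:h, 0:w]
    x = xx * px - cx
    y = yy * px - cy
    rho = np.hypot(x, y)
    theta = wrap_angle(np.arctan2(y, x))

    rb = truth.radius_at(theta, frame_index)
    half_band = 0.5 * cfg.membrane_band_um
    max_extent = float(np.max(rb)) + half_band
    if (cx - max_extent < 0 or cy - max_extent < 0
            or cx + max_extent > w * px or cy + max_extent > h * px):
        raise GeometryError("cell (radius + protrusion) exceeds image bounds")

    cyto = rho < rb - half_band
    band = np.abs(rho - rb) <= half_band

    in_patch = np.zeros((h, w), dtype=bool)
    in_ring = np.zeros((h, w), dtype=bool)
    patch_fold_map = np.ones((h, w), dtype=np.float64)
    ring_theta = cfg.ring_width_um / cfg.cell_radius_um
    for p in truth.patches[frame_index]:
        inside = p.contains(theta)
        in_patch |= inside
        patch_fold_map[inside] = cfg.patch_fold * p.fold
        for start, width in _ring_segments(p, ring_theta, cfg.ring_placement):
            in_ring |= interval_contains(start, width, theta)
    if cfg.ring_placement == "exterior":
        # the ring reporter is excluded from patch interiors: a segment that
        # would reach into a neighbouring patch (e.g. across a split gap)
        # stops at that patch's boundary
        in_ring &= ~in_patch

    out = np.zeros((2, h, w), dtype=np.float64)
    for ci, fold in ((0, patch_fold_map),
                     (1, np.where(in_ring, cfg.ring_fold, 1.0))):
        img = np.where(cyto, cfg.cyto_mean[ci], 0.0)
        img = np.where(band, cfg.cyto_mean[ci] * cfg.baseline_membrane_fold * fold, img)
        out[ci] = img

    if noise and (cfg.noise_poisson_scale > 0 or cfg.noise_gauss_sd > 0):
        if rng is None:
            rng = np.random.default_rng([cfg.seed, 202, frame_index])
        if cfg.noise_poisson_scale > 0:
            out = rng.poisson(cfg.noise_poisson_scale * out) / cfg.noise_poisson_scale
        if cfg.noise_gauss_sd > 0:
            out = out + rng.normal(0.0, cfg.noise_gauss_sd, size=out.shape)
        out = np.maximum(out, 0.0)
    return out.astype(np.float32)


def make_cell_movie(config: SynthConfig) -> tuple[FrameStack, GroundTruthSet]:
    """Compose schedule + motion + renderer into a full movie."""
    truth = make_patch_schedule(config)
    frames = np.stack([
        render_frame(truth, t) for t in range(truth.n_frames)
    ])
    stack = FrameStack(
        pixels=frames,
        channel_names=CHANNEL_NAMES,
        pixel_size_um=config.pixel_size_um,
        frame_interval_s=config.frame_interval_s,
    )
    return stack, truth


def make_radius_ramp_movie(
    config: SynthConfig, rate_um_s: float
) -> tuple[FrameStack, GroundTruthSet]:
    """Patch-free movie of a cell whose radius grows at ``rate_um_s``.

    Used as an analytic oracle for the signed membrane-speed estimator: an
    isotropically expanding circle has normal velocity ``rate_um_s``
    everywhere.
    """
    base = config.replace(patch_birth_rate=0.0, initial_patches=0,
                          drift_speed_um_s=0.0, protrusion_amp_um=0.0)
    frames = []
    truths = []
    for t in range(base.n_frames):
        cfg_t = base.replace(
            cell_radius_um=base.cell_radius_um + rate_um_s * base.frame_interval_s * t,
            n_frames=1)
        truth_t = make_patch_schedule(cfg_t)
        frames.append(render_frame(truth_t, 0))
        truths.append(truth_t)
    stack = FrameStack(
        pixels=np.stack(frames),
        channel_names=CHANNEL_NAMES,
        pixel_size_um=base.pixel_size_um,
        frame_interval_s=base.frame_interval_s,
    )
    # a truth object spanning the movie, for centroids / radii
    truth = dataclasses.replace(
        truths[0],
        centroids_um=np.concatenate([t.centroids_um for t in truths]),
        patches=[t.patches[0] for t in truths],
    )
    return stack, truth


# ---------------------------------------------------------------------------
# truth ↔ contour-index helpers (used by tests and the acceptance script)
# ---------------------------------------------------------------------------


def truth_index_set(truth: GroundTruthSet, frame: int, contour) -> set:
    """Contour point indices whose angle lies in any truth interval."""
    c = truth.centroids_um[frame]
    theta = wrap_angle(np.arctan2(contour.points[:, 1] - c[1],
                                  contour.points[:, 0] - c[0]))
    idx: set[int] = set()
    for p in truth.patches[frame]:
        idx.update(np.nonzero(p.contains(theta))[0].tolist())
    return idx


def truth_lineage_index_set(truth: GroundTruthSet, frame: int, contour,
                            lineage_id: int) -> set:
    c = truth.centroids_um[frame]
    theta = wrap_angle(np.arctan2(contour.points[:, 1] - c[1],
                                  contour.points[:, 0] - c[0]))
    for p in truth.patches[frame]:
        if p.lineage_id == lineage_id:
            return set(np.nonzero(p.contains(theta))[0].tolist())
    return set()


# ---------------------------------------------------------------------------
# movie I/O: multi-page TIFF (frame-major, channel-minor) + YAML metadata
# ---------------------------------------------------------------------------


def save_movie(stack: FrameStack, tiff_path: str | Path,
               meta_path: str | Path | None = None) -> None:
    tiff_path = Path(tiff_path)
    t, c, h, w = stack.pixels.shape
    tifffile.imwrite(tiff_path, stack.pixels.reshape(t * c, h, w).astype(np.float32))
    meta = {
        "n_frames": int(t),
        "channel_names": list(stack.channel_names),
        "pixel_size_um": float(stack.pixel_size_um),
        "frame_interval_s": float(stack.frame_interval_s),
    }
    meta_path = Path(meta_path) if meta_path else tiff_path.with_suffix(".yaml")
    meta_path.write_text(yaml.safe_dump(meta, sort_keys=True))


def load_movie(tiff_path: str | Path,
               meta_path: str | Path | None = None) -> FrameStack:
    tiff_path = Path(tiff_path)
    meta_path = Path(meta_path) if meta_path else tiff_path.with_suffix(".yaml")
    meta = yaml.safe_load(meta_path.read_text())
    pages = tifffile.imread(tiff_path)
    t = int(meta["n_frames"])
    c = len(meta["channel_names"])
    pixels = np.asarray(pages).reshape(t, c, pages.shape[-2], pages.shape[-1])
    return FrameStack(
        pixels=pixels,
        channel_names=tuple(meta["channel_names"]),
        pixel_size_um=float(meta["pixel_size_um"]),
        frame_interval_s=float(meta["frame_interval_s"]),
    )
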