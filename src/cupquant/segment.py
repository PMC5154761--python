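"""Cell segmentation, sub-pixel contour extraction, cytosol statistics.

Coordinate convention (used throughout the package): x = column·pixel_size,
y = row·pixel_size, origin at the top-left pixel corner, y increasing
downward.  "Counter-clockwise" means the polar angle
``atan2(y - cy, x - cx)`` increases along the contour, which in this frame
corresponds to a positive shoelace area.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure, morphology

from .errors import ContourError, MarginTooLarge, NoCellFound


@dataclass
class CellMask:
    mask: np.ndarray  # boolean (H, W)
    frame_index: int = 0

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


@dataclass
class CytosolStats:
    """Mean and SD of the cytosolic pool, per channel.

    Computed over the cell mask eroded by ``erosion_margin_um`` so the
    bright membrane band is excluded; these numbers define both the
    normalisation and the patch-calling threshold (cytosol mean + k·SD).
    """

    mean: np.ndarray  # (C,)
    sd: np.ndarray  # (C,)
    n_pixels: int
    erosion_margin_um: float
    frame_index: int = 0


@dataclass
class Contour:
    """Closed, equal-arclength, counter-clockwise sub-pixel cell outline."""

    points: np.ndarray  # (N, 2) as (x, y) in µm
    arc_spacing_um: float
    centroid: np.ndarray  # (2,) µm
    frame_index: int = 0
    perimeter_um: float = 0.0

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def angles(self) -> np.ndarray:
        d = self.points - self.centroid[None, :]
        return np.mod(np.arctan2(d[:, 1], d[:, 0]), 2.0 * np.pi)

    def tangents(self) -> np.ndarray:
        p = self.points
        t = np.roll(p, -1, axis=0) - np.roll(p, 1, axis=0)
        norm = np.linalg.norm(t, axis=1, keepdims=True)
        return t / np.maximum(norm, 1e-12)

    def normals(self) -> np.ndarray:
        """Outward unit normals (rotate tangent; orient away from centroid)."""
        t = self.tangents()
        n = np.stack([t[:, 1], -t[:, 0]], axis=1)
        radial = self.points - self.centroid[None, :]
        sign = np.sign(np.sum(n * radial, axis=1))
        sign[sign == 0] = 1.0
        # orientation is a global property of the closed curve; use majority
        flip = np.sum(sign) < 0
        return -n if flip else n

    def enclosed_area_um2(self) -> float:
        x, y = self.points[:, 0], self.points[:, 1]
        x1, y1 = np.roll(x, -1), np.roll(y, -1)
        return float(0.5 * np.sum(x * y1 - x1 * y))


def segment_cell(
    image: np.ndarray,
    *,
    pixel_size_um: float,
    smooth_sigma_um: float = 0.1,
    threshold_method: str | float = "otsu",
    min_area_px: int = 500,
    frame_index: int = 0,
) -> CellMask:
    """Largest above-threshold connected component, hole-filled.

    ``threshold_method`` is "otsu", "mean", or a fixed numeric threshold.
    Raises :class:`NoCellFound` when no component reaches ``min_area_px``.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise NoCellFound("empty image")
    sigma_px = smooth_sigma_um / pixel_size_um
    smoothed = ndimage.gaussian_filter(image, sigma_px) if sigma_px > 0 else image
    if isinstance(threshold_method, (int, float)):
        thr = float(threshold_method)
    elif threshold_method == "otsu":
        if np.ptp(smoothed) == 0:
            raise NoCellFound("constant image")
        thr = filters.threshold_otsu(smoothed)
    elif threshold_method == "mean":
        thr = float(smoothed.mean())
    else:
        raise ValueError(f"unknown threshold_method {threshold_method!r}")
    bw = smoothed > thr
    labels, n = ndimage.label(bw)
    if n == 0:
        raise NoCellFound("no above-threshold pixels")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < min_area_px:
        raise NoCellFound(
            f"largest component has {int(sizes[best - 1])} px < {min_area_px}")
    mask = ndimage.binary_fill_holes(labels == best)
    return CellMask(mask=mask, frame_index=frame_index)


def extract_contour(
    cell: CellMask,
    n_points: int = 100,
    *,
    pixel_size_um: float,
    boundary_sigma_px: float = 1.0,
) -> Contour:
    """Sub-pixel boundary of the mask, resampled to equal arclength.

    The boundary is the 0.5 iso-contour of the Gaussian-smoothed mask
    (marching squares), traversed counter-clockwise with index 0 at the
    point nearest the +x ray from the centroid.
    """
    mask = cell.mask
    if mask.sum() < 8:
        raise ContourError("mask too small for a boundary")
    soft = ndimage.gaussian_filter(mask.astype(float), boundary_sigma_px)
    contours = measure.find_contours(soft, 0.5)
    if not contours:
        raise ContourError("no iso-contour found")

    def poly_length(rc):
        d = np.diff(rc, axis=0)
        return np.sum(np.hypot(d[:, 0], d[:, 1]))

    rc = max(contours, key=poly_length)
    if rc.shape[0] < 8:
        raise ContourError("degenerate boundary (< 8 boundary points)")
    # (row, col) → (x, y) in µm
    xy = np.stack([rc[:, 1], rc[:, 0]], axis=1) * pixel_size_um
    if np.allclose(xy[0], xy[-1]):
        xy = xy[:-1]
    # enforce counter-clockwise (positive shoelace in this frame)
    x, y = xy[:, 0], xy[:, 1]
    area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if area < 0:
        xy = xy[::-1]

    # marching-squares polylines are jagged at the pixel scale; resample
    # densely, smooth circularly, then take the final equal-arclength points
    dense = _resample_closed(xy, max(4 * n_points, 400))
    dense = ndimage.uniform_filter1d(dense, size=5, axis=0, mode="wrap")
    pts = _resample_closed(dense, n_points)
    closed = np.vstack([pts, pts[:1]])
    perimeter = float(np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1)))
    if perimeter <= 0:
        raise ContourError("zero-length boundary")

    centroid = _polygon_centroid(pts)
    theta = np.arctan2(pts[:, 1] - centroid[1], pts[:, 0] - centroid[0])
    # index origin: point nearest the +x ray (smallest |angle|)
    start = int(np.argmin(np.abs(np.mod(theta + np.pi, 2 * np.pi) - np.pi)))
    pts = np.roll(pts, -start, axis=0)
    return Contour(
        points=pts,
        arc_spacing_um=perimeter / n_points,
        centroid=centroid,
        frame_index=cell.frame_index,
        perimeter_um=perimeter,
    )


def _resample_closed(xy: np.ndarray, n: int) -> np.ndarray:
    """Equal-arclength resampling of a closed polyline to ``n`` points."""
    closed = np.vstack([xy, xy[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        raise ContourError("zero-length boundary")
    targets = np.arange(n) * s[-1] / n
    return np.stack([np.interp(targets, s, closed[:, 0]),
                     np.interp(targets, s, closed[:, 1])], axis=1)


def _polygon_centroid(pts: np.ndarray) -> np.ndarray:
    x, y = pts[:, 0], pts[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    a = 0.5 * np.sum(cross)
    if abs(a) < 1e-12:
        return pts.mean(axis=0)
    cx = np.sum((x + x1) * cross) / (6.0 * a)
    cy = np.sum((y + y1) * cross) / (6.0 * a)
    return np.array([cx, cy])


def cytosol_stats(
    frame: np.ndarray,
    cell: CellMask,
    erosion_margin_um: float = 1.0,
    *,
    pixel_size_um: float,
) -> CytosolStats:
    """Mean/SD per channel over the mask eroded by ``erosion_margin_um``.

    ``frame`` is (C, H, W) or (H, W).  Raises :class:`MarginTooLarge` when
    erosion empties the mask.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim == 2:
        frame = frame[None, ...]
    radius_px = int(round(erosion_margin_um / pixel_size_um))
    eroded = (
        ndimage.binary_erosion(cell.mask, morphology.disk(radius_px))
        if radius_px > 0 else cell.mask
    )
    n = int(eroded.sum())
    if n == 0:
        raise MarginTooLarge(
            f"erosion by {erosion_margin_um} um emptied the mask")
    vals = frame[:, eroded]
    return CytosolStats(
        mean=vals.mean(axis=1),
        sd=vals.std(axis=1, ddof=1) if n > 1 else np.zeros(frame.shape[0]),
        n_pixels=n,
        erosion_margin_um=erosion_margin_um,
        frame_index=cell.frame_index,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def contours_to_csv(contours: list[Contour], path: str | Path) -> None:
    rows = []
    for c in contours:
        for i, (x, y) in enumerate(c.points):
            rows.append({"frame": c.frame_index, "index": i,
                         "x_um": x, "y_um": y})
    pd.DataFrame(rows).to_csv(path, index=False)


def contours_from_csv(path: str | Path) -> list[Contour]:
    df = pd.read_csv(path)
    out = []
    for frame, grp in df.groupby("frame", sort=True):
        grp = grp.sort_values("index")
        pts = grp[["x_um", "y_um"]].to_numpy()
        closed = np.vstack([pts, pts[:1]])
        perimeter = float(np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1)))
        out.append(Contour(
            points=pts,
            arc_spacing_um=perimeter / len(pts),
            centroid=_polygon_centroid(pts),
            frame_index=int(frame),
            perimeter_um=perimeter,
        ))
    return out
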