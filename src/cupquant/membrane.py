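"""Membrane-bound fluorescence sampling along the contour, joint statistics.

The membrane profile assigns each contour point the mean of bilinear image
samples taken along its normal.  By default the sampling band extends
*inward* from the contour over ``band_width_um`` (cortex-depth sampling):
the contour tracks the outer cell boundary, so an inward band keeps the
samples on the membrane rim and out of the extracellular background.  A
"centered" mode (band straddling the contour) is available.  When a cell
mask is supplied, samples falling outside the cell are excluded, which
makes the profile unbiased near the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import InsufficientData, ProfileError
from .segment import CellMask, Contour, CytosolStats

N_BAND_SAMPLES = 7
BAND_INSET_UM = 0.25  # default inward offset of the cortex band (see below)


@dataclass
class MembraneProfile:
    """Per-contour-point membrane intensities for one frame.

    ``raw`` and ``norm`` map channel name → (N,) array; ``norm`` is raw
    divided by the cytosol mean of the same channel, so 1.0 means
    "indistinguishable from cytosolic background".
    """

    raw: dict
    norm: dict
    arc_positions_um: np.ndarray
    arc_spacing_um: float
    band_width_um: float
    frame_index: int = 0
    clipped: bool = False

    @property
    def n_points(self) -> int:
        return len(self.arc_positions_um)

    def channels(self) -> list:
        return list(self.raw)


def sample_membrane(
    image: np.ndarray,
    contour: Contour,
    band_width_um: float,
    *,
    pixel_size_um: float,
    mode: str = "inward",
    n_samples: int = N_BAND_SAMPLES,
    mask: np.ndarray | None = None,
    band_inset_um: float = BAND_INSET_UM,
) -> tuple[np.ndarray, bool]:
    """Mean of bilinear samples along each contour point's normal segment.

    In "inward" mode the band starts ``band_inset_um`` inside the contour
    and extends ``band_width_um`` further inward.  The inset keeps the band
    on the membrane rim even where the segmentation boundary overshoots
    outward, which it systematically does next to very bright membrane
    regions (the threshold crossing of the smoothed image moves outward
    with edge brightness).  Returns ``(values, clipped)`` where ``clipped``
    reports whether any sample fell outside the image (such samples are
    dropped).
    """
    if band_width_um < pixel_size_um:
        raise ProfileError(
            "band_width_um must be at least one pixel "
            f"({band_width_um} < {pixel_size_um})")
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    normals = contour.normals()
    if mode == "inward":
        offsets = np.linspace(-band_inset_um, -band_inset_um - band_width_um,
                              n_samples)
    elif mode == "centered":
        offsets = np.linspace(-0.5 * band_width_um, 0.5 * band_width_um, n_samples)
    else:
        raise ProfileError(f"unknown band mode {mode!r}")
    # (N, S, 2) sample positions in µm
    pos = contour.points[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    cols = pos[..., 0] / pixel_size_um
    rows = pos[..., 1] / pixel_size_um
    inside = (rows >= 0) & (rows <= h - 1) & (cols >= 0) & (cols <= w - 1)
    clipped = bool(np.any(~inside))
    vals = ndimage.map_coordinates(
        image, [rows.ravel(), cols.ravel()], order=1, mode="nearest"
    ).reshape(rows.shape)
    weight = inside.astype(float)
    if mask is not None:
        in_cell = ndimage.map_coordinates(
            np.asarray(mask, dtype=float), [rows.ravel(), cols.ravel()],
            order=1, mode="constant", cval=0.0,
        ).reshape(rows.shape)
        weight = weight * (in_cell >= 0.5)
    wsum = weight.sum(axis=1)
    # if every sample of a point was excluded, fall back to all in-image ones
    fallback = wsum == 0
    if np.any(fallback):
        weight[fallback] = inside[fallback].astype(float)
        wsum = weight.sum(axis=1)
        wsum[wsum == 0] = 1.0
    values = (vals * weight).sum(axis=1) / wsum
    return values, clipped


def membrane_profile(
    frame: np.ndarray,
    contour: Contour,
    cyto: CytosolStats,
    band_width_um: float,
    *,
    channel_names,
    pixel_size_um: float,
    mode: str = "inward",
    cell: CellMask | None = None,
    band_inset_um: float = BAND_INSET_UM,
) -> MembraneProfile:
    """Sample every channel of a (C, H, W) frame into a MembraneProfile."""
    raw = {}
    norm = {}
    clipped = False
    for ci, name in enumerate(channel_names):
        vals, clip = sample_membrane(
            frame[ci], contour, band_width_um,
            pixel_size_um=pixel_size_um, mode=mode,
            mask=cell.mask if cell is not None else None,
            band_inset_um=band_inset_um)
        raw[name] = vals
        norm[name] = vals / cyto.mean[ci]
        clipped = clipped or clip
    n = contour.n_points
    return MembraneProfile(
        raw=raw,
        norm=norm,
        arc_positions_um=np.arange(n) * contour.arc_spacing_um,
        arc_spacing_um=contour.arc_spacing_um,
        band_width_um=band_width_um,
        frame_index=contour.frame_index,
        clipped=clipped,
    )


@dataclass
class JointHistogram:
    """2D histogram of two pooled per-point quantities plus correlations."""

    counts: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray
    pearson_r: float
    spearman_rho: float
    n_points: int
    degenerate: bool = False  # constant input: correlation undefined


def joint_histogram(a, b, bins: int = 40, value_range=None) -> JointHistogram:
    """Joint distribution + Pearson/Spearman correlation of paired samples.

    Constant inputs leave the correlations as NaN with ``degenerate=True``
    (never silently zero).  Supports pooling: pass concatenated arrays.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise InsufficientData("inputs must have equal length")
    if a.size < 3:
        raise InsufficientData("need at least 3 points")
    counts, xe, ye = np.histogram2d(a, b, bins=bins, range=value_range)
    degenerate = bool(np.ptp(a) == 0 or np.ptp(b) == 0)
    if degenerate:
        r = rho = float("nan")
    else:
        r = float(stats.pearsonr(a, b).statistic)
        rho = float(stats.spearmanr(a, b).statistic)
    return JointHistogram(
        counts=counts, x_edges=xe, y_edges=ye,
        pearson_r=r, spearman_rho=rho,
        n_points=int(a.size), degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# I/O: long-format CSV
# ---------------------------------------------------------------------------


def profiles_to_csv(profiles: list[MembraneProfile], path: str | Path) -> None:
    rows = []
    for p in profiles:
        for channel in p.channels():
            raw = p.raw[channel]
            norm = p.norm[channel]
            for i in range(p.n_points):
                rows.append({
                    "frame": p.frame_index, "point_index": i, "channel": channel,
                    "arc_um": p.arc_positions_um[i],
                    "raw": raw[i], "normalized": norm[i],
                })
    pd.DataFrame(rows).to_csv(path, index=False)


def profiles_from_csv(path: str | Path, band_width_um: float = float("nan")
                      ) -> list[MembraneProfile]:
    df = pd.read_csv(path)
    out = []
    for frame, grp in df.groupby("frame", sort=True):
        raw, norm = {}, {}
        arc = None
        for channel, cg in grp.groupby("channel"):
            cg = cg.sort_values("point_index")
            raw[channel] = cg["raw"].to_numpy()
            norm[channel] = cg["normalized"].to_numpy()
            arc = cg["arc_um"].to_numpy()
        spacing = float(arc[1] - arc[0]) if len(arc) > 1 else 0.0
        out.append(MembraneProfile(
            raw=raw, norm=norm, arc_positions_um=arc,
            arc_spacing_um=spacing, band_width_um=band_width_um,
            frame_index=int(frame),
        ))
    return out
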