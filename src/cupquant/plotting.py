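"""Optional figure output (membrane kymograph, channel joint histogram)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def save_kymograph_png(kym, path: str | Path, title: str = "membrane kymograph"):
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(kym.data, aspect="auto", origin="lower", cmap="magma")
    ax.set_xlabel("frame")
    ax.set_ylabel("membrane position (contour index)")
    ax.set_title(title)
    if kym.closure_frame is not None:
        ax.axvline(kym.closure_frame, color="orange", ls=":")
    fig.colorbar(im, ax=ax, label="normalised intensity")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_joint_histogram_png(hist, path: str | Path,
                             xlabel: str = "patch channel",
                             ylabel: str = "ring channel"):
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.pcolormesh(hist.x_edges, hist.y_edges, hist.counts.T + 1,
                       norm=matplotlib.colors.LogNorm(), cmap="viridis")
    ax.set_xlabel(f"{xlabel} (fold over cytosol)")
    ax.set_ylabel(f"{ylabel} (fold over cytosol)")
    r = hist.pearson_r
    ax.set_title(f"r = {r:.2f} (n = {hist.n_points})")
    fig.colorbar(im, ax=ax, label="count + 1")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_report_figures(outdir: Path, kym=None, channel_hist=None) -> None:
    outdir = Path(outdir)
    if kym is not None:
        save_kymograph_png(kym, outdir / "kymograph.png")
    if channel_hist is not None:
        save_joint_histogram_png(channel_hist, outdir / "joint_histogram.png")
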