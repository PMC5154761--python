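"""Configuration objects for the synthetic generator and the pipeline.

All physical quantities carry their unit in the field name (``_um``, ``_s``,
``_deg``).  Configs round-trip through flat YAML files so every run is
reproducible from its persisted configuration alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import InvalidConfigError

PATCH_CHANNEL = "patch"
RING_CHANNEL = "ring"
CHANNEL_NAMES = (PATCH_CHANNEL, RING_CHANNEL)


@dataclass
class SynthConfig:
    """Parameters of the synthetic two-channel single-cell movie.

    The defaults emulate a vegetative amoeba imaged on a spinning-disk
    confocal: a ~16 µm cell at 0.1 µm/px, 1 s frame interval, a cytosolic
    reporter pool with intense membrane patches (patch channel, e.g. a PIP3
    probe) and narrow accumulations flanking patch edges (ring channel, e.g.
    a SCAR/WAVE reporter), shot + read noise, slow drift and radial
    protrusions, and patch birth/growth/split/closure dynamics.
    """

    image_size_px: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.1
    n_frames: int = 50
    frame_interval_s: float = 1.0

    cell_radius_um: float = 8.0
    membrane_band_um: float = 0.5

    cyto_mean: tuple[float, float] = (100.0, 100.0)  # (patch, ring) channels
    patch_fold: float = 3.0
    patch_fold_cv: float = 0.15  # per-patch lognormal intensity variability
    ring_fold: float = 3.0
    ring_width_um: float = 2.4
    baseline_membrane_fold: float = 1.0
    ring_placement: str = "exterior"  # exterior | interior | coincident

    patch_birth_rate: float = 0.3  # Poisson events / frame, from frame 1 on
    patch_width_deg_mean: float = 50.0
    patch_width_deg_sd: float = 10.0
    patch_lifetime_frames_mean: float = 18.0
    split_probability: float = 0.62
    split_patience_frames: int = 8
    initial_patches: int = 4

    drift_speed_um_s: float = 0.05
    protrusion_amp_um: float = 0.5
    protrusion_freq: float = 0.05  # temporal cycles / frame ("global" mode)
    protrusion_mode: str = "global"  # global | patch | none

    noise_poisson_scale: float = 5.0  # photons per intensity unit (0 = off)
    noise_gauss_sd: float = 2.0  # additive read noise (0 = off)
    seed: int = 0

    def validate(self) -> "SynthConfig":
        h, w = self.image_size_px
        if h < 16 or w < 16:
            raise InvalidConfigError("image_size_px too small")
        if self.n_frames <= 0:
            raise InvalidConfigError("n_frames must be positive")
        for name in (
            "pixel_size_um",
            "frame_interval_s",
            "cell_radius_um",
            "membrane_band_um",
            "patch_fold",
            "ring_fold",
            "ring_width_um",
            "baseline_membrane_fold",
            "patch_width_deg_mean",
            "patch_lifetime_frames_mean",
        ):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be positive")
        if self.patch_birth_rate < 0:
            raise InvalidConfigError("patch_birth_rate must be >= 0")
        if not 0.0 <= self.split_probability <= 1.0:
            raise InvalidConfigError("split_probability must lie in [0, 1]")
        if self.membrane_band_um < 2.0 * self.pixel_size_um:
            raise InvalidConfigError(
                "membrane_band_um must span at least two pixels"
            )
        if self.patch_fold <= 1.0 or self.ring_fold <= 1.0:
            raise InvalidConfigError("patch_fold and ring_fold must exceed 1")
        if min(self.cyto_mean) <= 0:
            raise InvalidConfigError("cyto_mean must be positive per channel")
        if self.ring_placement not in ("exterior", "interior", "coincident"):
            raise InvalidConfigError(f"unknown ring_placement {self.ring_placement!r}")
        if self.protrusion_mode not in ("global", "patch", "none"):
            raise InvalidConfigError(f"unknown protrusion_mode {self.protrusion_mode!r}")
        if self.drift_speed_um_s < 0 or self.protrusion_amp_um < 0:
            raise InvalidConfigError("speeds and amplitudes must be >= 0")
        if self.noise_poisson_scale < 0 or self.noise_gauss_sd < 0:
            raise InvalidConfigError("noise parameters must be >= 0")
        if self.patch_fold_cv < 0:
            raise InvalidConfigError("patch_fold_cv must be >= 0")
        if self.initial_patches < 0:
            raise InvalidConfigError("initial_patches must be >= 0")
        return self

    # -- convenience -------------------------------------------------------
    def replace(self, **kw) -> "SynthConfig":
        return dataclasses.replace(self, **kw).validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["image_size_px"] = list(self.image_size_px)
        d["cyto_mean"] = list(self.cyto_mean)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        if "image_size_px" in d:
            d["image_size_px"] = tuple(int(v) for v in d["image_size_px"])
        if "cyto_mean" in d:
            cm = d["cyto_mean"]
            if isinstance(cm, (int, float)):
                cm = (float(cm), float(cm))
            d["cyto_mean"] = tuple(float(v) for v in cm)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidConfigError(f"unknown SynthConfig fields: {sorted(unknown)}")
        return cls(**d).validate()


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs.

    Either ``movie_path`` points at an existing two-page-per-frame TIFF with a
    YAML metadata sidecar, or (``generate=True``) the movie is produced by the
    synthetic generator from ``synth``.
    """

    synth: SynthConfig = field(default_factory=SynthConfig)
    generate: bool = True
    movie_path: str | None = None

    # channel roles: index into the movie's channel axis
    patch_channel: int = 0
    ring_channel: int = 1

    # stage parameters
    n_contour_points: int = 100
    smooth_sigma_um: float = 0.1
    threshold_method: str = "otsu"
    min_area_px: int = 500
    erosion_margin_um: float = 1.0
    band_width_um: float = 0.5
    band_mode: str = "inward"  # inward | centered
    band_inset_um: float = 0.25
    k_sd: float = 1.0
    min_patch_points: int = 3
    half_width_points: int = 8
    line_length_um: float = 5.0
    gap_tolerance: int = 1

    outdir: str = "cupquant_out"
    seed: int = 0
    figures: bool = False
    log_level: str = "INFO"

    def validate(self) -> "PipelineConfig":
        if self.patch_channel == self.ring_channel:
            raise InvalidConfigError("patch_channel and ring_channel must differ")
        if self.n_contour_points < 8:
            raise InvalidConfigError("n_contour_points must be >= 8")
        if self.band_width_um <= 0:
            raise InvalidConfigError("band_width_um must be positive")
        if self.band_mode not in ("inward", "centered"):
            raise InvalidConfigError(f"unknown band_mode {self.band_mode!r}")
        if self.min_patch_points < 1:
            raise InvalidConfigError("min_patch_points must be >= 1")
        if self.half_width_points < 3:
            raise InvalidConfigError("half_width_points must be >= 3")
        if self.gap_tolerance < 0:
            raise InvalidConfigError("gap_tolerance must be >= 0")
        if not self.generate and not self.movie_path:
            raise InvalidConfigError("movie_path required when generate is false")
        self.synth.validate()
        return self

    def replace(self, **kw) -> "PipelineConfig":
        return dataclasses.replace(self, **kw).validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synth"] = self.synth.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "synth" in d and d["synth"] is not None:
            d["synth"] = SynthConfig.from_dict(d["synth"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidConfigError(f"unknown PipelineConfig fields: {sorted(unknown)}")
        return cls(**d).validate()


def save_yaml(config: SynthConfig | PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def load_synth_config(path: str | Path) -> SynthConfig:
    return SynthConfig.from_dict(yaml.safe_load(Path(path).read_text()))


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    return PipelineConfig.from_dict(yaml.safe_load(Path(path).read_text()))


def config_hash(config: SynthConfig | PipelineConfig) -> str:
    """Stable SHA-256 over the canonical JSON form of a config.

    Bookkeeping fields that cannot affect the numbers (output location, log
    verbosity) are excluded, so runs of the same analysis hash identically.
    """
    d = config.to_dict()
    for key in ("outdir", "log_level", "figures"):
        d.pop(key, None)
    blob = json.dumps(d, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
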