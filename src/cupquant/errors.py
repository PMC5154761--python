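"""Exception hierarchy for cupquant.

Every stage raises a subclass of :class:`CupquantError` so that the pipeline
driver can attribute failures to a stage instead of swallowing them.
"""


class CupquantError(Exception):
    """Base class for all cupquant errors."""


class InvalidConfigError(CupquantError):
    """A configuration value violates its documented range or invariant."""


class GeometryError(CupquantError):
    """The synthetic cell (radius + protrusion + drift) would leave the image."""


class NoCellFound(CupquantError):
    """Segmentation found no connected component above the minimum area."""


class ContourError(CupquantError):
    """The mask boundary is degenerate (too few boundary pixels)."""


class MarginTooLarge(CupquantError):
    """Eroding the cell mask by the cytosol margin emptied it."""


class ProfileError(CupquantError):
    """Invalid membrane-profile parameters (e.g. zero sampling band)."""


class EmptyDistribution(CupquantError):
    """A summary statistic was requested on an empty collection of patches."""


class EmptyProfileSet(CupquantError):
    """No patch edge had enough clearance to extract a boundary profile."""


class InsufficientData(CupquantError):
    """Too few observations for the requested statistical test."""


class TrackingLost(CupquantError):
    """Frame-to-frame contour correspondence failed (centroid jump too large)."""


class ComparisonError(CupquantError):
    """A metric required for a between-condition comparison is missing."""


class PipelineError(CupquantError):
    """End-to-end run failed; the message carries the stage attribution."""
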