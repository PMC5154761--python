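"""Shared fixtures: analysed synthetic movies reused across test modules.

Movie generation plus per-frame analysis is the expensive part of the
suite, so the standard movies (built from the canonical study conditions
in :mod:`cupquant.experiments`) are session-scoped.
"""

from __future__ import annotations

import pytest

from cupquant.experiments import (
    Bundle,
    build_bundle,
    default_config,
    noise_free_config,
    static_config,
)


@pytest.fixture(scope="session")
def default_movie() -> Bundle:
    """The default study conditions: noisy, motile cell, 50 frames."""
    return build_bundle(default_config(seed=1))


@pytest.fixture(scope="session")
def noise_free_movie() -> Bundle:
    """Noise-free movie with births, splits and closures (100 frames)."""
    return build_bundle(noise_free_config(seed=11))


@pytest.fixture(scope="session")
def static_movie() -> Bundle:
    """Static cell (no drift / protrusion), default noise, 60 frames."""
    return build_bundle(static_config(seed=21))
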