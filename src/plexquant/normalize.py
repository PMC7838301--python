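"""Normalization at the reporter-intensity, peptide-ratio and protein-ratio
levels, and the seven composite strategies built from them.

Reporter-level normalization rescales each channel so that all channel
medians coincide (assuming equal sample amounts across channels); the
common target is the median of the channel medians, a scale-robust choice
that is ratio-neutral — any common target yields identical downstream
ratios.  Ratio-level normalization divides peptide (protein) ratios by
their median so the normalized set has median 1 (assuming most peptides/
proteins are unchanged between channels).
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)


def channel_scaling_factors(
    intensities: np.ndarray,
    channels: Sequence[str],
    target: Optional[float] = None,
) -> np.ndarray:
    """Per-channel multipliers that equalize channel medians.

    ``intensities`` is an (n_psms, n_channels) matrix of the current
    processing stage.  Zero intensities (missing reporters) are excluded
    from the median computation; a channel with no positive intensity at
    all cannot be normalized and is a fatal error.
    """
    intensities = np.asarray(intensities, dtype=float)
    if intensities.ndim != 2 or intensities.shape[1] != len(channels):
        raise ValueError("expected an (n_psms, n_channels) intensity matrix")
    medians = np.empty(len(channels))
    for j, label in enumerate(channels):
        col = intensities[:, j]
        positive = col[col > 0]
        if positive.size == 0:
            raise ValueError(
                f"channel {label} has no positive intensity; cannot normalize"
            )
        medians[j] = np.median(positive)
    if target is None:
        target = float(np.median(medians))
    return target / medians


def normalize_reporter_medians(
    intensities: np.ndarray,
    channels: Sequence[str],
    target: Optional[float] = None,
) -> np.ndarray:
    """Return intensities rescaled so that every channel median equals the
    target (median of channel medians by default)."""
    factors = channel_scaling_factors(intensities, channels, target)
    return np.asarray(intensities, dtype=float) * factors[np.newaxis, :]


def normalize_ratio_set(values: Sequence[float]) -> np.ndarray:
    """Divide a set of ratios by its median so the normalized median is 1.

    An empty set is a no-op with a warning rather than an error.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        logger.warning("normalize_ratio_set called on an empty ratio set; no-op")
        return arr.copy()
    med = float(np.median(arr))
    if med <= 0:
        raise ValueError(f"median ratio must be positive, got {med}")
    return arr / med
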