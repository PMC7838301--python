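"""Precursor signal-to-interference (S2I) estimation and ratio-compression
correction (RCC).

Co-isolated peptides co-fragment with the target and contribute close to
1:1 reporter signal, compressing measured ratios toward 1.  S2I is the
fraction of ion signal inside the precursor isolation window that belongs
to the targeted precursor and its isotope cluster, measured on the MS1
scans flanking the MS2.  RCC treats ``(1 − S2I) × Σ(reporter intensities)``
as the total interference contribution and subtracts it from the reporter
channels.

Key modelling assumption, inherited from the interference model the
correction is built on: the interference noise is split *equally* across
channels, the only split consistent with 1:1-mixed co-isolation.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np

from .model import InterferenceRecord, Spectrum

logger = logging.getLogger(__name__)

ISOTOPE_SPACING = 1.00335  # Th, averagine C13-C12 spacing
DEFAULT_K_MAX = 3
DEFAULT_MATCH_PPM = 10.0


def compute_s2i_single(
    ms1: Spectrum,
    precursor: tuple[float, int],
    window: tuple[float, float],
    k_max: int = DEFAULT_K_MAX,
    match_ppm: float = DEFAULT_MATCH_PPM,
) -> float:
    """S2I of one MS1 scan: precursor-cluster signal over total window signal.

    The numerator sums peaks matching ``target_mz + k·1.00335/charge`` for
    ``k = 0..k_max`` within ``match_ppm`` (and inside the window); the
    denominator sums every peak inside ``[center − width/2, center + width/2]``.
    An empty window returns 1.0 with a warning (nothing observed, nothing to
    subtract).
    """
    target_mz, charge = precursor
    center, width = window
    if width <= 0:
        raise ValueError(f"isolation width must be positive, got {width}")
    if k_max < 0:
        raise ValueError(f"k_max must be >= 0, got {k_max}")
    lo, hi = center - width / 2.0, center + width / 2.0
    i0 = np.searchsorted(ms1.mz, lo, side="left")
    i1 = np.searchsorted(ms1.mz, hi, side="right")
    mz = ms1.mz[i0:i1]
    intensity = ms1.intensity[i0:i1]
    total = float(intensity.sum())
    if total <= 0:
        logger.warning(
            "empty isolation window [%.4f, %.4f] in scan %s; S2I defaults to 1",
            lo,
            hi,
            ms1.scan_id,
        )
        return 1.0
    cluster = np.zeros(mz.size, dtype=bool)
    for k in range(k_max + 1):
        iso_mz = target_mz + k * ISOTOPE_SPACING / max(charge, 1)
        tol = iso_mz * match_ppm * 1e-6
        cluster |= np.abs(mz - iso_mz) <= tol
    signal = float(intensity[cluster].sum())
    return float(np.clip(signal / total, 0.0, 1.0))


def interpolate_s2i(
    s2i_before: float,
    rt_before: float,
    s2i_after: Optional[float],
    rt_after: Optional[float],
    rt_ms2: float,
) -> float:
    """Linear interpolation of S2I in retention time between flanking MS1 scans.

    Falls back to the preceding value when no following MS1 exists (end of
    the run) or the flanks coincide in time.
    """
    if s2i_after is None or rt_after is None:
        return s2i_before
    if rt_after == rt_before:
        return s2i_before
    frac = (rt_ms2 - rt_before) / (rt_after - rt_before)
    frac = min(max(frac, 0.0), 1.0)
    return s2i_before + frac * (s2i_after - s2i_before)


def s2i_for_ms2(
    ms2: Spectrum,
    preceding: Optional[Spectrum],
    following: Optional[Spectrum],
    k_max: int = DEFAULT_K_MAX,
    match_ppm: float = DEFAULT_MATCH_PPM,
) -> InterferenceRecord:
    """Full S2I estimate for one MS2: both flanks, then RT interpolation.

    With no flanking MS1 (or no precursor descriptor) S2I is 1.0 — the
    correction becomes a no-op rather than an error.
    """
    p = ms2.precursor
    if p is None or preceding is None:
        logger.warning(
            "scan %s has no usable precursor/flanking MS1; S2I set to 1 (RCC no-op)",
            ms2.scan_id,
        )
        return InterferenceRecord(ms2.scan_id, 1.0, None, 1.0)
    center = p.isolation_center if p.isolation_center is not None else p.target_mz
    width = p.isolation_width if p.isolation_width is not None else 2.0
    window = (center, width)
    s_before = compute_s2i_single(preceding, (p.target_mz, p.charge), window, k_max, match_ppm)
    s_after = (
        compute_s2i_single(following, (p.target_mz, p.charge), window, k_max, match_ppm)
        if following is not None
        else None
    )
    s2i = interpolate_s2i(
        s_before,
        preceding.retention_time,
        s_after,
        following.retention_time if following is not None else None,
        ms2.retention_time,
    )
    return InterferenceRecord(ms2.scan_id, s_before, s_after, s2i)


def apply_rcc(intensities: np.ndarray, s2i: float) -> np.ndarray:
    """Subtract the inferred co-isolation noise from reporter intensities.

    Total noise is ``(1 − s2i) · Σ intensities``, split equally across
    channels; corrected channels are clamped at zero.
    """
    if not 0.0 <= s2i <= 1.0:
        raise ValueError(f"S2I must lie in [0, 1], got {s2i}")
    intensities = np.asarray(intensities, dtype=float)
    if intensities.size == 0:
        return intensities.copy()
    noise_per_channel = (1.0 - s2i) * intensities.sum() / intensities.size
    return np.maximum(intensities - noise_per_channel, 0.0)
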