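"""Identification filtering, reporter-ion extraction, and impurity correction.

The FDR filter reproduces TPP-style semantics: when records carry q-values
those are compared to the threshold directly; otherwise the model-based FDR
of the top-k records sorted by posterior probability, mean(1 − p), selects
the longest prefix under the threshold.  The same procedure runs
independently at PSM and protein level.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .model import IsotopeImpurityMatrix, ProteinGroup, PSMRecord, Spectrum
from .plexes import ChannelDefinition, check_window_overlap

logger = logging.getLogger(__name__)

DEFAULT_FDR_THRESHOLD = 0.01
DEFAULT_REPORTER_TOLERANCE = 0.002  # Th


def _keep_by_probability(probabilities: Sequence[float], threshold: float) -> int:
    """Longest prefix (after sorting descending) with mean(1 − p) <= threshold."""
    p = np.sort(np.asarray(probabilities, dtype=float))[::-1]
    if p.size == 0:
        return 0
    fdr = np.cumsum(1.0 - p) / np.arange(1, p.size + 1)
    # tolerance absorbs float cancellation in 1 - p at the boundary
    passing = np.nonzero(fdr <= threshold + 1e-12)[0]
    return 0 if passing.size == 0 else int(passing[-1]) + 1


def filter_by_fdr(
    psms: Sequence[PSMRecord],
    proteins: Sequence[ProteinGroup],
    threshold: float = DEFAULT_FDR_THRESHOLD,
) -> tuple[list[PSMRecord], list[ProteinGroup]]:
    """Filter PSMs and protein groups to the given FDR (default 1%).

    Records with q-values are kept when ``q_value <= threshold``; otherwise
    the probability-based estimate applies.  PSMs are additionally dropped
    when every referenced protein fell below the protein-level cut.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"FDR threshold must lie in (0, 1], got {threshold}")

    with_q = [p for p in psms if p.q_value is not None]
    if with_q and len(with_q) == len(psms):
        kept_psms = [p for p in psms if p.q_value <= threshold]
    else:
        if with_q:
            logger.warning(
                "mixed q-value availability: falling back to probabilities for all PSMs"
            )
        order = sorted(psms, key=lambda p: -p.probability)
        k = _keep_by_probability([p.probability for p in order], threshold)
        kept_psms = order[:k]

    order = sorted(proteins, key=lambda g: -g.probability)
    k = _keep_by_probability([g.probability for g in order], threshold)
    kept_proteins = order[:k]

    if proteins:
        kept_accessions = {g.accession for g in kept_proteins}
        before = len(kept_psms)
        kept_psms = [
            p for p in kept_psms if any(r in kept_accessions for r in p.protein_refs)
        ]
        if before != len(kept_psms):
            logger.info(
                "%d PSMs dropped because all their proteins failed the protein-level FDR",
                before - len(kept_psms),
            )
    if not kept_psms:
        logger.warning("no PSM passed the %.3g FDR threshold", threshold)
    return kept_psms, kept_proteins


def extract_reporter_ions(
    spectrum: Spectrum,
    channels: Sequence[ChannelDefinition],
    tol: float = DEFAULT_REPORTER_TOLERANCE,
) -> np.ndarray:
    """Intensity of the most intense peak within ±tol of each reporter m/z.

    Returns an array in channel order; channels with no peak in the window
    get 0.  A tolerance wide enough to make neighbouring channel windows
    overlap is a configuration error.
    """
    if tol <= 0:
        raise ValueError(f"reporter tolerance must be positive, got {tol}")
    check_window_overlap(tuple(channels), tol)
    out = np.zeros(len(channels))
    if spectrum.mz.size == 0:
        return out
    for i, channel in enumerate(channels):
        lo = np.searchsorted(spectrum.mz, channel.reporter_mz - tol, side="left")
        hi = np.searchsorted(spectrum.mz, channel.reporter_mz + tol, side="right")
        if hi > lo:
            out[i] = float(spectrum.intensity[lo:hi].max())
    return out


def correct_impurities(
    raw: np.ndarray, matrix: IsotopeImpurityMatrix
) -> np.ndarray:
    """Invert the channel cross-contamination: solve ``M x = raw``.

    Negative components of the solution (possible when noise exceeds the
    leaked signal) are clamped to zero in a single pass; no non-negative
    refit is attempted.
    """
    raw = np.asarray(raw, dtype=float)
    n = len(matrix.channels)
    if raw.shape != (n,):
        raise ValueError(
            f"intensity vector of length {raw.shape} does not cover the "
            f"{n} channels of plex {matrix.plex_name}"
        )
    cond = np.linalg.cond(matrix.matrix)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(
            f"impurity matrix for {matrix.plex_name} is singular or "
            f"near-singular (condition number {cond:.3g})"
        )
    x = np.linalg.solve(matrix.matrix, raw)
    return np.where(x < 0, 0.0, x)
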