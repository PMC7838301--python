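"""Ratio kernels and the algorithmic-combination lattice.

Ratios between two channels are computed at three levels.  PSM ratios
divide the (corrected) reporter intensities of the two channels.  Four
peptide kernels aggregate a peptide's PSMs:

* ``LinearRegression`` — slope through the origin of numerator vs
  denominator intensities, Σ(x·y)/Σ(x²);
* ``SumPsmIntensity`` — ratio of channel sums;
* ``MedianPsmRatio`` — median of PSM ratios;
* ``WeightedPsmRatio`` — intensity-weighted mean of PSM ratios.

Six protein kernels aggregate either PSM ratios directly
(``SumPsmIntensity``, ``MedianPsmRatio``, ``WeightedPsmRatio``,
``TrimmedMeanPsmRatio``) or peptide ratios computed by the chosen peptide
kernel (``MedianPepRatio``, ``WeightedPepRatio``).  All arithmetic stays on
the linear scale.

A PSM ratio's weight is the summed intensity of the two selected channels
(switchable to the all-channel sum); a peptide's weight is the median of
its PSM weights.
"""

from __future__ import annotations

import itertools
import logging
import math
from typing import Iterable, Optional, Sequence

import numpy as np

from .model import (
    NORMALIZATION_STRATEGIES,
    PEPTIDE_KERNELS,
    PROTEIN_KERNELS,
    AlgorithmCombination,
    ChannelPair,
    RatioValue,
    ReporterProfile,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Elementary kernels
# ---------------------------------------------------------------------------

def psm_ratio(
    profile: ReporterProfile,
    pair: ChannelPair,
    stage: str = "impurity_corrected",
    weight_mode: str = "pair",
) -> Optional[RatioValue]:
    """Ratio of the two selected channels of one PSM, or None when undefined.

    Undefined (and excluded from every aggregate) when either channel's
    intensity is not strictly positive.
    """
    vec = profile.stage(stage)
    try:
        i = profile.channels.index(pair.numerator)
        j = profile.channels.index(pair.denominator)
    except ValueError as exc:
        raise ValueError(f"pair {pair} not in plex channels {profile.channels}") from exc
    num, den = float(vec[i]), float(vec[j])
    if num <= 0 or den <= 0:
        return None
    weight = num + den if weight_mode == "pair" else float(vec.sum())
    return RatioValue(profile.psm_id, "psm", pair, num / den, weight)


def regression_slope_ratio(points: Sequence[tuple[float, float]]) -> Optional[float]:
    """Least-squares slope through the origin, Σ(x·y)/Σ(x²).

    ``points`` are (denominator_intensity, numerator_intensity) pairs.
    Returns None when Σ(x²) = 0 or the slope is not positive.
    """
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    sxx = float(np.dot(x, x))
    if sxx <= 0:
        return None
    slope = float(np.dot(x, y)) / sxx
    return slope if slope > 0 else None


def sum_intensity_ratio(
    pairs: Sequence[tuple[float, float]]
) -> Optional[float]:
    """Ratio of summed numerator to summed denominator intensities."""
    den = sum(p[0] for p in pairs)
    num = sum(p[1] for p in pairs)
    if den <= 0 or num <= 0:
        return None
    return num / den


def median_ratio(values: Sequence[float]) -> Optional[float]:
    """Standard median (mean of central pair for even counts)."""
    if len(values) == 0:
        return None
    return float(np.median(np.asarray(values, dtype=float)))


def weighted_mean_ratio(
    values: Sequence[float], weights: Sequence[float]
) -> Optional[float]:
    """Σ(wᵢ·rᵢ)/Σwᵢ; falls back to the plain mean when all weights vanish."""
    if len(values) == 0:
        return None
    w = np.asarray(weights, dtype=float)
    v = np.asarray(values, dtype=float)
    total = float(w.sum())
    if total <= 0:
        logger.warning("all ratio weights are zero; falling back to unweighted mean")
        return float(v.mean())
    return float(np.dot(w, v) / total)


def trimmed_mean_ratio(values: Sequence[float]) -> Optional[float]:
    """Mean after removing floor(0.2·n) smallest and largest values.

    The floor rule guarantees a non-empty remainder for every n >= 1.
    """
    n = len(values)
    if n == 0:
        return None
    k = math.floor(0.2 * n)
    trimmed = np.sort(np.asarray(values, dtype=float))[k : n - k]
    return float(trimmed.mean())


def peptide_weight(psm_weights: Sequence[float]) -> Optional[float]:
    """A peptide ratio's weight: the median of its PSM weights."""
    if len(psm_weights) == 0:
        return None
    return float(np.median(np.asarray(psm_weights, dtype=float)))


# ---------------------------------------------------------------------------
# Kernel dispatch over grouped PSM data
# ---------------------------------------------------------------------------

def apply_peptide_kernel(
    kernel: str,
    intensity_pairs: Sequence[tuple[float, float]],
) -> Optional[tuple[float, float, int]]:
    """Peptide ratio from its PSMs' (den, num) intensity pairs.

    Returns (ratio, weight, n_psms) or None when undefined.  The weight is
    the median of the PSM pair-sums, shared by every kernel.
    """
    usable = [(d, n) for d, n in intensity_pairs if d > 0 and n > 0]
    if kernel == "LinearRegression":
        # regression admits points with one zero channel; require at least
        # one positive denominator
        points = [(d, n) for d, n in intensity_pairs if d > 0 or n > 0]
        ratio = regression_slope_ratio(points) if points else None
    elif kernel == "SumPsmIntensity":
        ratio = sum_intensity_ratio(usable)
    elif kernel == "MedianPsmRatio":
        ratio = median_ratio([n / d for d, n in usable])
    elif kernel == "WeightedPsmRatio":
        ratio = weighted_mean_ratio(
            [n / d for d, n in usable], [n + d for d, n in usable]
        )
    else:
        raise ValueError(f"unknown peptide kernel {kernel!r}")
    if ratio is None or ratio <= 0:
        return None
    support = usable if usable else intensity_pairs
    weight = peptide_weight([d + n for d, n in support])
    return ratio, float(weight), len(support)


def apply_protein_kernel(
    kernel: str,
    peptide_kernel: str,
    psm_pairs_by_peptide: dict[str, list[tuple[float, float]]],
) -> Optional[tuple[float, int]]:
    """Protein ratio from its PSMs grouped by peptide.

    PSM-level kernels pool every PSM of the protein and ignore the peptide
    kernel; peptide-level kernels first reduce each peptide with
    ``peptide_kernel`` and then aggregate the peptide ratios.  Returns
    (ratio, n_support) or None.
    """
    if kernel in ("SumPsmIntensity", "MedianPsmRatio", "WeightedPsmRatio", "TrimmedMeanPsmRatio"):
        pooled = [p for pairs in psm_pairs_by_peptide.values() for p in pairs]
        usable = [(d, n) for d, n in pooled if d > 0 and n > 0]
        if kernel == "SumPsmIntensity":
            ratio = sum_intensity_ratio(usable)
        elif kernel == "MedianPsmRatio":
            ratio = median_ratio([n / d for d, n in usable])
        elif kernel == "WeightedPsmRatio":
            ratio = weighted_mean_ratio(
                [n / d for d, n in usable], [n + d for d, n in usable]
            )
        else:
            ratio = trimmed_mean_ratio([n / d for d, n in usable])
        if ratio is None or ratio <= 0:
            return None
        return ratio, len(usable)

    if kernel in ("MedianPepRatio", "WeightedPepRatio"):
        peptide_results = []
        for pairs in psm_pairs_by_peptide.values():
            result = apply_peptide_kernel(peptide_kernel, pairs)
            if result is not None:
                peptide_results.append(result)
        if not peptide_results:
            return None
        values = [r for r, _, _ in peptide_results]
        if kernel == "MedianPepRatio":
            ratio = median_ratio(values)
        else:
            ratio = weighted_mean_ratio(values, [w for _, w, _ in peptide_results])
        if ratio is None or ratio <= 0:
            return None
        return ratio, len(peptide_results)

    raise ValueError(f"unknown protein kernel {kernel!r}")


# ---------------------------------------------------------------------------
# Combination lattice
# ---------------------------------------------------------------------------

def enumerate_combinations(
    allowed_normalizations: Iterable[str] = NORMALIZATION_STRATEGIES,
) -> list[AlgorithmCombination]:
    """The full cross product of 4 peptide kernels x 6 protein kernels x
    allowed normalization strategies x {RCC off, on}, in deterministic order.

    With all seven strategies this yields the complete 336-point lattice;
    restricting to ``{"none"}`` yields the 48 combinations applicable when
    channel amounts are deliberately unequal.
    """
    allowed = [n for n in NORMALIZATION_STRATEGIES if n in set(allowed_normalizations)]
    if not allowed:
        raise ValueError("allowed_normalizations must name at least one strategy")
    return [
        AlgorithmCombination(pep, prot, norm, rcc)
        for pep, prot, norm, rcc in itertools.product(
            PEPTIDE_KERNELS, PROTEIN_KERNELS, allowed, (False, True)
        )
    ]


def fixed_design_combinations() -> list[AlgorithmCombination]:
    """The 12-combination design: six protein kernels x RCC toggle, with the
    peptide-ratio-based kernels fixed to MedianPepRatio-LinearRegression and
    WeightedPepRatio-WeightedPsmRatio, normalization disabled."""
    chosen_peptide = {
        "MedianPepRatio": "LinearRegression",
        "WeightedPepRatio": "WeightedPsmRatio",
    }
    combos = []
    for protein_kernel in PROTEIN_KERNELS:
        peptide_kernel = chosen_peptide.get(protein_kernel, "LinearRegression")
        for rcc in (False, True):
            combos.append(
                AlgorithmCombination(peptide_kernel, protein_kernel, "none", rcc)
            )
    return combos


def protein_equivalence_key(combination: AlgorithmCombination) -> tuple:
    """Key under which combinations produce identical protein-level output.

    The four PSM-level protein kernels ignore the peptide kernel entirely,
    so their protein tables coincide across the four peptide kernels; with
    all seven normalizations this collapses 336 combinations to
    (4 + 2·4) × 14 = 168 distinct protein outputs.
    """
    peptide_dependent = combination.protein_kernel in ("MedianPepRatio", "WeightedPepRatio")
    return (
        combination.protein_kernel,
        combination.peptide_kernel if peptide_dependent else None,
        combination.normalization,
        combination.rcc,
    )


def __getattr__(name: str):
    # pipeline orchestration lives in pipeline.py; re-exported here lazily
    # to avoid a circular import
    if name in ("run_pipeline", "sweep", "prepare_dataset"):
        from . import pipeline

        return getattr(pipeline, name)
    raise AttributeError(f"module {__name__!r} has no attribute {name!r}")
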