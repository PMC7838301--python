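"""Accuracy metrics for calculated protein ratios against ideal values.

With ``x_i`` the calculated and ``y_i`` the ideal protein ratios (over all
protein/channel-pair entries, m in total):

* ARE  — average relative error, mean of ``|x_i − y_i| / y_i``; restricted
  to the standard (spiked, fold-changing) or background (unchanged)
  protein classes it becomes ARE_Std / ARE_Bg;
* RMSE — ``sqrt(Σ(x_i − y_i)² / m)``;
* AUCCD — area under the coverage-vs-deviation curve: coverage(d) is the
  fraction of entries whose relative deviation is ≤ d, integrated over
  d ∈ [0, 1] (trapezoidal, normalized by the range so a perfect result
  scores 1).

Differential-candidate lists (entities with at least one ratio above a
fold-change threshold) are compared with the Jaccard index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import ChannelPair

logger = logging.getLogger(__name__)

DEFAULT_AUCCD_STEP = 0.01
DEFAULT_FOLD_CHANGE_THRESHOLD = 1.5


@dataclass
class EvaluationInput:
    """Paired calculated/ideal protein ratios with protein classes."""

    entity_ids: list[str]
    x: np.ndarray  # calculated
    y: np.ndarray  # ideal
    classes: list[str]

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.entity_ids) == self.x.size == self.y.size == len(self.classes)):
            raise ValueError("entries of EvaluationInput differ in length")
        if np.any(self.y <= 0):
            raise ValueError("ideal ratios must be strictly positive")

    @property
    def m(self) -> int:
        return int(self.x.size)

    def filtered(self, class_filter: Optional[str]) -> "EvaluationInput":
        if class_filter is None:
            return self
        keep = [i for i, c in enumerate(self.classes) if c == class_filter]
        return EvaluationInput(
            [self.entity_ids[i] for i in keep],
            self.x[keep],
            self.y[keep],
            [self.classes[i] for i in keep],
        )


def are(input: EvaluationInput, class_filter: Optional[str] = None) -> float:
    """Average relative error, mean of |x−y|/y (optionally per class)."""
    sub = input.filtered(class_filter)
    if sub.m == 0:
        raise ValueError(f"no entries left after class filter {class_filter!r}")
    return float(np.mean(np.abs(sub.x - sub.y) / sub.y))


def rmse(input: EvaluationInput) -> float:
    """Root mean square error, sqrt(Σ(x−y)²/m)."""
    if input.m == 0:
        raise ValueError("RMSE undefined for an empty input")
    return float(np.sqrt(np.mean((input.x - input.y) ** 2)))


def coverage_at_deviation(input: EvaluationInput, d: float) -> float:
    """Fraction of entries with relative deviation |x−y|/y ≤ d."""
    if input.m == 0:
        raise ValueError("coverage undefined for an empty input")
    if not 0.0 <= d <= 1.0:
        raise ValueError(f"deviation must lie in [0,1], got {d}")
    deviation = np.abs(input.x - input.y) / input.y
    return float(np.mean(deviation <= d))


def auccd(input: EvaluationInput, step: float = DEFAULT_AUCCD_STEP) -> float:
    """Area under the coverage-vs-deviation curve over d ∈ [0, 1].

    Trapezoidal integration on a uniform grid of the given spacing,
    normalized by the unit range.
    """
    if input.m == 0:
        raise ValueError("AUCCD undefined for an empty input")
    if not 0.0 < step <= 0.1:
        raise ValueError(f"step must lie in (0, 0.1], got {step}")
    grid = np.linspace(0.0, 1.0, int(round(1.0 / step)) + 1)
    deviation = np.abs(input.x - input.y) / input.y
    coverage = np.array([np.mean(deviation <= d) for d in grid])
    return float(np.trapezoid(coverage, grid) / 1.0)


def summarize(
    input: EvaluationInput, ideal_value: float
) -> tuple[float, Optional[float]]:
    """Mean and sample SD (n−1) of calculated ratios whose ideal equals
    ``ideal_value``; SD is None with fewer than two entries."""
    mask = input.y == ideal_value
    values = input.x[mask]
    if values.size == 0:
        raise ValueError(f"no entries with ideal ratio {ideal_value}")
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size >= 2 else None
    return mean, sd


def select_differential(
    protein_ratios: Mapping[str, Iterable[float]],
    threshold: float = DEFAULT_FOLD_CHANGE_THRESHOLD,
    symmetric: bool = False,
) -> set[str]:
    """Entities with at least one ratio above the fold-change threshold.

    The literal rule selects on ``max(ratios) > threshold`` only; with
    ``symmetric=True`` down-regulation (``min(ratios) < 1/threshold``) also
    selects — off by default.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    selected = set()
    for entity, ratios in protein_ratios.items():
        values = [r for r in ratios if r is not None and np.isfinite(r)]
        if not values:
            continue
        if max(values) > threshold:
            selected.add(entity)
        elif symmetric and min(values) < 1.0 / threshold:
            selected.add(entity)
    return selected


def jaccard(list_a: Iterable[str], list_b: Iterable[str]) -> float:
    """|A ∩ B| / |A ∪ B|; undefined when both sets are empty."""
    a, b = set(list_a), set(list_b)
    union = a | b
    if not union:
        raise ValueError("Jaccard index undefined for two empty sets")
    return len(a & b) / len(union)


# ---------------------------------------------------------------------------
# Ground truth plumbing
# ---------------------------------------------------------------------------

@dataclass
class ProteinTruthTable:
    """Ideal per-pair protein ratios and protein classes."""

    classes: dict[str, str]  # accession -> class
    ideals: dict[str, dict[str, float]]  # accession -> pair -> ideal ratio

    def ideal(self, accession: str, pair: str) -> Optional[float]:
        return self.ideals.get(accession, {}).get(pair)


def read_ground_truth(path: str) -> ProteinTruthTable:
    """Read a ground-truth TSV: accession, class, then ``ratio_<num>/<den>``
    columns with ideal ratios."""
    df = pd.read_csv(path, sep="\t", dtype={"accession": str, "class": str})
    ratio_cols = [c for c in df.columns if c.startswith("ratio_")]
    if "accession" not in df.columns or "class" not in df.columns or not ratio_cols:
        raise ValueError(
            f"ground truth {path} needs accession, class and ratio_* columns"
        )
    classes, ideals = {}, {}
    for _, row in df.iterrows():
        acc = str(row["accession"])
        classes[acc] = str(row["class"])
        ideals[acc] = {
            c[len("ratio_"):]: float(row[c])
            for c in ratio_cols
            if not pd.isna(row[c])
        }
    return ProteinTruthTable(classes=classes, ideals=ideals)


def write_ground_truth(truth: ProteinTruthTable, path: str) -> None:
    pairs = sorted({p for d in truth.ideals.values() for p in d})
    rows = []
    for acc in sorted(truth.ideals):
        row = {"accession": acc, "class": truth.classes.get(acc, "standard")}
        for pair in pairs:
            row[f"ratio_{pair}"] = truth.ideals[acc].get(pair)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def build_evaluation_input(
    protein_values: Mapping[str, Mapping[str, float]],
    truth: ProteinTruthTable,
    pairs: Sequence[ChannelPair],
) -> EvaluationInput:
    """Pair calculated protein ratios with their ideal values across pairs."""
    ids, xs, ys, classes = [], [], [], []
    for acc in sorted(protein_values):
        for pair in pairs:
            pkey = str(pair)
            x = protein_values[acc].get(pkey)
            y = truth.ideal(acc, pkey)
            if x is None or y is None:
                continue
            ids.append(f"{acc}|{pkey}")
            xs.append(x)
            ys.append(y)
            classes.append(truth.classes.get(acc, "standard"))
    return EvaluationInput(ids, np.asarray(xs), np.asarray(ys), classes)
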