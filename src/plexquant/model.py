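"""Core data model: spectra, identifications, reporter profiles, ratios.

These containers are deliberately light — plain dataclasses over numpy
arrays — so that every processing stage (raw, impurity-corrected,
interference-corrected, normalized) is explicit and inspectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

PEPTIDE_KERNELS = (
    "LinearRegression",
    "SumPsmIntensity",
    "MedianPsmRatio",
    "WeightedPsmRatio",
)

PROTEIN_KERNELS = (
    "SumPsmIntensity",
    "MedianPsmRatio",
    "WeightedPsmRatio",
    "TrimmedMeanPsmRatio",
    "MedianPepRatio",
    "WeightedPepRatio",
)

# The seven composite strategies: normalization can act on reporter
# intensities, peptide ratios, and protein ratios; peptide/protein-only
# combinations without the reporter level are offered exactly as this list
# enumerates them.
NORMALIZATION_STRATEGIES = (
    "none",
    "reporter",
    "peptide",
    "protein",
    "reporter+peptide",
    "reporter+protein",
    "reporter+peptide+protein",
)

Stage = Literal["raw", "impurity_corrected", "rcc_corrected", "normalized"]


@dataclass(frozen=True)
class Precursor:
    """MS2 precursor descriptor: what was isolated and from where."""

    target_mz: float
    charge: int = 2
    isolation_center: Optional[float] = None
    isolation_width: Optional[float] = None
    parent_ms1_scan: Optional[str] = None


@dataclass
class Spectrum:
    """One centroided scan.

    ``mz`` and ``intensity`` are parallel arrays sorted by m/z; retention
    time is stored in seconds regardless of the file's units.
    """

    scan_id: str
    ms_level: int
    retention_time: float
    mz: np.ndarray
    intensity: np.ndarray
    precursor: Optional[Precursor] = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays differ in length")
        if np.any(self.intensity < 0):
            raise ValueError(f"negative intensity in scan {self.scan_id}")
        order = np.argsort(self.mz, kind="stable")
        if not np.all(order == np.arange(len(order))):
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]

    @property
    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensity.tolist()))


@dataclass
class PSMRecord:
    """A validated peptide-spectrum match."""

    psm_id: str
    spectrum_ref: str
    peptide_key: str
    charge: int
    protein_refs: list[str]
    probability: float
    q_value: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(
                f"probability {self.probability} outside [0,1] for {self.psm_id}"
            )
        if not self.protein_refs:
            raise ValueError(f"PSM {self.psm_id} has no protein reference")


@dataclass
class ProteinGroup:
    """A protein (group) with its member peptides and posterior probability."""

    accession: str
    member_peptide_keys: set[str]
    probability: float = 1.0
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if not self.member_peptide_keys:
            raise ValueError(f"protein group {self.accession} has no member peptides")


@dataclass
class IsotopeImpurityMatrix:
    """Channel cross-contamination matrix.

    Entry ``matrix[i, j]`` is the fraction of channel ``j``'s true signal
    observed in channel ``i``.  Columns may sum to less than 1 when isotope
    envelopes leak outside the plex.
    """

    plex_name: str
    channels: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.channels)
        if self.matrix.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match {n} channels"
            )
        if np.any(self.matrix < 0):
            raise ValueError("impurity matrix has negative entries")
        colsums = self.matrix.sum(axis=0)
        if np.any(colsums > 1.0 + 1e-9):
            bad = [self.channels[j] for j in np.nonzero(colsums > 1.0 + 1e-9)[0]]
            raise ValueError(f"impurity matrix columns sum above 1: {bad}")

    @property
    def is_identity(self) -> bool:
        return bool(np.allclose(self.matrix, np.eye(len(self.channels))))


@dataclass
class ReporterProfile:
    """Per-PSM channel intensities at each processing stage, plus S2I."""

    psm_id: str
    channels: tuple[str, ...]
    raw: np.ndarray
    impurity_corrected: np.ndarray
    rcc_corrected: Optional[np.ndarray] = None
    normalized: Optional[np.ndarray] = None
    s2i: Optional[float] = None

    def stage(self, name: Stage) -> np.ndarray:
        vec = getattr(self, name)
        if vec is None:
            raise ValueError(f"stage {name!r} not populated for PSM {self.psm_id}")
        return vec


@dataclass
class InterferenceRecord:
    """S2I estimates around one MS2 scan."""

    psm_id: str
    s2i_preceding: float
    s2i_following: Optional[float]
    s2i: float
    window_peak_count: int = 0


@dataclass(frozen=True)
class ChannelPair:
    """Numerator/denominator channel labels of a reported ratio."""

    numerator: str
    denominator: str

    def __post_init__(self) -> None:
        if self.numerator == self.denominator:
            raise ValueError("numerator and denominator channels must differ")

    def __str__(self) -> str:
        return f"{self.numerator}/{self.denominator}"

    @classmethod
    def parse(cls, text: str) -> "ChannelPair":
        num, _, den = text.partition("/")
        if not num or not den:
            raise ValueError(f"cannot parse channel pair {text!r}; expected NUM/DEN")
        return cls(num.strip(), den.strip())


@dataclass
class RatioValue:
    """A ratio at PSM, peptide, or protein level, with its weight and support."""

    entity_id: str
    level: Literal["psm", "peptide", "protein"]
    pair: ChannelPair
    value: float
    weight: float
    n_support: int = 1

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError(f"ratio value must be positive, got {self.value}")
        if self.n_support < 1:
            raise ValueError("n_support must be >= 1")


@dataclass(frozen=True)
class AlgorithmCombination:
    """One point of the configuration lattice: peptide kernel x protein kernel
    x normalization strategy x interference-correction flag."""

    peptide_kernel: str
    protein_kernel: str
    normalization: str
    rcc: bool

    def __post_init__(self) -> None:
        if self.peptide_kernel not in PEPTIDE_KERNELS:
            raise ValueError(f"unknown peptide kernel {self.peptide_kernel!r}")
        if self.protein_kernel not in PROTEIN_KERNELS:
            raise ValueError(f"unknown protein kernel {self.protein_kernel!r}")
        if self.normalization not in NORMALIZATION_STRATEGIES:
            raise ValueError(f"unknown normalization {self.normalization!r}")

    @property
    def combo_id(self) -> str:
        rcc = "enRCC" if self.rcc else "disRCC"
        return f"{self.protein_kernel}-{self.peptide_kernel}-{self.normalization}-{rcc}"

    @property
    def normalization_levels(self) -> frozenset[str]:
        if self.normalization == "none":
            return frozenset()
        return frozenset(self.normalization.split("+"))
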