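"""Self-contained synthetic datasets with known ground truth.

The generator emulates the structure of spiked-standard benchmark designs:
a majority of *background* proteins mixed 1:1 across channels and a set of
*standard* proteins at known, deliberately varied channel abundances.  For
each PSM it produces

* an MS2 scan whose reporter peaks carry ``base × channel abundance ×
  log-normal peak noise``, blended with a flat 1:1 interference component
  contributing exactly ``interference_fraction`` of the summed reporter
  signal, then forward-mixed through the isotope-impurity matrix;
* flanking MS1 scans containing the precursor isotope cluster plus an
  interfering ion sized so that the true S2I equals
  ``1 − interference_fraction``.

The interference component mirrors the correction model's own assumption
(flat 1:1 co-isolation), which makes the correction exactly right in
expectation — model-matched validation, not independent evidence about
real co-isolation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import _mzml
from .evaluate import ProteinTruthTable, write_ground_truth
from .io import write_correction_matrix, write_protein_table, write_psm_table
from .model import (
    AlgorithmCombination,
    ChannelPair,
    IsotopeImpurityMatrix,
    Precursor,
    ProteinGroup,
    PSMRecord,
    Spectrum,
)
from .plexes import plex_channels

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: relative isotope-cluster intensities used for generated precursors (k = 0..3)
_CLUSTER_SHAPE = np.array([0.5, 0.3, 0.15, 0.05])

_ISOTOPE_SPACING = 1.00335


def _rotations(pattern: Sequence[float]) -> tuple[tuple[float, ...], ...]:
    """All cyclic rotations of an abundance pattern (channel-balanced design)."""
    n = len(pattern)
    return tuple(
        tuple(pattern[(j - r) % n] for j in range(n)) for r in range(n)
    )


@dataclass
class SyntheticSpec:
    """Parameters of a generated benchmark dataset.

    Defaults describe a 50-protein spiked-standard design: background
    proteins at 1:1 and one standard protein per cyclic rotation of a
    0.25–4-fold abundance pattern, 3 peptides of 3 PSMs each, 10%
    multiplicative peak noise and no co-isolation interference.  Rotating
    the standard pattern across channels keeps the total amount per channel
    identical, so channel-median normalization remains valid — the balance
    deliberately engineered into spiked-standard benchmark mixtures.

    ``true_ratios`` maps a protein class to one abundance vector or to a
    list of vectors cycled across the class's proteins.
    """

    n_proteins: int = 50
    peptides_per_protein: tuple[int, int] = (3, 3)
    psms_per_peptide: tuple[int, int] = (3, 3)
    plex: str = "TMT-6"
    true_ratios: dict = field(
        default_factory=lambda: {
            "background": (1.0, 1.0, 1.0, 1.0, 1.0, 1.0),
            "standard": _rotations((4.0, 2.0, 1.0, 1.0, 0.5, 0.25)),
        }
    )
    class_counts: Optional[dict[str, int]] = None  # default: see resolved_class_counts
    cv_noise: float = 0.1
    interference_fraction: float = 0.0
    impurity: Optional[IsotopeImpurityMatrix] = None
    seed: int = 42
    base_intensity: float = 1e5

    def __post_init__(self) -> None:
        if not 0.0 <= self.interference_fraction < 1.0:
            raise ValueError("interference_fraction must lie in [0, 1)")
        if self.cv_noise < 0:
            raise ValueError("cv_noise must be non-negative")
        n_channels = len(plex_channels(self.plex))
        for cls, vecs in self.true_ratios.items():
            for vec in self.class_patterns(cls):
                if vec.size != n_channels or np.any(vec <= 0):
                    raise ValueError(
                        f"abundance vector for class {cls!r} must be {n_channels} "
                        "strictly positive values"
                    )
        for lo, hi in (self.peptides_per_protein, self.psms_per_peptide):
            if not 1 <= lo <= hi:
                raise ValueError("count ranges must be non-empty with lo >= 1")

    def class_patterns(self, cls: str) -> list[np.ndarray]:
        """The abundance vectors of a class (one, or several cycled)."""
        vecs = self.true_ratios[cls]
        if len(vecs) and np.ndim(vecs[0]) > 0:
            return [np.asarray(v, dtype=float) for v in vecs]
        return [np.asarray(vecs, dtype=float)]

    def resolved_class_counts(self) -> dict[str, int]:
        """Default design: one standard protein per abundance pattern (a full
        rotation set keeps channel loads equal), the rest background."""
        if self.class_counts is not None:
            if sum(self.class_counts.values()) != self.n_proteins:
                raise ValueError("class_counts must sum to n_proteins")
            return dict(self.class_counts)
        n_standard = 0
        if "standard" in self.true_ratios and len(self.true_ratios) > 1:
            n_standard = min(
                len(self.class_patterns("standard")), self.n_proteins - 1
            )
        counts = {"standard": n_standard, "background": self.n_proteins - n_standard}
        return {c: n for c, n in counts.items() if c in self.true_ratios and n > 0}


@dataclass
class GroundTruth:
    """What the generator actually put in: ideal protein ratios, protein
    classes, and each PSM's true S2I."""

    protein_class: dict[str, str]
    abundance: dict[str, np.ndarray]
    channels: tuple[str, ...]
    psm_s2i: dict[str, float]

    def ideal_ratio(self, accession: str, pair: ChannelPair) -> float:
        vec = self.abundance[accession]
        i = self.channels.index(pair.numerator)
        j = self.channels.index(pair.denominator)
        return float(vec[i] / vec[j])

    def truth_table(self, pairs: Sequence[ChannelPair]) -> ProteinTruthTable:
        return ProteinTruthTable(
            classes=dict(self.protein_class),
            ideals={
                acc: {str(p): self.ideal_ratio(acc, p) for p in pairs}
                for acc in self.abundance
            },
        )


@dataclass
class SyntheticDataset:
    spectra: list[Spectrum]
    psms: list[PSMRecord]
    protein_groups: list[ProteinGroup]
    matrix: IsotopeImpurityMatrix
    truth: GroundTruth
    spec: SyntheticSpec


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 multiplicative log-normal noise with the given CV."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=size)


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate spectra, identifications, matrix and ground truth.

    Deterministic under ``spec.seed``.  Scan layout alternates MS1 and MS2
    (one extra trailing MS1), with each MS2's precursor cluster and
    interference ion present in both flanking MS1 scans, so S2I
    interpolation reproduces the designed value exactly.
    """
    rng = np.random.default_rng(spec.seed)
    channel_defs = plex_channels(spec.plex)
    labels = tuple(c.label for c in channel_defs)
    n_chan = len(labels)
    matrix = spec.impurity or IsotopeImpurityMatrix(
        plex_name=spec.plex, channels=labels, matrix=np.eye(n_chan)
    )
    if tuple(matrix.channels) != labels:
        raise ValueError("impurity matrix channels do not match the plex")

    f = spec.interference_fraction
    s2i_true = 1.0 - f

    counts = spec.resolved_class_counts()
    accessions, classes, abundance = [], {}, {}
    i = 0
    for cls in sorted(counts):
        patterns = spec.class_patterns(cls)
        for k in range(counts[cls]):
            acc = f"PROT{i + 1:04d}"
            accessions.append(acc)
            classes[acc] = cls
            abundance[acc] = patterns[k % len(patterns)]
            i += 1

    # peptide inventory: unique synthetic tryptic-looking sequences
    peptides_of: dict[str, list[str]] = {}
    seen: set[str] = set()
    for acc in accessions:
        n_pep = int(rng.integers(spec.peptides_per_protein[0], spec.peptides_per_protein[1] + 1))
        peps = []
        for _ in range(n_pep):
            while True:
                seq = "".join(rng.choice(_AMINO_ACIDS, size=int(rng.integers(8, 13)))) + "K"
                if seq not in seen:
                    seen.add(seq)
                    break
            peps.append(seq)
        peptides_of[acc] = peps

    # precursor m/z grid: consecutive PSMs get windows far apart so the two
    # clusters present in a shared MS1 never pollute each other's window
    mz_grid = 400.0 + 3.1 * np.arange(97)

    # roll the PSM inventory first, then lay out scans
    all_psm_meta = []  # (acc, peptide, precursor_mz, charge, reporter_obs, base)
    psm_no = 0
    for acc in accessions:
        vec = abundance[acc]
        for pep in peptides_of[acc]:
            pep_base = spec.base_intensity * float(rng.lognormal(mean=0.0, sigma=0.5))
            n_psm = int(
                rng.integers(spec.psms_per_peptide[0], spec.psms_per_peptide[1] + 1)
            )
            for _ in range(n_psm):
                base = pep_base * float(rng.lognormal(mean=0.0, sigma=0.3))
                noise = _lognormal_factors(rng, spec.cv_noise, n_chan)
                signal = base * vec * noise
                blended = (1.0 - f) * signal + f * signal.sum() / n_chan
                observed = matrix.matrix @ blended
                precursor_mz = float(mz_grid[psm_no % mz_grid.size])
                all_psm_meta.append((acc, pep, precursor_mz, 2, observed, base))
                psm_no += 1

    def cluster_peaks(precursor_mz: float, charge: int, base: float):
        mz = precursor_mz + np.arange(_CLUSTER_SHAPE.size) * _ISOTOPE_SPACING / charge
        inten = 10.0 * base * _CLUSTER_SHAPE
        if f > 0:
            # one co-isolated ion inside the isolation window, off every
            # isotope position, sized against the *in-window* cluster signal
            # so the measured S2I equals 1 - f exactly (higher isotopologues
            # fall outside the +/-1 Th window and count for neither side)
            in_window = np.abs(mz - precursor_mz) <= 1.0
            signal_in_window = float(inten[in_window].sum())
            mz = np.append(mz, precursor_mz + 0.41)
            inten = np.append(inten, signal_in_window * f / (1.0 - f))
        return mz, inten

    spectra: list[Spectrum] = []
    psms: list[PSMRecord] = []
    psm_s2i: dict[str, float] = {}
    scan_no = 0
    rt = 0.0
    pending_cluster: Optional[tuple[np.ndarray, np.ndarray]] = None

    def append_ms1(clusters) -> str:
        nonlocal scan_no, rt
        scan_no += 1
        rt += 1.0
        if clusters:
            mz = np.concatenate([c[0] for c in clusters])
            inten = np.concatenate([c[1] for c in clusters])
        else:
            mz, inten = np.array([]), np.array([])
        spectra.append(Spectrum(f"scan={scan_no}", 1, rt, mz, inten))
        return spectra[-1].scan_id

    for meta_index, (acc, pep, precursor_mz, charge, observed, base) in enumerate(
        all_psm_meta
    ):
        cluster = cluster_peaks(precursor_mz, charge, base)
        # each MS1 carries the cluster of the MS2 it precedes and the one it
        # follows, so both flanks see the precursor
        parent_id = append_ms1(
            [cluster] + ([pending_cluster] if pending_cluster is not None else [])
        )
        pending_cluster = cluster

        scan_no += 1
        rt += 1.0
        scan_id = f"scan={scan_no}"
        spectra.append(
            Spectrum(
                scan_id,
                2,
                rt,
                np.array([c.reporter_mz for c in channel_defs]),
                np.asarray(observed, dtype=float),
                precursor=Precursor(
                    target_mz=precursor_mz,
                    charge=charge,
                    isolation_center=precursor_mz,
                    isolation_width=2.0,
                    parent_ms1_scan=parent_id,
                ),
            )
        )
        psm_id = f"PSM{meta_index + 1:05d}"
        psms.append(
            PSMRecord(
                psm_id=psm_id,
                spectrum_ref=scan_id,
                peptide_key=pep,
                charge=charge,
                protein_refs=[acc],
                probability=1.0,
            )
        )
        psm_s2i[psm_id] = s2i_true

    # trailing MS1 so the last MS2 has a following flank
    append_ms1([pending_cluster] if pending_cluster is not None else [])

    groups = [
        ProteinGroup(accession=acc, member_peptide_keys=set(peptides_of[acc]), probability=1.0)
        for acc in accessions
    ]
    truth = GroundTruth(
        protein_class=classes, abundance=abundance, channels=labels, psm_s2i=psm_s2i
    )
    return SyntheticDataset(spectra, psms, groups, matrix, truth, spec)


def write_fixture_files(
    dataset: SyntheticDataset,
    out_dir: str,
    pairs: Optional[Sequence[ChannelPair]] = None,
) -> dict[str, str]:
    """Write the dataset in standard formats readable by the io module:
    mzML spectra, PSM and protein TSV tables, matrix CSV, ground-truth TSV
    and per-PSM true S2I."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "spectra": os.path.join(out_dir, "spectra.mzML"),
        "psms": os.path.join(out_dir, "psms.tsv"),
        "proteins": os.path.join(out_dir, "proteins.tsv"),
        "matrix": os.path.join(out_dir, "matrix.csv"),
        "ground_truth": os.path.join(out_dir, "ground_truth.tsv"),
        "psm_truth": os.path.join(out_dir, "psm_truth.tsv"),
    }
    _mzml.write_mzml(dataset.spectra, paths["spectra"])
    write_psm_table(dataset.psms, paths["psms"])
    write_protein_table(dataset.protein_groups, paths["proteins"])
    write_correction_matrix(dataset.matrix, paths["matrix"])
    if pairs is None:
        pairs = default_pairs(dataset.truth.channels)
    write_ground_truth(dataset.truth.truth_table(pairs), paths["ground_truth"])
    pd.DataFrame(
        {
            "psm_id": sorted(dataset.truth.psm_s2i),
            "s2i_true": [dataset.truth.psm_s2i[k] for k in sorted(dataset.truth.psm_s2i)],
        }
    ).to_csv(paths["psm_truth"], sep="\t", index=False)
    return paths


def default_pairs(channels: Sequence[str]) -> list[ChannelPair]:
    """Every channel against the first (the conventional reference channel)."""
    return [ChannelPair(c, channels[0]) for c in channels[1:]]


def compression_curve(
    spec: SyntheticSpec,
    interference_grid: Sequence[float],
    pair: Optional[ChannelPair] = None,
    combination: Optional[AlgorithmCombination] = None,
) -> pd.DataFrame:
    """Median standard-protein ratio with and without interference
    correction across a grid of interference fractions.

    Uncorrected ratios compress toward 1 as the interference fraction
    grows; corrected ratios track the truth while no clamping occurs.
    """
    from .pipeline import prepare_dataset, run_pipeline

    channels = tuple(c.label for c in plex_channels(spec.plex))
    if pair is None:
        pair = ChannelPair(channels[0], channels[-1])
    base = combination or AlgorithmCombination(
        "MedianPsmRatio", "MedianPsmRatio", "none", False
    )
    rows = []
    for f in interference_grid:
        ds = generate_dataset(replace(spec, interference_fraction=float(f)))
        prepared = prepare_dataset(
            ds.spectra, ds.psms, ds.protein_groups, ds.matrix, plex=spec.plex
        )
        values = {}
        for rcc in (False, True):
            combo = AlgorithmCombination(
                base.peptide_kernel, base.protein_kernel, base.normalization, rcc
            )
            result = run_pipeline(prepared, combo, [pair])
            standard = [
                v[str(pair)]
                for acc, v in result.protein_values.items()
                if ds.truth.protein_class.get(acc) == "standard" and str(pair) in v
            ]
            values[rcc] = float(np.median(standard)) if standard else float("nan")
        clamped = bool(np.any((prepared.rcc == 0) & (prepared.corrected > 0)))
        rows.append(
            {
                "interference_fraction": float(f),
                "uncorrected_ratio": values[False],
                "rcc_ratio": values[True],
                "clamping": clamped,
            }
        )
    return pd.DataFrame(rows)
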