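"""End-to-end quantitation: spectra + identifications → PSM/peptide/protein
ratio tables, for a single algorithmic combination or a sweep over many.

Stage order is fixed: reporter extraction → isotope-impurity correction →
interference correction (when enabled) → reporter-level normalization (when
in the strategy) → PSM ratios → peptide ratios (+ peptide-level
normalization) → protein ratios (+ protein-level normalization).

:func:`prepare_dataset` runs every combination-independent stage once;
:func:`sweep` reuses that work across the whole combination lattice.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .interference import apply_rcc, s2i_for_ms2
from .model import (
    AlgorithmCombination,
    ChannelPair,
    IsotopeImpurityMatrix,
    ProteinGroup,
    PSMRecord,
    RatioValue,
    ReporterProfile,
    Spectrum,
)
from .normalize import normalize_ratio_set, normalize_reporter_medians
from .plexes import ChannelDefinition, plex_channels
from .preprocess import (
    DEFAULT_FDR_THRESHOLD,
    DEFAULT_REPORTER_TOLERANCE,
    correct_impurities,
    extract_reporter_ions,
    filter_by_fdr,
)
from .quant import apply_peptide_kernel, median_ratio, weighted_mean_ratio

logger = logging.getLogger(__name__)


@dataclass
class QuantOptions:
    """Tunable parameters of the combination-independent pipeline stages."""

    fdr_threshold: float = DEFAULT_FDR_THRESHOLD
    reporter_tolerance_th: float = DEFAULT_REPORTER_TOLERANCE
    s2i_kmax: int = 3
    s2i_match_ppm: float = 10.0
    unique_peptides_only: bool = True
    require_complete_channels: bool = False
    psm_weight_mode: str = "pair"  # or "all": weight over all channels


@dataclass
class PreparedDataset:
    """Combination-independent intermediate state shared across a sweep."""

    channels: tuple[str, ...]
    psms: list[PSMRecord]
    protein_groups: list[ProteinGroup]
    raw: np.ndarray  # (n_psms, n_channels)
    corrected: np.ndarray
    rcc: np.ndarray
    s2i: np.ndarray
    peptide_of: list[str]
    proteins_of: list[list[str]]  # accessions each PSM contributes to
    scan_of: list[str]
    counts: dict[str, int] = field(default_factory=dict)
    _norm_cache: dict[bool, np.ndarray] = field(default_factory=dict, repr=False)

    def stage_matrix(self, rcc: bool, reporter_norm: bool) -> np.ndarray:
        base = self.rcc if rcc else self.corrected
        if not reporter_norm:
            return base
        if rcc not in self._norm_cache:
            self._norm_cache[rcc] = normalize_reporter_medians(base, self.channels)
        return self._norm_cache[rcc]

    @property
    def profiles(self) -> list[ReporterProfile]:
        return [
            ReporterProfile(
                psm_id=p.psm_id,
                channels=self.channels,
                raw=self.raw[i],
                impurity_corrected=self.corrected[i],
                rcc_corrected=self.rcc[i],
                s2i=float(self.s2i[i]),
            )
            for i, p in enumerate(self.psms)
        ]


_SCAN_NUM = re.compile(r"(\d+)\s*$")


def _scan_number(scan_id: str) -> Optional[str]:
    m = _SCAN_NUM.search(scan_id.replace("scan=", " "))
    return m.group(1).lstrip("0") or "0" if m else None


def _spectrum_index(spectra: Sequence[Spectrum]) -> dict[str, int]:
    index: dict[str, int] = {}
    for i, s in enumerate(spectra):
        index.setdefault(s.scan_id, i)
        num = _scan_number(s.scan_id)
        if num is not None:
            index.setdefault(f"#{num}", i)
    return index


def _lookup_spectrum(index: dict[str, int], ref: str) -> Optional[int]:
    if ref in index:
        return index[ref]
    num = _scan_number(ref)
    if num is not None and f"#{num}" in index:
        return index[f"#{num}"]
    return None


def prepare_dataset(
    spectra: Sequence[Spectrum],
    psms: Sequence[PSMRecord],
    protein_groups: Sequence[ProteinGroup],
    matrix: IsotopeImpurityMatrix,
    plex: Optional[str] = None,
    options: Optional[QuantOptions] = None,
) -> PreparedDataset:
    """Run every combination-independent stage: FDR filtering, reporter
    extraction, impurity correction, S2I estimation and interference
    correction."""
    options = options or QuantOptions()
    plex_name = plex or matrix.plex_name
    channel_defs: tuple[ChannelDefinition, ...] = plex_channels(plex_name)
    labels = tuple(c.label for c in channel_defs)
    if labels != tuple(matrix.channels):
        raise ValueError(
            f"impurity matrix channels {matrix.channels} do not match "
            f"plex {plex_name} channels {labels}"
        )

    kept_psms, kept_groups = filter_by_fdr(psms, protein_groups, options.fdr_threshold)
    counts = {"psms_read": len(psms), "psms_fdr_kept": len(kept_psms)}

    # protein membership for assignment resolution
    kept_accessions = {g.accession for g in kept_groups} if kept_groups else None

    index = _spectrum_index(spectra)
    prev_ms1 = [None] * len(spectra)
    next_ms1 = [None] * len(spectra)
    last = None
    for i, s in enumerate(spectra):
        prev_ms1[i] = last
        if s.ms_level == 1:
            last = i
    nxt = None
    for i in range(len(spectra) - 1, -1, -1):
        next_ms1[i] = nxt
        if spectra[i].ms_level == 1:
            nxt = i

    rows_raw, rows_corr, rows_rcc, s2i_list = [], [], [], []
    final_psms, peptide_of, proteins_of, scan_of = [], [], [], []
    n_missing_spec = n_all_zero = n_incomplete = n_shared = 0

    for psm in kept_psms:
        si = _lookup_spectrum(index, psm.spectrum_ref)
        if si is None or spectra[si].ms_level < 2:
            n_missing_spec += 1
            continue
        ms2 = spectra[si]
        raw = extract_reporter_ions(ms2, channel_defs, options.reporter_tolerance_th)
        if not np.any(raw > 0):
            n_all_zero += 1
            continue
        if options.require_complete_channels and np.any(raw <= 0):
            n_incomplete += 1
            continue
        corrected = correct_impurities(raw, matrix)

        # flanking MS1 scans: the declared parent if resolvable, else the
        # nearest preceding MS1 in scan order
        parent = None
        if ms2.precursor is not None and ms2.precursor.parent_ms1_scan:
            pi = _lookup_spectrum(index, ms2.precursor.parent_ms1_scan)
            if pi is not None:
                parent = spectra[pi]
        if parent is None and prev_ms1[si] is not None:
            parent = spectra[prev_ms1[si]]
        following = spectra[next_ms1[si]] if next_ms1[si] is not None else None
        rec = s2i_for_ms2(
            ms2, parent, following, options.s2i_kmax, options.s2i_match_ppm
        )

        refs = psm.protein_refs
        if kept_accessions is not None:
            refs = [r for r in refs if r in kept_accessions]
        if options.unique_peptides_only and len(set(refs)) > 1:
            n_shared += 1
            assigned: list[str] = []
        else:
            assigned = sorted(set(refs))

        rows_raw.append(raw)
        rows_corr.append(corrected)
        rows_rcc.append(apply_rcc(corrected, rec.s2i))
        s2i_list.append(rec.s2i)
        final_psms.append(psm)
        peptide_of.append(psm.peptide_key)
        proteins_of.append(assigned)
        scan_of.append(ms2.scan_id)

    counts.update(
        psms_no_spectrum=n_missing_spec,
        psms_all_zero_reporters=n_all_zero,
        psms_incomplete_channels=n_incomplete,
        psms_shared_excluded=n_shared,
        psms_quantified=len(final_psms),
    )
    for key in ("psms_no_spectrum", "psms_all_zero_reporters", "psms_incomplete_channels"):
        if counts[key]:
            logger.info("%s: %d", key, counts[key])

    n = len(final_psms)
    k = len(labels)
    shape = (n, k) if n else (0, k)
    return PreparedDataset(
        channels=labels,
        psms=final_psms,
        protein_groups=list(kept_groups),
        raw=np.asarray(rows_raw).reshape(shape),
        corrected=np.asarray(rows_corr).reshape(shape),
        rcc=np.asarray(rows_rcc).reshape(shape),
        s2i=np.asarray(s2i_list, dtype=float),
        peptide_of=peptide_of,
        proteins_of=proteins_of,
        scan_of=scan_of,
        counts=counts,
    )


@dataclass
class QuantResult:
    """Quantitation output at the three levels for one combination."""

    combination: AlgorithmCombination
    pairs: tuple[ChannelPair, ...]
    channels: tuple[str, ...]
    protein_values: dict[str, dict[str, float]]  # accession -> pair -> ratio
    protein_support: dict[str, dict[str, int]]
    peptide_values: dict[str, dict[str, float]]
    peptide_support: dict[str, int]
    peptide_proteins: dict[str, list[str]]
    psm_values: dict[str, dict[str, float]]
    prepared: PreparedDataset
    counts: dict[str, int]

    def _ratio_frame(self, values: dict[str, dict[str, float]], key: str) -> pd.DataFrame:
        ids = sorted(values)
        data: dict[str, list] = {key: ids}
        for pair in self.pairs:
            col = f"ratio_{pair}"
            data[col] = [values[i].get(str(pair)) for i in ids]
        return pd.DataFrame(data)

    @property
    def proteins(self) -> pd.DataFrame:
        df = self._ratio_frame(self.protein_values, "accession")
        pep_count, psm_count = {}, {}
        for pep, idxs in _group(self.prepared.peptide_of).items():
            for acc in set(
                a for i in idxs for a in self.prepared.proteins_of[i]
            ):
                pep_count[acc] = pep_count.get(acc, 0) + 1
                psm_count[acc] = psm_count.get(acc, 0) + len(idxs)
        df.insert(1, "n_peptides", [pep_count.get(a, 0) for a in df["accession"]])
        df.insert(2, "n_psms", [psm_count.get(a, 0) for a in df["accession"]])
        df["normalized"] = self.combination.normalization != "none"
        return df

    @property
    def peptides(self) -> pd.DataFrame:
        df = self._ratio_frame(self.peptide_values, "peptide_key")
        df.insert(
            1,
            "proteins",
            [";".join(self.peptide_proteins.get(p, [])) for p in df["peptide_key"]],
        )
        df.insert(2, "n_psms", [self.peptide_support.get(p, 0) for p in df["peptide_key"]])
        return df

    @property
    def psms(self) -> pd.DataFrame:
        prep = self.prepared
        ids = [p.psm_id for p in prep.psms]
        data: dict[str, list] = {
            "psm_id": ids,
            "peptide_key": list(prep.peptide_of),
            "scan_id": list(prep.scan_of),
        }
        for j, ch in enumerate(prep.channels):
            data[f"raw_{ch}"] = prep.raw[:, j].tolist()
        for j, ch in enumerate(prep.channels):
            data[f"corrected_{ch}"] = prep.corrected[:, j].tolist()
        for j, ch in enumerate(prep.channels):
            data[f"rcc_{ch}"] = prep.rcc[:, j].tolist()
        data["s2i"] = prep.s2i.tolist()
        df = pd.DataFrame(data)
        for pair in self.pairs:
            col = f"ratio_{pair}"
            df[col] = [self.psm_values.get(i, {}).get(str(pair)) for i in ids]
        return df


def _group(keys: Sequence[str]) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {}
    for i, key in enumerate(keys):
        out.setdefault(key, []).append(i)
    return out


def run_pipeline(
    prepared: PreparedDataset,
    combination: AlgorithmCombination,
    pairs: Sequence[ChannelPair],
    options: Optional[QuantOptions] = None,
) -> QuantResult:
    """Compute PSM, peptide and protein ratios for one combination.

    ``prepared`` comes from :func:`prepare_dataset`; RCC and reporter
    normalization select the intensity stage, then the chosen kernels roll
    ratios up, with peptide/protein-level normalization applied to the
    respective ratio sets when the strategy includes them.
    """
    options = options or QuantOptions()
    levels = combination.normalization_levels
    X = prepared.stage_matrix(combination.rcc, "reporter" in levels)
    chan_index = {c: j for j, c in enumerate(prepared.channels)}

    peptide_groups = _group(prepared.peptide_of)
    protein_groups: dict[str, list[int]] = {}
    for i, accs in enumerate(prepared.proteins_of):
        for acc in accs:
            protein_groups.setdefault(acc, []).append(i)

    psm_values: dict[str, dict[str, float]] = {}
    peptide_values: dict[str, dict[str, float]] = {}
    peptide_support: dict[str, int] = {}
    protein_values: dict[str, dict[str, float]] = {}
    protein_support: dict[str, dict[str, int]] = {}
    n_undefined = 0

    for pair in pairs:
        pkey = str(pair)
        ni, di = chan_index[pair.numerator], chan_index[pair.denominator]
        num, den = X[:, ni], X[:, di]
        ok = (num > 0) & (den > 0)
        all_sum = X.sum(axis=1)

        for i, psm in enumerate(prepared.psms):
            if ok[i]:
                psm_values.setdefault(psm.psm_id, {})[pkey] = float(num[i] / den[i])
            else:
                n_undefined += 1

        # peptide level
        pep_ratio: dict[str, float] = {}
        pep_weight: dict[str, float] = {}
        for pep, idxs in peptide_groups.items():
            pairs_dn = [(float(den[i]), float(num[i])) for i in idxs]
            result = apply_peptide_kernel(combination.peptide_kernel, pairs_dn)
            if result is None:
                continue
            value, weight, support = result
            if options.psm_weight_mode == "all":
                usable = [i for i in idxs if ok[i]]
                if usable:
                    weight = float(np.median([all_sum[i] for i in usable]))
            pep_ratio[pep] = value
            pep_weight[pep] = weight
            peptide_support[pep] = max(peptide_support.get(pep, 0), support)
        if "peptide" in levels and pep_ratio:
            keys = sorted(pep_ratio)
            normed = normalize_ratio_set([pep_ratio[k] for k in keys])
            pep_ratio = dict(zip(keys, normed.tolist()))
        for pep, value in pep_ratio.items():
            peptide_values.setdefault(pep, {})[pkey] = value

        # protein level
        prot_ratio: dict[str, float] = {}
        prot_support: dict[str, int] = {}
        psm_level = combination.protein_kernel in (
            "SumPsmIntensity",
            "MedianPsmRatio",
            "WeightedPsmRatio",
            "TrimmedMeanPsmRatio",
        )
        for acc, idxs in protein_groups.items():
            if psm_level:
                usable = [i for i in idxs if ok[i]]
                if not usable:
                    continue
                r = num[usable] / den[usable]
                if combination.protein_kernel == "SumPsmIntensity":
                    value = float(num[usable].sum() / den[usable].sum())
                elif combination.protein_kernel == "MedianPsmRatio":
                    value = float(np.median(r))
                elif combination.protein_kernel == "WeightedPsmRatio":
                    if options.psm_weight_mode == "all":
                        w = all_sum[usable]
                    else:
                        w = num[usable] + den[usable]
                    value = float(np.dot(w, r) / w.sum())
                else:  # TrimmedMeanPsmRatio
                    k = int(0.2 * len(r))
                    value = float(np.sort(r)[k : len(r) - k].mean())
                prot_ratio[acc] = value
                prot_support[acc] = len(usable)
            else:
                peps = sorted({prepared.peptide_of[i] for i in idxs})
                values = [pep_ratio[p] for p in peps if p in pep_ratio]
                weights = [pep_weight[p] for p in peps if p in pep_ratio]
                if not values:
                    continue
                if combination.protein_kernel == "MedianPepRatio":
                    value = median_ratio(values)
                else:  # WeightedPepRatio
                    value = weighted_mean_ratio(values, weights)
                prot_ratio[acc] = float(value)
                prot_support[acc] = len(values)
        if "protein" in levels and prot_ratio:
            keys = sorted(prot_ratio)
            normed = normalize_ratio_set([prot_ratio[k] for k in keys])
            prot_ratio = dict(zip(keys, normed.tolist()))
        for acc, value in prot_ratio.items():
            protein_values.setdefault(acc, {})[pkey] = value
            protein_support.setdefault(acc, {})[pkey] = prot_support[acc]

    peptide_proteins = {
        pep: sorted({a for i in idxs for a in prepared.proteins_of[i]})
        for pep, idxs in peptide_groups.items()
    }
    counts = dict(prepared.counts)
    counts["ratios_undefined"] = n_undefined
    counts["proteins_quantified"] = len(protein_values)
    return QuantResult(
        combination=combination,
        pairs=tuple(pairs),
        channels=prepared.channels,
        protein_values=protein_values,
        protein_support=protein_support,
        peptide_values=peptide_values,
        peptide_support=peptide_support,
        peptide_proteins=peptide_proteins,
        psm_values=psm_values,
        prepared=prepared,
        counts=counts,
    )


def sweep(
    prepared: PreparedDataset,
    combinations: Sequence[AlgorithmCombination],
    pairs: Sequence[ChannelPair],
    truth: "ProteinTruthTable",
    options: Optional[QuantOptions] = None,
) -> pd.DataFrame:
    """Evaluate every combination against ground truth.

    Returns one row per combination with AUCCD, ARE, ARE_Std, ARE_Bg and
    RMSE, in the (stable) order the combinations were supplied.
    """
    from .evaluate import are, auccd, build_evaluation_input, rmse

    rows = []
    for combination in combinations:
        result = run_pipeline(prepared, combination, pairs, options)
        ev = build_evaluation_input(result.protein_values, truth, pairs)
        row = {
            "combo_id": combination.combo_id,
            "peptide_kernel": combination.peptide_kernel,
            "protein_kernel": combination.protein_kernel,
            "normalization": combination.normalization,
            "rcc": combination.rcc,
            "n_ratios": ev.m,
            "AUCCD": auccd(ev),
            "ARE": are(ev),
            "RMSE": rmse(ev),
        }
        for cls, name in (("standard", "ARE_Std"), ("background", "ARE_Bg")):
            try:
                row[name] = are(ev, class_filter=cls)
            except ValueError:
                row[name] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
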