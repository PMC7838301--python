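"""Readers and writers: spectra (mzML/mzXML), identifications (pepXML,
protXML, generic PSM tables), isotope-impurity matrices, and result tables.

mzXML, pepXML and protXML go through pyteomics; mzML uses the package's own
lightweight reader (:mod:`plexquant._mzml`).
"""

from __future__ import annotations

import logging
import os
import re
from importlib import resources
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from pyteomics import mzxml as _pyt_mzxml
from pyteomics import pepxml as _pyt_pepxml
from pyteomics import protxml as _pyt_protxml

from . import _mzml
from .model import (
    IsotopeImpurityMatrix,
    Precursor,
    ProteinGroup,
    PSMRecord,
    Spectrum,
)
from .plexes import PLEXES, plex_channels

logger = logging.getLogger(__name__)

DECOY_PREFIX = "DECOY_"

#: Default total isolation width (Th) when the file carries none.
DEFAULT_ISOLATION_WIDTH = 2.0


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

def _detect_spectra_format(path: str) -> str:
    lower = str(path).lower()
    if lower.endswith(".mzml"):
        return "mzML"
    if lower.endswith(".mzxml"):
        return "mzXML"
    raise ValueError(f"cannot infer spectra format from {path!r}; pass format=")


def read_spectra(
    path: str,
    format: Optional[str] = None,
    default_isolation_width: float = DEFAULT_ISOLATION_WIDTH,
) -> list[Spectrum]:
    """Read an mzML or mzXML file into :class:`Spectrum` records in scan order.

    MS2 spectra carry precursor descriptors; when the file lacks isolation
    window metadata the width defaults to ``default_isolation_width`` Th
    centered on the precursor m/z.  MS2 scans without any precursor
    information are kept (flagged with ``precursor=None``); they are excluded
    from interference estimation but not from quantitation.
    """
    fmt = format or _detect_spectra_format(path)
    if fmt == "mzML":
        spectra = list(_mzml.read_mzml(path, default_isolation_width))
    elif fmt == "mzXML":
        spectra = _read_mzxml(path, default_isolation_width)
    else:
        raise ValueError(f"unknown spectra format {fmt!r}")
    if not spectra:
        logger.warning("no spectra found in %s", path)
    n_flagged = sum(1 for s in spectra if s.ms_level >= 2 and s.precursor is None)
    if n_flagged:
        logger.warning(
            "%d MS2 spectra in %s lack precursor metadata; "
            "they are excluded from interference correction",
            n_flagged,
            path,
        )
    return spectra


def _read_mzxml(path: str, default_isolation_width: float) -> list[Spectrum]:
    spectra: list[Spectrum] = []
    last_ms1: Optional[str] = None
    with _pyt_mzxml.read(str(path)) as reader:
        for scan in reader:
            scan_id = str(scan["num"])
            ms_level = int(scan["msLevel"])
            rt = scan.get("retentionTime", float("nan"))
            unit = getattr(rt, "unit_info", "minute")
            rt_s = float(rt) * 60.0 if str(unit).startswith("minute") else float(rt)
            precursor = None
            if ms_level >= 2:
                pmz_list = scan.get("precursorMz") or []
                if pmz_list:
                    p = pmz_list[0]
                    mz = float(p["precursorMz"])
                    # mzXML has no explicit isolation metadata: center at the
                    # precursor m/z with the configured default width.
                    precursor = Precursor(
                        target_mz=mz,
                        charge=int(p.get("precursorCharge", 2)),
                        isolation_center=mz,
                        isolation_width=default_isolation_width,
                        parent_ms1_scan=last_ms1,
                    )
            else:
                last_ms1 = scan_id
            spectra.append(
                Spectrum(
                    scan_id=scan_id,
                    ms_level=ms_level,
                    retention_time=rt_s,
                    mz=scan["m/z array"],
                    intensity=scan["intensity array"],
                    precursor=precursor,
                )
            )
    return spectra


# ---------------------------------------------------------------------------
# Identifications
# ---------------------------------------------------------------------------

def _hit_probability(hit: dict) -> Optional[float]:
    """Posterior from the latest analysis present: iProphet wins over
    PeptideProphet when both were run."""
    results = {r.get("analysis"): r for r in hit.get("analysis_result", [])}
    for analysis in ("interprophet", "peptideprophet"):
        entry = results.get(analysis)
        if entry is None:
            continue
        for value in entry.values():
            if isinstance(value, dict) and "probability" in value:
                return float(value["probability"])
    return None


def read_pepxml(path: str) -> list[PSMRecord]:
    """Read validated PSMs from a pepXML file (one record per top-ranked hit)."""
    records: list[PSMRecord] = []
    n_skipped = 0
    with _pyt_pepxml.read(str(path)) as reader:
        for query in reader:
            hits = query.get("search_hit") or []
            top = min(hits, key=lambda h: h.get("hit_rank", 1), default=None)
            if top is None:
                continue
            probability = _hit_probability(top)
            if probability is None:
                n_skipped += 1
                continue
            proteins = [p["protein"] for p in top.get("proteins", [])]
            peptide_key = top.get("modified_peptide") or top["peptide"]
            spectrum = query.get("spectrum", "")
            start_scan = query.get("start_scan")
            records.append(
                PSMRecord(
                    psm_id=spectrum or f"scan_{start_scan}",
                    spectrum_ref=str(start_scan) if start_scan is not None else spectrum,
                    peptide_key=peptide_key,
                    charge=int(query.get("assumed_charge", 2)),
                    protein_refs=proteins,
                    probability=probability,
                )
            )
    if n_skipped:
        logger.warning(
            "%d hits in %s lacked an analysis probability and were excluded",
            n_skipped,
            path,
        )
    return records


def read_protxml(path: str) -> list[ProteinGroup]:
    """Read protein groups (leader accession, member peptides, probability)."""
    groups: list[ProteinGroup] = []
    with _pyt_protxml.read(str(path)) as reader:
        for group in reader:
            proteins = group.get("protein") or []
            if not proteins:
                continue
            leader = proteins[0]
            peptides = {
                p["peptide_sequence"]
                for protein in proteins
                for p in protein.get("peptide", [])
            }
            accession = leader["protein_name"]
            groups.append(
                ProteinGroup(
                    accession=accession,
                    member_peptide_keys=peptides,
                    probability=float(group.get("probability", leader.get("probability", 0.0))),
                    is_decoy=accession.startswith(DECOY_PREFIX),
                )
            )
    return groups


_PSM_TABLE_COLUMNS = ("psm_id", "scan_id", "peptide", "charge", "proteins", "probability")


def read_psm_table(path: str) -> list[PSMRecord]:
    """Read PSMs from a generic tab-separated table.

    Mandatory columns: psm_id, scan_id, peptide, charge, proteins
    (``;``-separated accessions), probability.  Optional: q_value.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in _PSM_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"PSM table {path} is missing mandatory columns: {missing}")
    has_q = "q_value" in df.columns
    records = []
    for row in df.itertuples(index=False):
        records.append(
            PSMRecord(
                psm_id=str(row.psm_id),
                spectrum_ref=str(row.scan_id),
                peptide_key=str(row.peptide),
                charge=int(row.charge),
                protein_refs=[p for p in str(row.proteins).split(";") if p],
                probability=float(row.probability),
                q_value=float(row.q_value)
                if has_q and not pd.isna(row.q_value)
                else None,
            )
        )
    return records


def read_protein_table(path: str) -> list[ProteinGroup]:
    """Read protein groups from a generic tab-separated table.

    Columns: accession, peptides (``;``-separated peptide keys), probability.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in ("accession", "peptides", "probability") if c not in df.columns]
    if missing:
        raise ValueError(f"protein table {path} is missing mandatory columns: {missing}")
    return [
        ProteinGroup(
            accession=str(row.accession),
            member_peptide_keys={p for p in str(row.peptides).split(";") if p},
            probability=float(row.probability),
            is_decoy=str(row.accession).startswith(DECOY_PREFIX),
        )
        for row in df.itertuples(index=False)
    ]


def write_protein_table(groups: Iterable[ProteinGroup], path: str) -> None:
    rows = [
        {
            "accession": g.accession,
            "peptides": ";".join(sorted(g.member_peptide_keys)),
            "probability": g.probability,
        }
        for g in sorted(groups, key=lambda g: g.accession)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_psm_table(psms: Iterable[PSMRecord], path: str) -> None:
    rows = [
        {
            "psm_id": p.psm_id,
            "scan_id": p.spectrum_ref,
            "peptide": p.peptide_key,
            "charge": p.charge,
            "proteins": ";".join(p.protein_refs),
            "probability": p.probability,
            "q_value": p.q_value if p.q_value is not None else "",
        }
        for p in sorted(psms, key=lambda p: p.psm_id)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Isotope-impurity matrices
# ---------------------------------------------------------------------------

_MATRIX_COLUMNS = ("channel", "minus2", "minus1", "plus1", "plus2")


def load_correction_matrix(
    plex_or_path: str, plex_name: Optional[str] = None
) -> IsotopeImpurityMatrix:
    """Load an isotope-impurity matrix from a preset plex name or a CSV file.

    CSV rows are ``channel, minus2, minus1, plus1, plus2`` with impurity
    *percentages* (the fraction of that channel's signal leaking into the
    channel −2/−1/+1/+2 positions away in channel order).  The diagonal is
    ``1 − (sum of the four impurity fractions)``; leaks that fall outside
    the plex are dropped from the matrix but remain subtracted from the
    diagonal, so columns may sum to less than one.

    Loading a preset *name* returns an identity matrix (correction is a
    no-op) with a prominent warning: manufacturer impurity values are
    lot-specific and are never invented here.
    """
    if plex_or_path in PLEXES:
        channels = tuple(c.label for c in plex_channels(plex_or_path))
        logger.warning(
            "preset %s ships no manufacturer impurity values (they are "
            "lot-specific); using the identity matrix — impurity correction "
            "is a NO-OP. Supply your reagent certificate as a CSV.",
            plex_or_path,
        )
        return IsotopeImpurityMatrix(
            plex_name=plex_or_path,
            channels=channels,
            matrix=np.eye(len(channels)),
        )
    if not os.path.exists(plex_or_path):
        raise ValueError(
            f"{plex_or_path!r} is neither a preset plex "
            f"({', '.join(sorted(PLEXES))}) nor an existing CSV file"
        )
    df = pd.read_csv(plex_or_path, comment="#", skipinitialspace=True)
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in _MATRIX_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"correction matrix {plex_or_path} lacks columns {missing}")
    channels = tuple(str(c).strip() for c in df["channel"])
    n = len(channels)
    matrix = np.zeros((n, n))
    for j, row in enumerate(df.itertuples(index=False)):
        fractions = {}
        for col, offset in (("minus2", -2), ("minus1", -1), ("plus1", 1), ("plus2", 2)):
            pct = float(getattr(row, col))
            if pct < 0:
                raise ValueError(
                    f"negative impurity percentage {pct} for channel "
                    f"{channels[j]} in {plex_or_path}"
                )
            fractions[offset] = pct / 100.0
        matrix[j, j] = 1.0 - sum(fractions.values())
        for offset, frac in fractions.items():
            i = j + offset
            if 0 <= i < n:
                matrix[i, j] = frac
            # else: leak outside the plex — dropped, but already subtracted
            # from the diagonal above
    return IsotopeImpurityMatrix(
        plex_name=plex_name or os.path.splitext(os.path.basename(plex_or_path))[0],
        channels=channels,
        matrix=matrix,
    )


def write_correction_matrix(matrix: IsotopeImpurityMatrix, path: str) -> None:
    """Write a matrix back to the minus2/minus1/plus1/plus2 CSV layout.

    Only the ±1/±2 off-diagonals representable in that layout are written;
    the file round-trips through :func:`load_correction_matrix` for any
    matrix that was loaded from this layout.
    """
    n = len(matrix.channels)
    offsets = (("minus2", -2), ("minus1", -1), ("plus1", 1), ("plus2", 2))
    rows = []
    for j, channel in enumerate(matrix.channels):
        entry = {"channel": channel}
        inside = 0.0
        outside_cols = []
        for col, offset in offsets:
            i = j + offset
            if 0 <= i < n:
                frac = matrix.matrix[i, j]
                inside += frac
            else:
                frac = 0.0
                outside_cols.append(col)
            entry[col] = 100.0 * frac
        # the diagonal deficit beyond in-plex leaks is mass lost outside the
        # plex; assign it to one out-of-range offset so the file reloads to
        # the same matrix (the split between out-of-range offsets is not
        # recoverable and does not affect the matrix)
        outside = 1.0 - matrix.matrix[j, j] - inside
        if outside > 1e-12:
            if not outside_cols:
                raise ValueError(
                    f"channel {channel}: diagonal deficit {outside:.3g} not "
                    "representable in the +/-2 CSV layout"
                )
            entry[outside_cols[0]] = 100.0 * outside
        rows.append(entry)
    pd.DataFrame(rows).to_csv(path, index=False)


def bundled_example_matrices() -> dict[str, str]:
    """Paths of the bundled *synthetic example* impurity CSVs, one per plex.

    The values are invented-but-plausible percentages for demonstration and
    testing only — real corrections must come from the reagent lot's
    certificate of analysis.
    """
    out = {}
    data_dir = resources.files("plexquant") / "data"
    for entry in data_dir.iterdir():
        name = entry.name
        match = re.match(r"(.+)_synthetic_example\.csv$", name)
        if match:
            out[match.group(1)] = str(entry)
    return out


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def write_quant_tables(result, out_dir: str) -> dict[str, str]:
    """Write proteins.tsv / peptides.tsv / psms.tsv from a pipeline result.

    Row order is deterministic (accession, then peptide key, then PSM id) and
    missing ratios are written as empty cells, so identical inputs produce
    byte-identical files.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name, df, key in (
        ("proteins", result.proteins, "accession"),
        ("peptides", result.peptides, "peptide_key"),
        ("psms", result.psms, "psm_id"),
    ):
        path = os.path.join(out_dir, f"{name}.tsv")
        out = df.sort_values(key, kind="stable").reset_index(drop=True)
        out.to_csv(path, sep="\t", index=False, na_rep="", float_format="%.10g")
        paths[name] = path
    return paths
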