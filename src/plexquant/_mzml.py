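"""Minimal mzML 1.1 reader and writer for centroided MS1/MS2 spectra.

Covers the subset of mzML this package consumes and produces: spectrum
lists with ms level, scan start time, precursor isolation windows and
selected ions, and uncompressed or zlib-compressed 32/64-bit float peak
arrays.  Profile-mode spectra, chromatograms and indexed wrappers are out
of scope (an ``<indexedmzML>`` wrapper around a plain ``<mzML>`` element is
tolerated on read).
"""

from __future__ import annotations

import base64
import struct
import zlib
from typing import Iterator, Optional

import numpy as np
from lxml import etree

from .model import Precursor, Spectrum

_NS = "http://psi.hupo.org/ms/mzml"

# PSI-MS controlled-vocabulary accessions used below
_ACC_MS_LEVEL = "MS:1000511"
_ACC_SCAN_START = "MS:1000016"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_NOCOMP = "MS:1000576"
_ACC_ISO_TARGET = "MS:1000827"
_ACC_ISO_LOWER = "MS:1000828"
_ACC_ISO_UPPER = "MS:1000829"
_ACC_SELECTED_MZ = "MS:1000744"
_ACC_CHARGE = "MS:1000041"


def _cv_params(elem: etree._Element) -> dict[str, etree._Element]:
    return {cv.get("accession"): cv for cv in elem.findall(f"{{{_NS}}}cvParam")}


def _decode_binary(bda: etree._Element, default_length: int) -> np.ndarray:
    params = _cv_params(bda)
    binary = bda.find(f"{{{_NS}}}binary")
    raw = base64.b64decode(binary.text or "")
    if _ACC_ZLIB in params:
        raw = zlib.decompress(raw)
    if _ACC_F32 in params:
        fmt, width = "f", 4
    else:  # 64-bit float is both the explicit and the fallback encoding
        fmt, width = "d", 8
    n = len(raw) // width
    values = struct.unpack(f"<{n}{fmt}", raw[: n * width])
    return np.asarray(values, dtype=float)


def _rt_seconds(scan_elem: etree._Element) -> float:
    for cv in scan_elem.iter(f"{{{_NS}}}cvParam"):
        if cv.get("accession") == _ACC_SCAN_START:
            value = float(cv.get("value"))
            unit = (cv.get("unitName") or "second").lower()
            return value * 60.0 if unit.startswith("minute") else value
    return float("nan")


def _parse_precursor(
    spec_elem: etree._Element, default_isolation_width: float
) -> Optional[Precursor]:
    plist = spec_elem.find(f"{{{_NS}}}precursorList")
    if plist is None:
        return None
    prec = plist.find(f"{{{_NS}}}precursor")
    if prec is None:
        return None
    parent = prec.get("spectrumRef")

    target = center = None
    lower = upper = None
    iso = prec.find(f"{{{_NS}}}isolationWindow")
    if iso is not None:
        params = _cv_params(iso)
        if _ACC_ISO_TARGET in params:
            center = float(params[_ACC_ISO_TARGET].get("value"))
        if _ACC_ISO_LOWER in params:
            lower = float(params[_ACC_ISO_LOWER].get("value"))
        if _ACC_ISO_UPPER in params:
            upper = float(params[_ACC_ISO_UPPER].get("value"))

    charge = 2
    sel_list = prec.find(f"{{{_NS}}}selectedIonList")
    if sel_list is not None:
        sel = sel_list.find(f"{{{_NS}}}selectedIon")
        if sel is not None:
            params = _cv_params(sel)
            if _ACC_SELECTED_MZ in params:
                target = float(params[_ACC_SELECTED_MZ].get("value"))
            if _ACC_CHARGE in params:
                charge = int(float(params[_ACC_CHARGE].get("value")))

    if target is None and center is None:
        return None
    if target is None:
        target = center
    if center is None:
        center = target
    width = (
        lower + upper
        if lower is not None and upper is not None
        else default_isolation_width
    )
    return Precursor(
        target_mz=target,
        charge=charge,
        isolation_center=center,
        isolation_width=width,
        parent_ms1_scan=parent,
    )


def read_mzml(path: str, default_isolation_width: float = 2.0) -> Iterator[Spectrum]:
    """Yield :class:`Spectrum` records from an mzML file in scan order."""
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"cannot parse mzML file {path}: {exc}") from exc
    root = tree.getroot()
    if root.tag == f"{{{_NS}}}indexedmzML":
        root = root.find(f"{{{_NS}}}mzML")
    if root is None or root.tag != f"{{{_NS}}}mzML":
        raise ValueError(f"{path} is not an mzML document")

    for spec_elem in root.iter(f"{{{_NS}}}spectrum"):
        scan_id = spec_elem.get("id")
        params = _cv_params(spec_elem)
        ms_level_param = params.get(_ACC_MS_LEVEL)
        if ms_level_param is None:
            raise ValueError(f"spectrum {scan_id!r} in {path} lacks an ms level")
        ms_level = int(ms_level_param.get("value"))

        n_default = int(spec_elem.get("defaultArrayLength", 0))
        mz = intensity = None
        for bda in spec_elem.iter(f"{{{_NS}}}binaryDataArray"):
            bda_params = _cv_params(bda)
            values = _decode_binary(bda, n_default)
            if _ACC_MZ_ARRAY in bda_params:
                mz = values
            elif _ACC_INT_ARRAY in bda_params:
                intensity = values
        if mz is None or intensity is None:
            raise ValueError(f"spectrum {scan_id!r} in {path} lacks peak arrays")

        yield Spectrum(
            scan_id=scan_id,
            ms_level=ms_level,
            retention_time=_rt_seconds(spec_elem),
            mz=mz,
            intensity=intensity,
            precursor=_parse_precursor(spec_elem, default_isolation_width)
            if ms_level >= 2
            else None,
        )


def _b64(values: np.ndarray) -> str:
    values = np.asarray(values, dtype=float)
    return base64.b64encode(struct.pack(f"<{values.size}d", *values)).decode()


_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>
  </cvList>
  <run id="{run_id}">
    <spectrumList count="{count}">
"""

_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def _spectrum_xml(spectrum: Spectrum, index: int) -> str:
    mz64 = _b64(spectrum.mz)
    int64 = _b64(spectrum.intensity)
    parts = [
        f'      <spectrum index="{index}" id="{spectrum.scan_id}" '
        f'defaultArrayLength="{spectrum.mz.size}">\n',
        f'        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" '
        f'value="{spectrum.ms_level}"/>\n',
        '        <cvParam cvRef="MS" accession="MS:1000127" '
        'name="centroid spectrum" value=""/>\n',
        "        <scanList count=\"1\">\n          <scan>\n",
        f'            <cvParam cvRef="MS" accession="MS:1000016" '
        f'name="scan start time" value="{spectrum.retention_time!r}" '
        f'unitCvRef="UO" unitAccession="UO:0000010" unitName="second"/>\n',
        "          </scan>\n        </scanList>\n",
    ]
    p = spectrum.precursor
    if p is not None:
        ref = f' spectrumRef="{p.parent_ms1_scan}"' if p.parent_ms1_scan else ""
        center = p.isolation_center if p.isolation_center is not None else p.target_mz
        width = p.isolation_width if p.isolation_width is not None else 2.0
        half = width / 2.0
        parts.append(
            f'        <precursorList count="1">\n'
            f"          <precursor{ref}>\n"
            f"            <isolationWindow>\n"
            f'              <cvParam cvRef="MS" accession="MS:1000827" '
            f'name="isolation window target m/z" value="{center!r}"/>\n'
            f'              <cvParam cvRef="MS" accession="MS:1000828" '
            f'name="isolation window lower offset" value="{half!r}"/>\n'
            f'              <cvParam cvRef="MS" accession="MS:1000829" '
            f'name="isolation window upper offset" value="{half!r}"/>\n'
            f"            </isolationWindow>\n"
            f'            <selectedIonList count="1">\n'
            f"              <selectedIon>\n"
            f'                <cvParam cvRef="MS" accession="MS:1000744" '
            f'name="selected ion m/z" value="{p.target_mz!r}"/>\n'
            f'                <cvParam cvRef="MS" accession="MS:1000041" '
            f'name="charge state" value="{p.charge}"/>\n'
            f"              </selectedIon>\n"
            f"            </selectedIonList>\n"
            f"            <activation/>\n"
            f"          </precursor>\n"
            f"        </precursorList>\n"
        )
    for accession, name, payload in (
        ("MS:1000514", "m/z array", mz64),
        ("MS:1000515", "intensity array", int64),
    ):
        parts.append(
            f'        <binaryDataArrayList count="2">\n'
            if accession == "MS:1000514"
            else ""
        )
        parts.append(
            f'          <binaryDataArray encodedLength="{len(payload)}">\n'
            f'            <cvParam cvRef="MS" accession="MS:1000523" '
            f'name="64-bit float" value=""/>\n'
            f'            <cvParam cvRef="MS" accession="MS:1000576" '
            f'name="no compression" value=""/>\n'
            f'            <cvParam cvRef="MS" accession="{accession}" '
            f'name="{name}" value=""/>\n'
            f"            <binary>{payload}</binary>\n"
            f"          </binaryDataArray>\n"
        )
    parts.append("        </binaryDataArrayList>\n      </spectrum>\n")
    return "".join(parts)


def write_mzml(spectra: list[Spectrum], path: str, run_id: str = "run1") -> None:
    """Write spectra to a plain (non-indexed) mzML 1.1 file."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_HEADER.format(run_id=run_id, count=len(spectra)))
        for i, spectrum in enumerate(spectra):
            fh.write(_spectrum_xml(spectrum, i))
        fh.write(_FOOTER)
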