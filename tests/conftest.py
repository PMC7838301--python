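"""Shared fixtures: small synthetic datasets and hand-written format fixtures."""

from __future__ import annotations

import base64
import struct
import textwrap

import numpy as np
import pytest

import plexquant as pq


@pytest.fixture(scope="session")
def small_dataset():
    """Six proteins (2 standard at a 2-fold rotation, 4 background), noisy."""
    spec = pq.SyntheticSpec(
        n_proteins=6,
        class_counts={"standard": 2, "background": 4},
        true_ratios={
            "background": (1.0,) * 6,
            "standard": ((2.0, 1.0, 1.0, 1.0, 1.0, 1.0), (1.0, 2.0, 1.0, 1.0, 1.0, 1.0)),
        },
        cv_noise=0.1,
        seed=7,
    )
    return pq.generate_dataset(spec)


@pytest.fixture(scope="session")
def small_prepared(small_dataset):
    ds = small_dataset
    return pq.prepare_dataset(ds.spectra, ds.psms, ds.protein_groups, ds.matrix, plex="TMT-6")


@pytest.fixture(scope="session")
def tmt6_channels():
    return pq.plex_channels("TMT-6")


@pytest.fixture
def pepxml_file(tmp_path):
    """pepXML with three hits: one carrying both PeptideProphet and iProphet
    probabilities, one plain, one referencing a decoy protein."""
    def hit(scan, peptide, protein, prob, iprob=None):
        analysis = (
            f'<analysis_result analysis="peptideprophet">'
            f'<peptideprophet_result probability="{prob}"/></analysis_result>'
        )
        if iprob is not None:
            analysis += (
                f'<analysis_result analysis="interprophet">'
                f'<interprophet_result probability="{iprob}"/></analysis_result>'
            )
        return f"""
<spectrum_query spectrum="run1.{scan:05d}.{scan:05d}.2" start_scan="{scan}" end_scan="{scan}" precursor_neutral_mass="1000" assumed_charge="2" index="{scan}">
<search_result>
<search_hit hit_rank="1" peptide="{peptide}" protein="{protein}" num_tot_proteins="1" calc_neutral_pep_mass="1000" massdiff="0.0">
{analysis}
</search_hit>
</search_result>
</spectrum_query>"""

    body = hit(2, "PEPTIDEK", "sp|P1|A", 0.90, iprob=0.99)
    body += hit(4, "ELVISLIVESK", "sp|P2|B", 0.98)
    body += hit(6, "DECOYPEPK", "DECOY_sp|P3|C", 0.50)
    text = f"""<?xml version="1.0" encoding="UTF-8"?>
<msms_pipeline_analysis xmlns="http://regis-web.systemsbiology.net/pepXML" date="2020-01-01T00:00:00" summary_xml="t.pep.xml">
<msms_run_summary base_name="run1" raw_data_type="raw" raw_data=".mzML">
<search_summary base_name="run1" search_engine="Comet" precursor_mass_type="monoisotopic" fragment_mass_type="monoisotopic"/>
{body}
</msms_run_summary>
</msms_pipeline_analysis>
"""
    path = tmp_path / "t.pep.xml"
    path.write_text(text)
    return str(path)


@pytest.fixture
def protxml_file(tmp_path):
    text = """<?xml version="1.0" encoding="UTF-8"?>
<protein_summary xmlns="http://regis-web.systemsbiology.net/protXML" summary_xml="t.prot.xml">
<protein_group group_number="1" probability="0.99">
<protein protein_name="sp|P1|A" probability="0.99" n_indistinguishable_proteins="1" group_sibling_id="a">
<peptide peptide_sequence="PEPTIDEK" charge="2" initial_probability="0.99" nsp_adjusted_probability="0.99" is_nondegenerate_evidence="Y" n_enzymatic_termini="2"/>
<peptide peptide_sequence="ELVISLIVESK" charge="2" initial_probability="0.95" nsp_adjusted_probability="0.95" is_nondegenerate_evidence="Y" n_enzymatic_termini="2"/>
<peptide peptide_sequence="ANOTHERK" charge="3" initial_probability="0.91" nsp_adjusted_probability="0.91" is_nondegenerate_evidence="Y" n_enzymatic_termini="2"/>
</protein>
</protein_group>
<protein_group group_number="2" probability="0.50">
<protein protein_name="sp|P2|B" probability="0.50" n_indistinguishable_proteins="1" group_sibling_id="a">
<peptide peptide_sequence="QWERTYK" charge="2" initial_probability="0.50" nsp_adjusted_probability="0.50" is_nondegenerate_evidence="Y" n_enzymatic_termini="2"/>
</protein>
</protein_group>
</protein_summary>
"""
    path = tmp_path / "t.prot.xml"
    path.write_text(text)
    return str(path)


def write_mzxml(path, scans):
    """Minimal mzXML writer for test fixtures.

    ``scans``: list of dicts with num, msLevel, rt_seconds, peaks
    [(mz, intensity)], and optional precursor (mz, charge).
    """
    def b64(peaks):
        flat = [v for p in peaks for v in p]
        return base64.b64encode(struct.pack(f">{len(flat)}f", *flat)).decode()

    parts = [
        '<?xml version="1.0" encoding="ISO-8859-1"?>\n'
        '<mzXML xmlns="http://sashimi.sourceforge.net/schema_revision/mzXML_3.2">\n'
        f'<msRun scanCount="{len(scans)}">\n'
    ]
    for s in scans:
        parts.append(
            f'<scan num="{s["num"]}" msLevel="{s["msLevel"]}" '
            f'peaksCount="{len(s["peaks"])}" retentionTime="PT{s["rt_seconds"]}S">\n'
        )
        if "precursor" in s:
            mz, charge = s["precursor"]
            parts.append(
                f'<precursorMz precursorIntensity="1000" precursorCharge="{charge}" '
                f'activationMethod="HCD">{mz}</precursorMz>\n'
            )
        parts.append(
            '<peaks precision="32" byteOrder="network" contentType="m/z-int" '
            f'compressionType="none" compressedLen="0">{b64(s["peaks"])}</peaks>\n</scan>\n'
        )
    parts.append("</msRun>\n</mzXML>\n")
    with open(path, "w") as fh:
        fh.write("".join(parts))
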