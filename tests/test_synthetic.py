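"""The synthetic benchmark generator: determinism, exactness, S2I realization."""

import numpy as np
import pytest

import plexquant as pq
from plexquant.interference import compute_s2i_single
from plexquant.synthetic import default_pairs


def _noise_free_spec(**kwargs):
    defaults = dict(
        n_proteins=4,
        class_counts={"standard": 2, "background": 2},
        true_ratios={
            "background": (1.0,) * 6,
            "standard": (2.0, 1.0, 1.0, 1.0, 1.0, 1.0),
        },
        cv_noise=0.0,
        interference_fraction=0.0,
        seed=5,
    )
    defaults.update(kwargs)
    return pq.SyntheticSpec(**defaults)


class TestGeneration:
    def test_same_seed_identical_datasets(self):
        a = pq.generate_dataset(pq.SyntheticSpec(n_proteins=5, seed=9))
        b = pq.generate_dataset(pq.SyntheticSpec(n_proteins=5, seed=9))
        assert [p.psm_id for p in a.psms] == [p.psm_id for p in b.psms]
        assert [p.peptide_key for p in a.psms] == [p.peptide_key for p in b.psms]
        for s, t in zip(a.spectra, b.spectra):
            assert np.array_equal(s.mz, t.mz)
            assert np.array_equal(s.intensity, t.intensity)

    def test_different_seed_differs(self):
        a = pq.generate_dataset(pq.SyntheticSpec(n_proteins=5, seed=9))
        b = pq.generate_dataset(pq.SyntheticSpec(n_proteins=5, seed=10))
        assert [p.peptide_key for p in a.psms] != [p.peptide_key for p in b.psms]

    def test_noise_free_psm_ratios_exact(self):
        ds = pq.generate_dataset(_noise_free_spec())
        prep = pq.prepare_dataset(
            ds.spectra, ds.psms, ds.protein_groups, ds.matrix, plex="TMT-6"
        )
        ratio = prep.corrected[:, 0] / prep.corrected[:, 1]
        for i, psm in enumerate(prep.psms):
            acc = psm.protein_refs[0]
            expected = ds.truth.abundance[acc][0] / ds.truth.abundance[acc][1]
            assert ratio[i] == pytest.approx(expected, rel=1e-9)

    def test_impurity_folding_inverts_exactly(self):
        matrix = pq.load_correction_matrix(pq.bundled_example_matrices()["TMT-6"])
        ds = pq.generate_dataset(_noise_free_spec(impurity=matrix))
        prep = pq.prepare_dataset(
            ds.spectra, ds.psms, ds.protein_groups, ds.matrix, plex="TMT-6"
        )
        std = [i for i, p in enumerate(prep.psms)
               if ds.truth.protein_class[p.protein_refs[0]] == "standard"
               and np.allclose(ds.truth.abundance[p.protein_refs[0]][:2], [2.0, 1.0])]
        assert std
        ratio = prep.corrected[std, 0] / prep.corrected[std, 1]
        assert np.allclose(ratio, 2.0, rtol=1e-9)

    def test_s2i_realized_on_generated_ms1(self):
        ds = pq.generate_dataset(_noise_free_spec(interference_fraction=0.4))
        scans = {s.scan_id: s for s in ds.spectra}
        order = [s.scan_id for s in ds.spectra]
        for psm in ds.psms:
            ms2 = scans[psm.spectrum_ref]
            p = ms2.precursor
            ms1 = scans[p.parent_ms1_scan]
            s2i = compute_s2i_single(
                ms1, (p.target_mz, p.charge), (p.isolation_center, p.isolation_width)
            )
            assert s2i == pytest.approx(0.6, abs=0.01)
            # the following MS1 also carries the cluster
            following = scans[order[order.index(ms2.scan_id) + 1]]
            assert following.ms_level == 1
            s2i_after = compute_s2i_single(
                following, (p.target_mz, p.charge), (p.isolation_center, p.isolation_width)
            )
            assert s2i_after == pytest.approx(0.6, abs=0.01)

    def test_ground_truth_row_count_and_classes(self):
        ds = pq.generate_dataset(pq.SyntheticSpec())
        assert len(ds.truth.protein_class) == 50
        counts = {
            c: sum(1 for v in ds.truth.protein_class.values() if v == c)
            for c in ("standard", "background")
        }
        assert counts == {"standard": 6, "background": 44}

    def test_infeasible_spec_rejected(self):
        with pytest.raises(ValueError):
            pq.SyntheticSpec(interference_fraction=1.0)
        with pytest.raises(ValueError):
            pq.SyntheticSpec(true_ratios={"background": (1.0, 1.0)})  # wrong length


class TestFixtureFiles:
    def test_round_trip_through_io(self, tmp_path, small_dataset):
        paths = pq.write_fixture_files(small_dataset, str(tmp_path))
        spectra = pq.read_spectra(paths["spectra"])
        psms = pq.read_psm_table(paths["psms"])
        groups = pq.read_protein_table(paths["proteins"])
        matrix = pq.load_correction_matrix(paths["matrix"])
        assert len(spectra) == len(small_dataset.spectra)
        assert len(psms) == len(small_dataset.psms)
        assert len(groups) == len(small_dataset.protein_groups)
        assert np.allclose(matrix.matrix, small_dataset.matrix.matrix)
        # the files support the same quantitation as the in-memory dataset
        prep_mem = pq.prepare_dataset(
            small_dataset.spectra,
            small_dataset.psms,
            small_dataset.protein_groups,
            small_dataset.matrix,
            plex="TMT-6",
        )
        prep_file = pq.prepare_dataset(spectra, psms, groups, matrix, plex="TMT-6")
        assert np.allclose(prep_mem.corrected, prep_file.corrected, rtol=1e-9)
        assert np.allclose(prep_mem.s2i, prep_file.s2i, atol=1e-9)

    def test_ground_truth_rows(self, tmp_path, small_dataset):
        paths = pq.write_fixture_files(small_dataset, str(tmp_path))
        truth = pq.read_ground_truth(paths["ground_truth"])
        assert len(truth.classes) == 6


class TestCompressionCurve:
    def test_zero_interference_equals_truth(self):
        curve = pq.compression_curve(_noise_free_spec(), [0.0])
        row = curve.iloc[0]
        assert row["uncorrected_ratio"] == pytest.approx(2.0, rel=1e-9)
        assert row["rcc_ratio"] == pytest.approx(2.0, rel=1e-9)

    def test_closed_form_blend_at_half(self):
        """Uncorrected = ((1-f)r + fT/n) / ((1-f) + fT/n) with T the summed
        abundance; correction restores r exactly in the noise-free case."""
        spec = _noise_free_spec()
        curve = pq.compression_curve(spec, [0.5])
        r, f, T, n = 2.0, 0.5, 7.0, 6
        expected = ((1 - f) * r + f * T / n) / ((1 - f) * 1.0 + f * T / n)
        row = curve.iloc[0]
        assert row["uncorrected_ratio"] == pytest.approx(expected, rel=1e-9)
        assert row["rcc_ratio"] == pytest.approx(2.0, rel=1e-9)

    def test_monotone_compression_toward_one(self):
        curve = pq.compression_curve(_noise_free_spec(), [0.0, 0.2, 0.4, 0.6])
        ratios = curve["uncorrected_ratio"].to_numpy()
        assert np.all(np.diff(ratios) < 0)
        assert np.all(ratios >= 1.0)
        assert np.allclose(curve["rcc_ratio"], 2.0, rtol=0.05)
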