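"""Normalization and replicate averaging: hand-checked examples plus
conservation, idempotence, shift-invariance and permutation properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from coipnet import (
    Genotype,
    ION_INTENSITY,
    ProteinQuantMatrix,
    SampleMeta,
    SPECTRAL_COUNT,
)
from coipnet.normalize import (
    average_replicates,
    normalize_intensities,
    normalize_spectral_counts,
)


def _count_matrix(data: dict, proteins) -> ProteinQuantMatrix:
    return ProteinQuantMatrix(
        SPECTRAL_COUNT, pd.DataFrame(data, index=pd.Index(proteins, name="accession"))
    )


def _spectra(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["spectrum_id", "sample_id", "accessions", "intensity"])


META2 = [SampleMeta("s1", Genotype.WT, 1), SampleMeta("s2", Genotype.ALA56, 1)]


class TestSpectralCounts:
    def test_hand_worked_scaling(self):
        # totals (100, 200): factors 1.5 and 0.75, so (10, 20) -> (15, 15)
        matrix = _count_matrix({"s1": [10, 90], "s2": [20, 180]}, ["P1", "P2"])
        normalized, report = normalize_spectral_counts(matrix)
        assert normalized.values.loc["P1"].tolist() == [15.0, 15.0]
        assert report.scale_factors == {"s1": 1.5, "s2": 0.75}

    def test_equal_totals_leave_matrix_unchanged(self):
        matrix = _count_matrix({"s1": [10, 90], "s2": [40, 60]}, ["P1", "P2"])
        normalized, _ = normalize_spectral_counts(matrix)
        pd.testing.assert_frame_equal(normalized.values, matrix.values.astype(float))

    def test_single_sample_unchanged(self):
        matrix = _count_matrix({"s1": [4, 6]}, ["P1", "P2"])
        normalized, _ = normalize_spectral_counts(matrix)
        pd.testing.assert_frame_equal(normalized.values, matrix.values.astype(float))

    def test_zero_total_sample_is_an_error(self):
        matrix = _count_matrix({"s1": [1, 2], "s2": [0, 0]}, ["P1", "P2"])
        with pytest.raises(ValueError, match="s2"):
            normalize_spectral_counts(matrix)

    @given(
        st.lists(
            st.lists(st.integers(min_value=0, max_value=50), min_size=3, max_size=3),
            min_size=2,
            max_size=6,
        )
    )
    def test_total_mass_is_conserved(self, rows):
        frame = pd.DataFrame(
            rows,
            index=pd.Index([f"P{i}" for i in range(len(rows))], name="accession"),
            columns=["a", "b", "c"],
        )
        if (frame.sum(axis=0) == 0).any():
            return
        normalized, _ = normalize_spectral_counts(ProteinQuantMatrix(SPECTRAL_COUNT, frame))
        totals = normalized.values.sum(axis=0)
        assert np.allclose(totals, totals.mean(), rtol=1e-9)
        assert np.isclose(normalized.values.to_numpy().sum(), frame.to_numpy().sum())

    def test_sample_order_never_changes_results(self):
        matrix = _count_matrix({"s1": [10, 90], "s2": [20, 180], "s3": [5, 45]}, ["P1", "P2"])
        flipped = ProteinQuantMatrix(SPECTRAL_COUNT, matrix.values[["s3", "s1", "s2"]])
        a, _ = normalize_spectral_counts(matrix)
        b, _ = normalize_spectral_counts(flipped)
        pd.testing.assert_frame_equal(a.values, b.values[a.values.columns])


class TestIntensities:
    def test_multi_protein_spectra_are_pruned(self):
        spectra = _spectra(
            [
                ("sp1", "s1", "P1", 8.0),
                ("sp2", "s1", "P1;P2", 64.0),
                ("sp3", "s2", "P1", 8.0),
            ]
        )
        matrix, report = normalize_intensities(spectra, META2)
        assert report.n_spectra_pruned_shared == 1
        assert "P2" not in matrix.values.index  # its only spectrum was shared

    def test_constant_shift_between_samples_is_removed(self):
        rng = np.random.default_rng(0)
        values = rng.normal(10, 1, 21)
        delta = 3.7
        rows = [(f"a{i}", "s1", f"P{i}", 2.0 ** v) for i, v in enumerate(values)]
        rows += [(f"b{i}", "s2", f"P{i}", 2.0 ** (v + delta)) for i, v in enumerate(values)]
        matrix, _ = normalize_intensities(_spectra(rows), META2)
        paired = matrix.values["s1"] - matrix.values["s2"]
        assert np.abs(paired.to_numpy()).max() < 1e-6
        medians = matrix.values.median(axis=0)
        assert np.allclose(medians, medians.iloc[0], atol=1e-6)

    def test_single_sample_converges_in_one_iteration_to_zero_median(self):
        meta = [SampleMeta("s1", Genotype.WT, 1)]
        rows = [(f"a{i}", "s1", f"P{i}", float(2 ** (i + 1))) for i in range(5)]
        matrix, report = normalize_intensities(rows and _spectra(rows), meta)
        assert report.iterations == 1
        assert abs(np.nanmedian(matrix.values.to_numpy())) < 1e-9

    def test_normalization_is_idempotent(self):
        rng = np.random.default_rng(1)
        rows = []
        for i in range(40):
            for sid in ("s1", "s2"):
                rows.append((f"{sid}_{i}", sid, f"P{i % 13}", float(2.0 ** rng.normal(12, 2))))
        spectra = _spectra(rows)
        matrix1, report1 = normalize_intensities(spectra, META2)
        centered = spectra.copy()
        offsets = centered["sample_id"].map(report1.log2_offsets)
        centered["intensity"] = centered["intensity"] / 2.0**offsets
        matrix2, report2 = normalize_intensities(centered, META2)
        pd.testing.assert_frame_equal(matrix1.values, matrix2.values, atol=1e-6)
        assert max(abs(v) for v in report2.log2_offsets.values()) < 1e-6

    def test_nonconvergence_raises_with_report(self):
        # exact median subtraction converges in one pass, so force the
        # failure path by allowing zero passes
        rows = [("a", "s1", "P1", 2.0), ("b", "s2", "P1", 4.0)]
        with pytest.raises(RuntimeError, match="converge"):
            normalize_intensities(_spectra(rows), META2, max_iter=0)

    def test_all_spectra_shared_is_an_error(self):
        rows = [("a", "s1", "P1;P2", 2.0)]
        with pytest.raises(ValueError, match="survive"):
            normalize_intensities(_spectra(rows), META2)


class TestAverageReplicates:
    META9 = [
        SampleMeta(f"{g}_{r}", Genotype(g), r)
        for g in ("WT", "ALA56", "KO")
        for r in (1, 2, 3)
    ]

    def test_count_mean_and_intensity_median(self):
        counts = ProteinQuantMatrix(
            SPECTRAL_COUNT,
            pd.DataFrame(
                [[10, 10, 10, 0, 0, 3, 1, 1, 1]],
                index=pd.Index(["P1"], name="accession"),
                columns=[s.sample_id for s in self.META9],
            ),
        )
        summary = average_replicates(counts, self.META9)
        assert summary.values.at["P1", "WT"] == 10.0
        assert summary.values.at["P1", "ALA56"] == 1.0  # mean of (0, 0, 3)

        intensities = ProteinQuantMatrix(
            ION_INTENSITY,
            pd.DataFrame(
                [[4.0, 5.0, 9.0, np.nan, np.nan, np.nan, 2.0, np.nan, np.nan]],
                index=pd.Index(["P1"], name="accession"),
                columns=[s.sample_id for s in self.META9],
            ),
        )
        summary_ii = average_replicates(intensities, self.META9)
        assert summary_ii.values.at["P1", "WT"] == 5.0  # median
        assert np.isnan(summary_ii.values.at["P1", "ALA56"])  # absent everywhere
        assert summary_ii.values.at["P1", "KO"] == 2.0  # median of present values

    def test_missing_genotype_is_an_error(self):
        meta = [s for s in self.META9 if s.genotype is not Genotype.KO]
        counts = ProteinQuantMatrix(
            SPECTRAL_COUNT,
            pd.DataFrame(
                [[1] * 6],
                index=pd.Index(["P1"], name="accession"),
                columns=[s.sample_id for s in meta],
            ),
        )
        with pytest.raises(ValueError, match="KO"):
            average_replicates(counts, meta)
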