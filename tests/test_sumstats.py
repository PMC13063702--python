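import numpy as np
import pandas as pd
import pytest

from cismr.sumstats import (
    HarmonizationError,
    LDMatrix,
    SumstatsFormatError,
    harmonize,
    read_ld_matrix,
    read_sumstats,
    regularize_ld,
    write_ld_matrix,
    write_sumstats,
)
from conftest import make_variant


def write_table(path, rows, columns=None):
    cols = columns or ["variant_id", "chrom", "pos", "effect_allele",
                       "other_allele", "eaf", "beta", "se", "pval", "n"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def toy_rows(k=13):
    return [
        [f"rs{i}", "1", 1_000_000 + i, "A", "G", 0.3, 0.1, 0.01, 1e-10, 10000]
        for i in range(k)
    ]


class TestReadSumstats:
    def test_count_preserved(self, tmp_path):
        p = tmp_path / "exp.tsv"
        write_table(p, toy_rows(13))
        assert len(read_sumstats(p, "exposure")) == 13

    def test_invalid_rows_rejected_with_diagnostics(self, tmp_path, caplog):
        rows = toy_rows(3)
        rows[1][5] = 1.2  # eaf out of range
        p = tmp_path / "exp.tsv"
        write_table(p, rows)
        with caplog.at_level("WARNING"):
            records = read_sumstats(p, "exposure")
        assert len(records) == 2
        assert "eaf out of range" in caplog.text
        assert "line 3" in caplog.text  # header is line 1

    def test_unparseable_numeric_reports_line(self, tmp_path):
        rows = toy_rows(2)
        rows[0][6] = "not_a_number"
        p = tmp_path / "exp.tsv"
        write_table(p, rows)
        with pytest.raises(SumstatsFormatError, match="line 2"):
            read_sumstats(p, "exposure", strict=True)

    def test_missing_column_named_in_error(self, tmp_path):
        p = tmp_path / "exp.tsv"
        pd.DataFrame({"variant_id": ["rs1"], "beta": [0.1]}).to_csv(
            p, sep="\t", index=False
        )
        with pytest.raises(SumstatsFormatError, match="effect_allele"):
            read_sumstats(p, "exposure")

    def test_column_synonyms_resolved(self, tmp_path):
        p = tmp_path / "exp.tsv"
        write_table(
            p, toy_rows(2),
            columns=["SNP", "CHR", "BP", "A1", "A2", "FREQ", "b",
                     "SE", "P", "N"],
        )
        records = read_sumstats(p, "exposure")
        assert records[0].variant_id == "rs0"
        assert records[0].pos == 1_000_000

    def test_outcome_reads_event_count(self, tmp_path):
        p = tmp_path / "out.tsv"
        rows = [r + [4010] for r in toy_rows(2)]
        write_table(p, rows, columns=["variant_id", "chrom", "pos",
                    "effect_allele", "other_allele", "eaf", "beta", "se",
                    "pval", "n", "n_events"])
        records = read_sumstats(p, "outcome")
        assert records[0].n_events == 4010


def test_roundtrip_is_exact(tmp_path):
    records = [
        make_variant(f"rs{i}", beta=0.123456789012345 * (i + 1),
                     se=0.01 + 1e-13 * i, eaf=0.2 + 0.01 * i, pval=10.0**-i - 1e-16)
        for i in range(5)
    ]
    p = tmp_path / "t.tsv"
    write_sumstats(records, p)
    back = read_sumstats(p, "exposure")
    for a, b in zip(records, back):
        assert a.variant_id == b.variant_id
        assert a.effect_allele == b.effect_allele
        for fieldname in ("eaf", "beta", "se", "pval", "n"):
            assert getattr(a, fieldname) == pytest.approx(
                getattr(b, fieldname), abs=1e-12
            )


def test_ld_matrix_roundtrip(tmp_path):
    rho = np.array([[1.0, 0.4], [0.4, 1.0]])
    ld = LDMatrix(["rs1", "rs2"], rho)
    p = tmp_path / "ld.tsv"
    write_ld_matrix(ld, p)
    back = read_ld_matrix(p)
    assert back.variant_ids == ["rs1", "rs2"]
    np.testing.assert_allclose(back.rho, rho, atol=1e-12)


class TestLDMatrixInvariants:
    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError, match="symmetric"):
            LDMatrix(["a", "b"], np.array([[1.0, 0.5], [0.1, 1.0]]))

    def test_rejects_bad_diagonal(self):
        with pytest.raises(ValueError, match="diagonal"):
            LDMatrix(["a", "b"], np.array([[0.9, 0.1], [0.1, 1.0]]))

    def test_subset_and_flip(self):
        rho = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.1], [0.2, 0.1, 1.0]])
        ld = LDMatrix(["a", "b", "c"], rho)
        sub = ld.subset(["c", "a"])
        np.testing.assert_allclose(sub.rho, [[1.0, 0.2], [0.2, 1.0]])
        flipped = ld.flip_signs(["b"])
        assert flipped.rho[0, 1] == -0.5
        assert flipped.rho[0, 2] == 0.2


class TestHarmonize:
    def test_identical_alleles_kept_unchanged(self):
        exp = [make_variant("rs1", beta=0.1)]
        out = [make_variant("rs1", beta=0.05, se=0.02)]
        h = harmonize(exp, out)
        assert h.k == 1
        assert h.by[0] == 0.05
        assert list(h.provenance["status"]) == ["kept"]

    def test_swapped_alleles_flip_outcome_sign(self):
        exp = [make_variant("rs1", ea="A", oa="G", beta=0.1)]
        out = [make_variant("rs1", ea="G", oa="A", eaf=0.7, beta=0.05)]
        h = harmonize(exp, out)
        assert h.by[0] == pytest.approx(-0.05)
        assert h.table["eaf"].iloc[0] == pytest.approx(0.3)

    def test_strand_flip_resolved_before_mismatch(self):
        # outcome reported on the other strand: A/G <-> T/C
        exp = [make_variant("rs1", ea="A", oa="G", beta=0.1)]
        out = [make_variant("rs1", ea="T", oa="C", beta=0.05)]
        h = harmonize(exp, out)
        assert h.k == 1
        assert h.by[0] == 0.05

    def test_strand_flip_then_swap(self):
        exp = [make_variant("rs1", ea="A", oa="G", beta=0.1)]
        out = [make_variant("rs1", ea="C", oa="T", beta=0.05)]
        h = harmonize(exp, out)
        assert h.by[0] == pytest.approx(-0.05)

    def test_true_mismatch_dropped_with_reason(self):
        exp = [make_variant("rs1", ea="A", oa="G"), make_variant("rs2")]
        out = [make_variant("rs1", ea="A", oa="C"), make_variant("rs2")]
        h = harmonize(exp, out)
        assert h.variant_ids == ["rs2"]
        reason = h.provenance.set_index("variant_id").loc["rs1", "reason"]
        assert reason == "allele_mismatch"

    def test_palindromic_ambiguous_dropped(self):
        exp = [make_variant("rs1", ea="A", oa="T", eaf=0.5),
               make_variant("rs2")]
        out = [make_variant("rs1", ea="A", oa="T", eaf=0.5),
               make_variant("rs2")]
        h = harmonize(exp, out, palindrome_eaf_window=0.08)
        assert h.variant_ids == ["rs2"]
        reason = h.provenance.set_index("variant_id").loc["rs1", "reason"]
        assert reason == "palindromic_ambiguous"

    def test_palindromic_clear_frequency_kept(self):
        exp = [make_variant("rs1", ea="A", oa="T", eaf=0.1)]
        out = [make_variant("rs1", ea="A", oa="T", eaf=0.1, beta=0.02)]
        h = harmonize(exp, out, palindrome_eaf_window=0.08)
        assert h.k == 1

    def test_missing_in_outcome_dropped(self):
        exp = [make_variant("rs1"), make_variant("rs2")]
        out = [make_variant("rs1")]
        h = harmonize(exp, out)
        assert h.variant_ids == ["rs1"]

    def test_no_overlap_raises(self):
        with pytest.raises(HarmonizationError, match="no overlapping"):
            harmonize([make_variant("rs1")], [make_variant("rs2")])

    def test_ld_subset_follows_retention(self):
        rho = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.1], [0.2, 0.1, 1.0]])
        ld = LDMatrix(["rs1", "rs2", "rs3"], rho)
        exp = [make_variant(f"rs{i}") for i in (1, 2, 3)]
        out = [make_variant("rs1"), make_variant("rs3")]
        h = harmonize(exp, out, ld)
        assert h.ld.variant_ids == ["rs1", "rs3"]
        assert h.ld.rho[0, 1] == 0.2

    def test_idempotent(self):
        exp = [make_variant("rs1", beta=0.1),
               make_variant("rs2", ea="C", oa="T", beta=-0.2, eaf=0.4)]
        out = [make_variant("rs1", ea="G", oa="A", eaf=0.7, beta=0.05),
               make_variant("rs2", ea="C", oa="T", beta=0.01, eaf=0.4)]
        h1 = harmonize(exp, out)
        h2 = harmonize(h1.exposure_records(), h1.outcome_records(), h1.ld)
        pd.testing.assert_frame_equal(
            h1.table.drop(columns=["pval_x", "pval_y"]),
            h2.table.drop(columns=["pval_x", "pval_y"]),
        )
        np.testing.assert_allclose(h1.ld.rho, h2.ld.rho)


class TestRegularizeLD:
    def test_identity_untouched(self):
        ld = LDMatrix.identity(["a", "b"])
        fixed, inflation = regularize_ld(ld)
        assert inflation == 0.0
        np.testing.assert_allclose(fixed.rho, np.eye(2))

    def test_mildly_indefinite_repaired(self):
        rho = np.array([[1.0, 1.000001], [1.000001, 1.0]])
        ld = LDMatrix(["a", "b"], rho)
        assert not ld.is_psd()
        fixed, inflation = regularize_ld(ld, jitter_max=1e-5)
        assert 0 < inflation <= 1e-5
        # spectral check: all eigenvalues non-negative within tolerance
        assert np.linalg.eigvalsh(fixed.rho).min() >= -1e-8
        assert np.allclose(np.diag(fixed.rho), 1.0)

    def test_already_psd_unchanged(self):
        rho = np.array([[1.0, 0.3], [0.3, 1.0]])
        fixed, inflation = regularize_ld(LDMatrix(["a", "b"], rho))
        assert inflation == 0.0
        np.testing.assert_allclose(fixed.rho, rho)

    def test_unrepairable_raises(self):
        rho = np.array([[1.0, 0.0, 0.9], [0.0, 1.0, 0.9], [0.9, 0.9, 1.0]])
        # strongly indefinite (min eigenvalue ~ -0.27): far above the cap
        ld = LDMatrix(["a", "b", "c"], rho)
        assert not ld.is_psd()
        with pytest.raises(ValueError, match="not repairable"):
            regularize_ld(ld, jitter_max=1e-8)
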