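import numpy as np
import pandas as pd
import pytest

from phenocopy.core_io import (
    AnalysisConfig,
    ExpressionStudy,
    GeneSet,
    SampleRecord,
    load_config,
    quantile_normalize,
    read_gmt,
    read_study,
    save_config,
    write_gmt,
    write_study,
)


def _write_toy(tmp_path, matrix_rows, design_rows):
    matrix = tmp_path / "m.tsv"
    design = tmp_path / "d.csv"
    matrix.write_text("\n".join(matrix_rows) + "\n")
    header = "sample_id,modulator,compound_id,concentration_uM,time_h,stimulated,vehicle,replicate"
    design.write_text(header + "\n" + "\n".join(design_rows) + "\n")
    return matrix, design


TOY_MATRIX = [
    "gene_id\tS1\tS2\tS3\tS4",
    "G1\t1.5\t2.0\t2.5\t3.0",
    "G2\t0.1\t0.2\t0.3\t0.4",
    "G3\t5\t5\t5\t5",
]
TOY_DESIGN = [
    "S1,none,,,2,1,dmso,1",
    "S2,none,,,2,1,dmso,2",
    "S3,none,,,2,0,dmso,1",
    "S4,none,,,2,0,dmso,2",
]


def test_read_study_dimensions_and_order(tmp_path):
    matrix, design = _write_toy(tmp_path, TOY_MATRIX, TOY_DESIGN)
    study = read_study(matrix, design)
    assert study.n_genes == 3 and study.n_samples == 4
    assert [s.sample_id for s in study.samples] == ["S1", "S2", "S3", "S4"]
    assert study.values[0, 3] == 3.0


def test_read_study_missing_sample_named(tmp_path):
    matrix, design = _write_toy(tmp_path, TOY_MATRIX, TOY_DESIGN[:-1])
    with pytest.raises(ValueError, match="S4"):
        read_study(matrix, design)


def test_read_study_duplicate_gene(tmp_path):
    rows = TOY_MATRIX + ["G1\t9\t9\t9\t9"]
    matrix, design = _write_toy(tmp_path, rows, TOY_DESIGN)
    with pytest.raises(ValueError, match="duplicate gene"):
        read_study(matrix, design)


def test_read_study_non_numeric_cell_located(tmp_path):
    rows = list(TOY_MATRIX)
    rows[2] = "G2\t0.1\tnot_a_number\t0.3\t0.4"
    matrix, design = _write_toy(tmp_path, rows, TOY_DESIGN)
    with pytest.raises(ValueError, match="G2.*S2"):
        read_study(matrix, design)


def test_study_round_trip_bit_exact(tmp_path, noisy_study):
    study, _ = noisy_study
    write_study(study, tmp_path / "m.tsv", tmp_path / "d.csv")
    back = read_study(tmp_path / "m.tsv", tmp_path / "d.csv")
    assert back.genes == study.genes
    assert np.array_equal(back.values, study.values)
    assert back.samples == study.samples


class TestGMT:
    def test_parse(self, tmp_path):
        path = tmp_path / "x.gmt"
        path.write_text("P1\tdesc\tG1\tG2\nP2\tother\tG3\n")
        sets = read_gmt(path)
        assert sets[0].name == "P1" and sets[0].members == ("G1", "G2")
        assert sets[1].members == ("G3",)

    def test_duplicate_member_deduplicated(self, tmp_path):
        path = tmp_path / "x.gmt"
        path.write_text("P1\tdesc\tG1\tG1\n")
        (one,) = read_gmt(path)
        assert one.members == ("G1",)

    def test_short_line_rejected_with_lineno(self, tmp_path):
        path = tmp_path / "x.gmt"
        path.write_text("P0\tdesc\tG1\nP1\tdesc\n")
        with pytest.raises(ValueError, match=":2"):
            read_gmt(path)

    def test_round_trip_identity(self, tmp_path):
        sets = [GeneSet("A", "d1", ("G1", "G2")), GeneSet("B", "", ("G9",))]
        write_gmt(sets, tmp_path / "x.gmt")
        back = read_gmt(tmp_path / "x.gmt")
        assert [(s.name, s.members) for s in back] == [(s.name, s.members) for s in sets]

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="no members"):
            GeneSet("A", "d", ())


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        x = np.array([[1.0, 1.0], [3.0, 3.0]])
        assert np.allclose(quantile_normalize(x), x)

    def test_sorted_mean_oracle(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]])
        expected = np.array([[1.5, 1.5], [3.5, 3.5]])
        assert np.allclose(quantile_normalize(x), expected)

    def test_column_means_equalized(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(50, 4)) * [1, 2, 3, 4]
        out = quantile_normalize(x)
        means = out.mean(axis=0)
        assert np.allclose(means, means[0])

    def test_single_column_identity(self):
        x = np.array([[1.0], [2.0]])
        assert np.array_equal(quantile_normalize(x), x)


class TestSampleRecord:
    def test_nce_requires_compound_and_concentration(self):
        with pytest.raises(ValueError, match="nce"):
            SampleRecord("s", "nce", None, None, 2.0, True, "dmso", 1)

    def test_control_must_not_carry_compound(self):
        with pytest.raises(ValueError, match="none"):
            SampleRecord("s", "none", "BI1", 2.0, 2.0, True, "dmso", 1)

    def test_float_criteria_match_tolerantly(self):
        rec = SampleRecord("s", "nce", "BI1", 0.08, 2.0, True, "dmso", 1)
        assert rec.matches(concentration_uM=0.08, compound_id="BI1")
        assert not rec.matches(concentration_uM=2.0)


class TestConfig:
    def test_round_trip(self, tmp_path):
        config = AnalysisConfig(alpha=0.05, lr_min=0.5, seed=3)
        save_config(config, tmp_path / "c.yaml")
        assert load_config(tmp_path / "c.yaml") == config

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            AnalysisConfig(alpha=1.5)

    def test_low_permutations_rejected(self):
        with pytest.raises(ValueError):
            AnalysisConfig(permutations_B=10)

    def test_unknown_key_rejected(self, tmp_path):
        (tmp_path / "c.yaml").write_text("alpha: 0.01\nbogus: 3\n")
        with pytest.raises(ValueError, match="bogus"):
            load_config(tmp_path / "c.yaml")


def test_matrix_rejects_nan():
    samples = [
        SampleRecord(f"S{i}", "none", None, None, 2.0, True, "dmso", i + 1) for i in range(2)
    ]
    with pytest.raises(ValueError, match="missing value"):
        ExpressionStudy(genes=["G1"], samples=samples, values=np.array([[1.0, np.nan]]))
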