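"""Expression I/O, probe collapsing, quantile normalization, variance filter."""

import numpy as np
import pandas as pd
import pytest

from degnet import (
    ExpressionDataset,
    collapse_probes,
    quantile_normalize,
    read_expression_matrix,
    variance_filter,
    write_expression_matrix,
)
from degnet.datasets import ExpressionParseError, ValidationError

from conftest import make_dataset


def write_tsv(path, header, rows):
    lines = ["\t".join(header)] + ["\t".join(map(str, r)) for r in rows]
    path.write_text("\n".join(lines) + "\n")


def labels_file(tmp_path, pairs):
    p = tmp_path / "labels.tsv"
    p.write_text("\n".join(f"{s}\t{c}" for s, c in pairs) + "\n")
    return p


class TestReadExpressionMatrix:
    def test_round_trip_identity(self, tmp_path):
        p = tmp_path / "m.tsv"
        write_tsv(p, ["id", "s1", "s2", "s3", "s4"],
                  [["g1", 1.0, 2.0, 3.0, 4.0],
                   ["g2", 5.5, 6.5, 7.5, 8.5],
                   ["g3", 0.1, 0.2, 0.3, 0.4]])
        labels = labels_file(tmp_path, [("s1", "control"), ("s2", "control"),
                                        ("s3", "case"), ("s4", "case")])
        ds = read_expression_matrix(p, "d1", "LC", labels)
        assert ds.values.shape == (3, 4)
        assert ds.case_ids == ["s3", "s4"]
        # write and re-read reproduces values
        out = tmp_path / "round.tsv"
        write_expression_matrix(ds, out)
        ds2 = read_expression_matrix(out, "d1", "LC", labels)
        np.testing.assert_allclose(ds2.values.to_numpy(),
                                   ds.values.to_numpy(), atol=1e-12)

    def test_na_row_dropped(self, tmp_path):
        p = tmp_path / "m.tsv"
        write_tsv(p, ["id", "s1", "s2", "s3", "s4"],
                  [["g1", 1, 2, 3, 4], ["g2", 1, "NA", 3, 4], ["g3", 2, 2, 2, 2]])
        labels = labels_file(tmp_path, [("s1", "control"), ("s2", "control"),
                                        ("s3", "case"), ("s4", "case")])
        ds = read_expression_matrix(p, "d1", "LC", labels)
        assert ds.gene_ids == ["g1", "g3"]

    def test_malformed_cell_names_location(self, tmp_path):
        p = tmp_path / "m.tsv"
        write_tsv(p, ["id", "s1", "s2", "s3", "s4"],
                  [["g1", 1, 2, 3, 4], ["g2", 1, "oops", 3, 4]])
        labels = labels_file(tmp_path, [("s1", "control"), ("s2", "control"),
                                        ("s3", "case"), ("s4", "case")])
        with pytest.raises(ExpressionParseError, match="g2.*s2"):
            read_expression_matrix(p, "d1", "LC", labels)

    def test_duplicate_sample_column_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        write_tsv(p, ["id", "s1", "s1", "s2", "s3"],
                  [["g1", 1, 2, 3, 4]])
        labels = labels_file(tmp_path, [("s1", "control"), ("s2", "control"),
                                        ("s3", "case")])
        with pytest.raises(ValidationError, match="duplicate sample"):
            read_expression_matrix(p, "d1", "LC", labels)

    def test_missing_class_label_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        write_tsv(p, ["id", "s1", "s2", "s3", "s4"],
                  [["g1", 1, 2, 3, 4]])
        labels = labels_file(tmp_path, [("s1", "control"), ("s2", "control"),
                                        ("s3", "case")])
        with pytest.raises(ValidationError, match="without class label"):
            read_expression_matrix(p, "d1", "LC", labels)


class TestDatasetInvariants:
    def test_too_few_cases_rejected(self):
        with pytest.raises(ValidationError, match=">=2 case"):
            make_dataset(np.ones((3, 4)), n_case=1)

    def test_nonfinite_rejected(self):
        vals = np.ones((3, 4))
        vals[1, 2] = np.inf
        with pytest.raises(ValidationError, match="non-finite"):
            make_dataset(vals)

    def test_linear_scale_warning(self, caplog):
        vals = np.full((3, 4), 5000.0)
        with caplog.at_level("WARNING"):
            make_dataset(vals)
        assert any("log2" in rec.message for rec in caplog.records)


class TestCollapseProbes:
    def test_max_variance_probe_wins(self):
        ds = make_dataset(np.array([[1.0, 1.5, 1.0, 1.5],   # var 0.083
                                    [0.0, 4.0, 0.0, 4.0]]),  # var 5.33
                          gene_prefix="p")
        out = collapse_probes(ds, {"p1": "GENE", "p2": "GENE"})
        assert out.gene_ids == ["GENE"]
        np.testing.assert_array_equal(out.values.loc["GENE"],
                                      [0.0, 4.0, 0.0, 4.0])

    def test_one_to_one_renames_only(self, small_dataset):
        mapping = {p: p.replace("G", "SYMBOL") for p in small_dataset.gene_ids}
        out = collapse_probes(small_dataset, mapping)
        np.testing.assert_array_equal(out.values.to_numpy(),
                                      small_dataset.values.to_numpy())
        assert out.gene_ids == [mapping[p] for p in small_dataset.gene_ids]

    def test_all_unmapped_is_error(self, small_dataset):
        with pytest.raises(ValidationError, match="no probes"):
            collapse_probes(small_dataset, {"absent": "X"})

    def test_gene_count_equals_distinct_mapped(self, rng):
        ds = make_dataset(rng.standard_normal((10, 6)), gene_prefix="p")
        mapping = {f"p{i + 1}": f"GENE{i % 4}" for i in range(8)}  # p9,p10 unmapped
        out = collapse_probes(ds, mapping)
        assert out.n_genes == 4


class TestQuantileNormalize:
    def test_hand_computed_two_profiles(self):
        # columns alternate between profiles (1,3) and (2,4); the mean sorted
        # profile is (1.5, 3.5), so every column becomes (1.5, 3.5) in rank order
        vals = np.array([[1.0, 2.0, 1.0, 2.0],
                         [3.0, 4.0, 3.0, 4.0]])
        out = quantile_normalize(make_dataset(vals)).values.to_numpy()
        np.testing.assert_allclose(out, np.array([[1.5] * 4, [3.5] * 4]),
                                   atol=1e-12)

    def test_identical_columns_fixed_point(self, rng):
        col = rng.standard_normal(10)
        ds = make_dataset(np.column_stack([col] * 4))
        out = quantile_normalize(ds)
        np.testing.assert_allclose(out.values.to_numpy(),
                                   ds.values.to_numpy(), atol=1e-12)

    def test_sorted_mean_values(self):
        vals = np.array([[1.0, 4.0, 3.0, 2.0],
                         [3.0, 8.0, 1.0, 4.0],
                         [5.0, 6.0, 5.0, 6.0]])
        ds = make_dataset(vals)
        out = quantile_normalize(ds).values.to_numpy()
        ref = np.sort(vals, axis=0).mean(axis=1)
        # every column's sorted values equal the reference profile
        for j in range(4):
            np.testing.assert_allclose(np.sort(out[:, j]), ref, atol=1e-12)

    def test_idempotent_on_tie_free_data(self, rng):
        ds = make_dataset(rng.standard_normal((30, 6)))
        once = quantile_normalize(ds)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(twice.values.to_numpy(),
                                   once.values.to_numpy(), atol=1e-12)

    def test_tie_gets_mean_of_spanned_quantiles(self):
        vals = np.array([[1.0, 1.0, 1.0, 1.0],
                         [1.0, 2.0, 2.0, 2.0],
                         [3.0, 3.0, 3.0, 3.0]])
        out = quantile_normalize(make_dataset(vals)).values.to_numpy()
        ref = np.sort(vals, axis=0).mean(axis=1)   # (1.0, 1.75, 3.0)
        # column 0 has a tie at ranks 0-1: both get mean(ref[0], ref[1])
        np.testing.assert_allclose(out[0, 0], (ref[0] + ref[1]) / 2)
        np.testing.assert_allclose(out[1, 0], (ref[0] + ref[1]) / 2)
        np.testing.assert_allclose(out[2, 0], ref[2])


class TestVarianceFilter:
    def test_keep_all_is_identity(self, small_dataset):
        out = variance_filter(small_dataset, 1.0)
        assert out.gene_ids == small_dataset.gene_ids

    def test_top_half_matches_brute_force(self, rng):
        ds = make_dataset(rng.standard_normal((10, 8)))
        out = variance_filter(ds, 0.5)
        variances = ds.values.var(axis=1, ddof=1)
        expected = set(variances.sort_values(ascending=False).index[:5])
        assert set(out.gene_ids) == expected
        assert out.n_genes == 5
        # original order preserved
        assert out.gene_ids == [g for g in ds.gene_ids if g in expected]

    def test_constant_gene_removed_first(self, rng):
        vals = rng.standard_normal((5, 6))
        vals[2] = 7.0
        ds = make_dataset(vals)
        out = variance_filter(ds, 0.8)  # keeps ceil(4) = 4 of 5
        assert "G3" not in out.gene_ids

    def test_bad_fraction_rejected(self, small_dataset):
        with pytest.raises(ValidationError):
            variance_filter(small_dataset, 0.0)
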