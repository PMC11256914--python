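import numpy as np
import pytest

from phylaugment.otu_io import (
    OtuTable,
    OtuTableError,
    filter_all_zero_otus,
    normalize_relative_abundance,
    read_labels,
    read_otu_table,
    read_taxonomy,
    write_otu_table,
    write_taxonomy,
)


class TestReadWrite:
    def test_roundtrip_identity(self, tmp_path, count_table):
        path = tmp_path / "t.tsv"
        write_otu_table(count_table, str(path))
        back = read_otu_table(str(path))
        assert back.sample_ids == count_table.sample_ids
        assert back.otu_ids == count_table.otu_ids
        assert back.mode == "counts"
        np.testing.assert_array_equal(back.values, count_table.values)

    def test_transpose_symmetry(self, tmp_path, count_table):
        path = tmp_path / "t.tsv"
        df = count_table.to_dataframe().T.astype(int)
        df.index.name = "otu_id"
        df.to_csv(path, sep="\t")
        back = read_otu_table(str(path), orientation="otus_rows")
        assert back.sample_ids == count_table.sample_ids
        np.testing.assert_array_equal(back.values, count_table.values)

    def test_duplicate_otu_id_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("sample\tg1\tg1\ns1\t1\t2\ns2\t3\t4\n")
        with pytest.raises(OtuTableError, match="[Dd]uplicate"):
            read_otu_table(str(path))

    def test_non_numeric_cell_named(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("sample\tg1\tg2\ns1\t1\toops\ns2\t3\t4\n")
        with pytest.raises(OtuTableError, match="g2"):
            read_otu_table(str(path))

    def test_relative_rows_must_sum_to_one(self, tmp_path):
        path = tmp_path / "rel.tsv"
        path.write_text("sample\tg1\tg2\ns1\t0.5\t0.2\n")
        with pytest.raises(OtuTableError, match="normal"):
            read_otu_table(str(path))

    def test_label_column_and_label_file(self, tmp_path, small_table):
        path = tmp_path / "t.tsv"
        write_otu_table(small_table, str(path), label_column="label")
        back = read_otu_table(str(path), label_column="label")
        np.testing.assert_array_equal(back.labels, small_table.labels)

        lab = tmp_path / "labels.tsv"
        lab.write_text("s1\tcontrol\ns2\tcase\n")
        assert read_labels(str(lab)) == {"s1": 0, "s2": 1}

    def test_csv_autodetected(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("sample,g1,g2\ns1,3,4\ns2,0,2\n")
        t = read_otu_table(str(path))
        assert t.mode == "counts"
        assert t.values[0, 1] == 4


class TestValidation:
    def test_negative_rejected(self):
        with pytest.raises(OtuTableError, match="negative"):
            OtuTable(values=np.array([[-1.0, 2.0]]), sample_ids=["a"],
                     otu_ids=["x", "y"], mode="counts")

    def test_nan_rejected(self):
        with pytest.raises(OtuTableError, match="NaN"):
            OtuTable(values=np.array([[np.nan, 1.0]]), sample_ids=["a"],
                     otu_ids=["x", "y"], mode="counts")

    def test_bad_labels_rejected(self):
        with pytest.raises(OtuTableError, match="labels"):
            OtuTable(values=np.array([[1.0, 0.0]]), sample_ids=["a"],
                     otu_ids=["x", "y"], labels=np.array([2]), mode="relative")


class TestNormalize:
    def test_simple_row(self):
        t = OtuTable(values=np.array([[2.0, 2.0, 0.0, 4.0]]), sample_ids=["a"],
                     otu_ids=list("wxyz"), mode="counts")
        out = normalize_relative_abundance(t)
        np.testing.assert_allclose(out.values[0], [0.25, 0.25, 0.0, 0.5])
        assert out.mode == "relative"

    def test_already_relative_rejected(self, small_table):
        with pytest.raises(OtuTableError):
            normalize_relative_abundance(small_table)

    def test_all_zero_sample_named(self):
        t = OtuTable(values=np.array([[1.0, 1.0], [0.0, 0.0]]),
                     sample_ids=["ok", "empty"], otu_ids=["x", "y"],
                     mode="counts")
        with pytest.raises(OtuTableError, match="empty"):
            normalize_relative_abundance(t)

    def test_random_rows_sum_to_one(self):
        rng = np.random.default_rng(3)
        vals = rng.integers(0, 50, size=(20, 50)).astype(float)
        vals[:, 0] += 1  # no all-zero rows
        t = OtuTable(values=vals, sample_ids=[f"s{i}" for i in range(20)],
                     otu_ids=[f"o{i}" for i in range(50)], mode="counts")
        out = normalize_relative_abundance(t)
        np.testing.assert_allclose(out.values.sum(axis=1), 1.0, atol=1e-9)

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        row = rng.integers(1, 30, size=12).astype(float)
        base = OtuTable(values=row[None, :], sample_ids=["a"],
                        otu_ids=[f"o{i}" for i in range(12)], mode="counts")
        scaled = OtuTable(values=(row * 7.5)[None, :], sample_ids=["a"],
                          otu_ids=[f"o{i}" for i in range(12)], mode="counts")
        np.testing.assert_allclose(
            normalize_relative_abundance(base).values,
            normalize_relative_abundance(scaled).values, atol=1e-12)


class TestFilter:
    def test_all_zero_column_removed(self):
        vals = np.array([[1.0, 0.0, 2.0]] * 4)
        t = OtuTable(values=vals, sample_ids=list("abcd"),
                     otu_ids=["o1", "o2", "o3"], mode="counts")
        out, removed = filter_all_zero_otus(t)
        assert removed == ["o2"]
        assert out.otu_ids == ["o1", "o3"]

    def test_no_op_when_dense(self, small_table):
        out, removed = filter_all_zero_otus(small_table)
        assert removed == []
        assert out is small_table

    def test_matches_brute_force_on_sparse_random(self):
        rng = np.random.default_rng(9)
        vals = rng.random((50, 200)) * (rng.random((50, 200)) < 0.05)
        vals[:, 0] = 1.0
        t = OtuTable(values=vals, sample_ids=[f"s{i}" for i in range(50)],
                     otu_ids=[f"o{i}" for i in range(200)], mode="counts")
        out, removed = filter_all_zero_otus(t)
        expected_keep = [j for j in range(200) if (vals[:, j] != 0).any()]
        assert out.n_otus == len(expected_keep)
        assert len(removed) == 200 - len(expected_keep)

    def test_idempotent(self, sim_small):
        table, _, _ = sim_small
        once, _ = filter_all_zero_otus(table)
        twice, removed = filter_all_zero_otus(once)
        assert removed == []
        np.testing.assert_array_equal(once.values, twice.values)

    def test_empty_result_rejected(self):
        t = OtuTable(values=np.zeros((2, 2)), sample_ids=["a", "b"],
                     otu_ids=["x", "y"], mode="counts")
        with pytest.raises(OtuTableError):
            filter_all_zero_otus(t)


class TestTaxonomy:
    def test_qiime_lineage_parsed(self, tmp_path):
        path = tmp_path / "tax.tsv"
        path.write_text("g1\tk__Bacteria;p__Firmicutes;c__Clostridia;g__Blautia\n")
        tax = read_taxonomy(str(path))
        assert tax.phylum("g1") == "Firmicutes"

    def test_missing_phylum_errors(self, tmp_path):
        path = tmp_path / "tax.tsv"
        path.write_text("g1\tk__Bacteria;c__Clostridia\n")
        with pytest.raises(OtuTableError, match="g1"):
            read_taxonomy(str(path))

    def test_roundtrip_and_count(self, tmp_path, sim_small):
        _, tax, _ = sim_small
        path = tmp_path / "tax.tsv"
        write_taxonomy(tax, str(path))
        back = read_taxonomy(str(path))
        assert len(back) == len(tax)
        assert all(back.phylum(o) == tax.phylum(o) for o in tax.entries)
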