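"""Tables, labels, filters, tokenization and archive round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from biomico.data_io import (
    OtuTable,
    SampleLabels,
    align_test_table,
    filter_high_abundance_otus,
    filter_singleton_otus,
    load_model,
    read_otu_table,
    read_sample_labels,
    save_model,
    tokenize,
    write_otu_table,
)
from biomico.simulator import SimulationScenario, generate_dataset
from biomico.trainer import McmcConfig, dimensions_for, run_training


def write_tsv(path, text):
    path.write_text(text)
    return path


class TestReadOtuTable:
    def test_basic_parse(self, tmp_path):
        p = write_tsv(tmp_path / "t.tsv", "sample\totu1\totu2\totu3\ns1\t1\t0\t2\ns2\t0\t4\t0\n")
        table = read_otu_table(p)
        assert table.n_samples == 2 and table.n_otus == 3
        assert table.row_sums().tolist() == [3, 4]
        assert table.sample_ids == ["s1", "s2"]
        assert table.otu_ids == ["otu1", "otu2", "otu3"]

    def test_fractional_count_rejected_with_location(self, tmp_path):
        p = write_tsv(tmp_path / "t.tsv", "sample\totu1\ns1\t2.5\n")
        with pytest.raises(ValueError, match=r"s1.*otu1"):
            read_otu_table(p)

    def test_fractional_count_roundable_when_enabled(self, tmp_path):
        p = write_tsv(tmp_path / "t.tsv", "sample\totu1\ns1\t2.0\n")
        assert read_otu_table(p, round_counts=True).counts[0, 0] == 2

    def test_header_only_is_no_samples(self, tmp_path):
        p = write_tsv(tmp_path / "t.tsv", "sample\totu1\totu2\n")
        with pytest.raises(ValueError, match="no samples"):
            read_otu_table(p)

    def test_non_numeric_cell_located(self, tmp_path):
        p = write_tsv(tmp_path / "t.tsv", "sample\totu1\ns1\tabc\n")
        with pytest.raises(ValueError, match="non-numeric"):
            read_otu_table(p)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate sample identifier"):
            OtuTable(["s1", "s1"], ["o1"], np.array([[1], [2]]))
        with pytest.raises(ValueError, match="duplicate OTU identifier"):
            OtuTable(["s1"], ["o1", "o1"], np.array([[1, 2]]))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            OtuTable(["s1"], ["o1"], np.array([[-1]]))

    def test_tsv_round_trip(self, tmp_path, tiny_table):
        write_otu_table(tiny_table, tmp_path / "out.tsv")
        back = read_otu_table(tmp_path / "out.tsv")
        assert back.sample_ids == tiny_table.sample_ids
        assert back.otu_ids == tiny_table.otu_ids
        np.testing.assert_array_equal(back.counts, tiny_table.counts)

    def test_biom_v1_sparse(self, tmp_path):
        import json

        doc = {
            "format_url": "http://biom-format.org",
            "matrix_type": "sparse",
            "shape": [2, 2],
            "rows": [{"id": "o1"}, {"id": "o2"}],
            "columns": [{"id": "s1"}, {"id": "s2"}],
            "data": [[0, 0, 3], [1, 1, 5]],
        }
        p = tmp_path / "t.biom"
        p.write_text(json.dumps(doc))
        table = read_otu_table(p, dialect="biom")
        assert table.sample_ids == ["s1", "s2"]
        np.testing.assert_array_equal(table.counts, [[3, 0], [0, 5]])


class TestSampleLabels:
    def test_combined_column_vocabulary(self, tmp_path):
        # 2 hosts x 4 body sites pre-combined into one column -> K = 8
        rows = ["sample\thost_site"]
        sids = []
        for h in "AB":
            for s in ("gut", "tongue", "lpalm", "rpalm"):
                sid = f"{h}_{s}"
                sids.append(sid)
                rows.append(f"{sid}\t{h}|{s}")
        p = write_tsv(tmp_path / "l.tsv", "\n".join(rows) + "\n")
        labels, vocab = read_sample_labels(p, ["host_site"])
        assert len(vocab) == 8
        assert all(len(lab.factor_values) == 1 for lab in labels)

    def test_two_column_mode_union_vocabulary(self, tmp_path):
        p = write_tsv(
            tmp_path / "l.tsv",
            "sample\thost\tsite\ns1\tA\tgut\ns2\tB\tgut\n",
        )
        labels, vocab = read_sample_labels(p, ["host", "site"])
        assert vocab == ["host=A", "site=gut", "host=B"]
        assert labels[0].factor_values == frozenset({0, 1})
        assert len(labels[0].factor_values) == 2

    def test_identical_label_sets_share_indices(self, tmp_path):
        p = write_tsv(tmp_path / "l.tsv", "sample\tgrp\ns1\tx\ns2\tx\n")
        labels, vocab = read_sample_labels(p, ["grp"])
        assert labels[0].factor_values == labels[1].factor_values
        assert len(vocab) == 1

    def test_unknown_sample_skipped_with_warning(self, tmp_path, tiny_table):
        p = write_tsv(tmp_path / "l.tsv", "sample\tgrp\ns1\tx\nGHOST\ty\ns2\tx\n")
        with pytest.warns(UserWarning, match="GHOST"):
            labels, _ = read_sample_labels(p, ["grp"], table=tiny_table)
        assert [lab.sample_id for lab in labels] == ["s1", "s2"]

    def test_missing_column_errors(self, tmp_path):
        p = write_tsv(tmp_path / "l.tsv", "sample\tgrp\ns1\tx\n")
        with pytest.raises(ValueError, match="nope"):
            read_sample_labels(p, ["nope"])


class TestFilters:
    def test_singletons_removed(self):
        table = OtuTable(["s1", "s2"], ["o1", "o2", "o3"], np.array([[3, 0, 1], [0, 2, 1]]))
        filtered, report = filter_singleton_otus(table)
        assert filtered.otu_ids == ["o3"]
        assert set(report["removed_otus"]) == {"o1", "o2"}
        assert report["removed_count"] == 5

    def test_no_singletons_identity(self):
        table = OtuTable(["s1", "s2"], ["o1", "o2"], np.array([[1, 2], [3, 4]]))
        filtered, report = filter_singleton_otus(table)
        assert filtered.otu_ids == table.otu_ids
        assert report["removed_otus"] == []

    def test_single_sample_loses_all_nonzero_otus(self):
        table = OtuTable(["s1"], ["o1", "o2"], np.array([[5, 0]]))
        filtered, report = filter_singleton_otus(table)
        assert filtered.otu_ids == ["o2"]
        assert report["removed_otus"] == ["o1"]

    def test_singleton_filter_idempotent(self):
        rng = np.random.default_rng(0)
        table = OtuTable(
            [f"s{i}" for i in range(6)],
            [f"o{j}" for j in range(12)],
            rng.integers(0, 3, size=(6, 12)),
        )
        once, _ = filter_singleton_otus(table)
        twice, report = filter_singleton_otus(once)
        assert twice.otu_ids == once.otu_ids
        assert report["removed_otus"] == []

    def test_high_abundance_zeroed_columns_kept(self):
        table = OtuTable(["s1", "s2"], ["big", "small"], np.array([[50, 50], [60, 40]]))
        out = filter_high_abundance_otus(table, threshold=0.01)
        assert out.otu_ids == ["big", "small"]  # columns retained
        assert out.counts[:, 0].sum() == 0 and out.counts[:, 1].sum() == 0

    def test_mean_of_per_sample_fractions(self):
        # otu1 fractions: 0.9, 0.1 -> mean 0.5; otu2: 0.1, 0.9 -> mean 0.5
        table = OtuTable(["s1", "s2"], ["o1", "o2"], np.array([[9, 1], [10, 90]]))
        out = filter_high_abundance_otus(table, threshold=0.5)
        np.testing.assert_array_equal(out.counts, table.counts)  # 0.5 not exceeded
        out2 = filter_high_abundance_otus(table, threshold=0.49)
        assert out2.counts.sum() == 0

    def test_all_below_threshold_unchanged(self):
        table = OtuTable(["s1"], [f"o{j}" for j in range(200)], np.ones((1, 200), dtype=int))
        out = filter_high_abundance_otus(table, threshold=0.01)
        np.testing.assert_array_equal(out.counts, table.counts)

    def test_unknown_scope_errors(self, tiny_table):
        with pytest.raises(ValueError, match="unknown samples"):
            filter_high_abundance_otus(tiny_table, 0.1, scope=["nope"])


class TestTokenize:
    def test_expansion_order_and_counts(self, tiny_table, tiny_labels):
        data = tokenize(tiny_table, tiny_labels)
        np.testing.assert_array_equal(data.tokens[0], [0, 2, 2])
        np.testing.assert_array_equal(data.tokens[1], [1, 1, 1, 1])

    def test_unlabeled_sample_errors(self, tiny_table):
        with pytest.raises(ValueError, match="s2"):
            tokenize(tiny_table, [SampleLabels("s1", frozenset({0}))])

    def test_zero_row_errors(self):
        table = OtuTable(["s1"], ["o1"], np.array([[0]]))
        with pytest.raises(ValueError, match="all-zero"):
            tokenize(table, [SampleLabels("s1", frozenset({0}))])

    @settings(max_examples=25, deadline=None)
    @given(
        counts=arrays(
            np.int64,
            st.tuples(st.integers(1, 4), st.integers(1, 5)),
            elements=st.integers(0, 6),
        )
    )
    def test_token_histogram_inverts_counts(self, counts):
        counts = counts + (counts.sum(axis=1, keepdims=True) == 0)  # no all-zero rows
        table = OtuTable(
            [f"s{i}" for i in range(counts.shape[0])],
            [f"o{j}" for j in range(counts.shape[1])],
            counts,
        )
        labels = [SampleLabels(s, frozenset({0})) for s in table.sample_ids]
        data = tokenize(table, labels)
        for n in range(table.n_samples):
            hist = np.bincount(data.tokens[n], minlength=table.n_otus)
            np.testing.assert_array_equal(hist, counts[n])


class TestAlignTestTable:
    def test_permutation_only(self, tiny_table):
        aligned, report = align_test_table(tiny_table, ["otuC", "otuA", "otuB"])
        assert aligned.otu_ids == ["otuC", "otuA", "otuB"]
        np.testing.assert_array_equal(aligned.counts, [[2, 1, 0], [0, 0, 4]])
        assert report["dropped_otus"] == []

    def test_novel_otu_dropped_and_reported(self):
        test = OtuTable(["t1"], ["known", "novel"], np.array([[2, 7]]))
        aligned, report = align_test_table(test, ["known"])
        assert report["dropped_otus"] == ["novel"]
        assert report["dropped_count"] == 7
        assert aligned.counts.tolist() == [[2]]

    def test_row_sums_decrease_by_dropped(self):
        rng = np.random.default_rng(1)
        test = OtuTable(
            ["t1", "t2"],
            ["a", "b", "c"],
            rng.integers(0, 5, size=(2, 3)) + 1,
        )
        aligned, report = align_test_table(test, ["c", "a", "extra_training_otu"])
        np.testing.assert_array_equal(
            aligned.row_sums(), test.row_sums() - test.counts[:, 1]
        )
        # training OTU absent from test becomes a zero column
        assert aligned.counts[:, 2].sum() == 0

    def test_zero_overlap_errors(self, tiny_table):
        with pytest.raises(ValueError, match="no overlap"):
            align_test_table(tiny_table, ["x", "y"])


@pytest.fixture(scope="module")
def trained():
    scenario = SimulationScenario(
        n_samples=5, n_factors=2, n_assemblages=3, n_otus=10,
        tokens_per_sample=20, seed=3,
    )
    ds = generate_dataset(scenario)
    data = ds.tokenized()
    dims = dimensions_for(data, 3)
    config = McmcConfig(burn_in=5, total_iterations=25, thin=5, seed=1)
    return run_training(data, dims, config, otu_ids=ds.table.otu_ids)


class TestModelArchive:
    def test_round_trip_lossless(self, trained, tmp_path):
        save_model(trained, tmp_path / "model")
        back = load_model(tmp_path / "model")
        np.testing.assert_array_equal(back.final_counts.c_wl, trained.final_counts.c_wl)
        np.testing.assert_array_equal(back.final_counts.c_kl, trained.final_counts.c_kl)
        np.testing.assert_array_equal(back.final_counts.c_nk, trained.final_counts.c_nk)
        np.testing.assert_array_equal(back.hp_trace, trained.hp_trace)
        np.testing.assert_array_equal(back.log_prob_trace, trained.log_prob_trace)
        assert back.otu_ids == trained.otu_ids
        assert back.factor_names == trained.factor_names
        assert back.config == trained.config
        assert len(back.snapshots) == len(trained.snapshots)
        for a, b in zip(back.snapshots, trained.snapshots):
            np.testing.assert_array_equal(a.counts.c_wl, b.counts.c_wl)
            assert a.hp == b.hp

    def test_manifest_records_dimensions_and_schedule(self, trained, tmp_path):
        import json

        save_model(trained, tmp_path / "model")
        manifest = json.loads((tmp_path / "model" / "manifest.json").read_text())
        assert manifest["n_factors"] == trained.dims.n_factors
        assert manifest["n_assemblages"] == trained.dims.n_assemblages
        assert manifest["n_otus"] == trained.dims.n_otus
        assert manifest["config"]["total_iterations"] == 25

    def test_truncated_archive_errors(self, trained, tmp_path):
        save_model(trained, tmp_path / "model")
        npz = tmp_path / "model" / "arrays.npz"
        npz.write_bytes(npz.read_bytes()[:100])
        with pytest.raises(ValueError, match="corrupt"):
            load_model(tmp_path / "model")

    def test_version_mismatch_errors(self, trained, tmp_path):
        import json

        save_model(trained, tmp_path / "model")
        mpath = tmp_path / "model" / "manifest.json"
        manifest = json.loads(mpath.read_text())
        manifest["archive_version"] = 999
        mpath.write_text(json.dumps(manifest))
        with pytest.raises(ValueError, match="version"):
            load_model(tmp_path / "model")

    def test_missing_archive_errors(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_model(tmp_path / "nothing")
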