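import numpy as np
import pandas as pd
import pytest
import scipy.io
import scipy.sparse as sp

from lomo import simulate as sim
from lomo.datasets import (
    CELLTYPE,
    DONOR,
    SAMPLE,
    TIME,
    LongitudinalDataset,
    SingleCellDataset,
    collapse_replicates,
    filter_low_expression,
    filter_missing,
    filter_rare_celltypes,
    from_frames,
    load_bulk_dataset,
    load_single_cell,
    parse_timepoint,
    pseudobulk,
)


@pytest.mark.parametrize(
    "label, expected",
    [("W2", 2.0), ("D7", 7.0), ("Week6", 6.0), (3, 3.0), (2.5, 2.5), (" W10 ", 10.0)],
)
def test_parse_timepoint(label, expected):
    assert parse_timepoint(label) == expected


@pytest.mark.parametrize("label", ["", "week", float("nan"), "a-b"])
def test_parse_timepoint_rejects_nonnumeric(label):
    with pytest.raises(ValueError):
        parse_timepoint(label)


def _ann(rows):
    return pd.DataFrame(rows, columns=[SAMPLE, DONOR, TIME])


class TestFromFrames:
    def test_row_missing_donor_dropped(self):
        ann = _ann([["s1", "A", "W1"], ["s2", None, "W2"], ["s3", "B", "W1"]])
        mat = pd.DataFrame([[1.0, 2.0, 3.0]], index=["f"], columns=["s1", "s2", "s3"])
        ds = from_frames(ann, mat, SAMPLE, DONOR, TIME)
        assert list(ds.annotation.index) == ["s1", "s3"]
        assert ds.matrix.shape == (1, 2)

    def test_sample_order_invariance(self):
        ann = _ann([["s1", "A", 1], ["s2", "A", 2], ["s3", "B", 1]])
        mat = pd.DataFrame(
            [[1.0, 2.0, 3.0]], index=["f"], columns=["s1", "s2", "s3"]
        )
        shuffled = mat[["s3", "s1", "s2"]]
        a = from_frames(ann, mat, SAMPLE, DONOR, TIME)
        b = from_frames(ann, shuffled, SAMPLE, DONOR, TIME)
        pd.testing.assert_frame_equal(a.matrix, b.matrix)
        pd.testing.assert_frame_equal(a.annotation, b.annotation)

    def test_unannotated_matrix_column_dropped(self, caplog):
        ann = _ann([["s1", "A", 1], ["s2", "A", 2]])
        mat = pd.DataFrame(
            [[1.0, 2.0, 9.0]], index=["f"], columns=["s1", "s2", "sX"]
        )
        with caplog.at_level("WARNING", logger="lomo"):
            ds = from_frames(ann, mat, SAMPLE, DONOR, TIME)
        assert ds.matrix.shape == (1, 2)
        assert "1 matrix samples" in caplog.text

    def test_duplicate_sample_ids_error(self):
        ann = _ann([["s1", "A", 1], ["s1", "B", 2]])
        mat = pd.DataFrame([[1.0]], index=["f"], columns=["s1"])
        with pytest.raises(ValueError, match="duplicated sample ids"):
            from_frames(ann, mat, SAMPLE, DONOR, TIME)

    def test_zero_overlap_error(self):
        ann = _ann([["s1", "A", 1]])
        mat = pd.DataFrame([[1.0]], index=["f"], columns=["other"])
        with pytest.raises(ValueError, match="no overlapping"):
            from_frames(ann, mat, SAMPLE, DONOR, TIME)


def test_load_bulk_roundtrip(tmp_path, toy_bulk):
    """Text round-trip reproduces values exactly."""
    ann_p, mat_p = toy_bulk.to_tsv(tmp_path)
    ds = load_bulk_dataset(ann_p, mat_p)
    pd.testing.assert_frame_equal(ds.matrix, toy_bulk.matrix, check_exact=True)
    pd.testing.assert_frame_equal(
        ds.annotation[[DONOR, TIME]], toy_bulk.annotation[[DONOR, TIME]]
    )


class TestCollapseReplicates:
    def _with_reps(self, values):
        n = len(values)
        ann = pd.DataFrame(
            {DONOR: ["A"] * n, TIME: [1.0] * n},
            index=pd.Index([f"s{i}" for i in range(n)], name=SAMPLE),
        )
        mat = pd.DataFrame([values], index=["f"], columns=ann.index, dtype=float)
        return LongitudinalDataset(annotation=ann, matrix=mat)

    @pytest.mark.parametrize("values, expected", [([1, 3], 2.0), ([1, 2, 100], 2.0)])
    def test_median_of_replicates(self, values, expected):
        out = collapse_replicates(self._with_reps(values))
        assert out.n_samples == 1
        assert out.matrix.iloc[0, 0] == expected

    def test_no_replicates_identity(self, toy_bulk):
        out = collapse_replicates(toy_bulk)
        pd.testing.assert_frame_equal(out.matrix, toy_bulk.matrix)

    def test_idempotent(self):
        once = collapse_replicates(self._with_reps([1, 2, 100]))
        twice = collapse_replicates(once)
        pd.testing.assert_frame_equal(once.matrix, twice.matrix)


class TestFilterMissing:
    def _ds(self, na_counts, n=10):
        ann = pd.DataFrame(
            {DONOR: ["A"] * n, TIME: np.arange(n, dtype=float)},
            index=pd.Index([f"s{i}" for i in range(n)], name=SAMPLE),
        )
        rows = {}
        for name, k in na_counts.items():
            v = np.arange(n, dtype=float)
            v[:k] = np.nan
            rows[name] = v
        mat = pd.DataFrame(rows).T
        mat.columns = ann.index
        return LongitudinalDataset(annotation=ann, matrix=mat)

    def test_strict_boundary(self):
        ds = self._ds({"half": 5, "boundary": 4, "clean": 0})
        out = filter_missing(ds, na_cutoff=0.4)
        assert set(out.matrix.index) == {"boundary", "clean"}  # 0.4 not > 0.4

    def test_cutoff_one_is_identity(self):
        ds = self._ds({"allna": 10, "clean": 0})
        assert filter_missing(ds, na_cutoff=1.0).n_features == 2

    def test_cutoff_zero_removes_any_na(self):
        ds = self._ds({"one": 1, "clean": 0})
        assert list(filter_missing(ds, na_cutoff=0.0).matrix.index) == ["clean"]

    def test_all_removed_error(self):
        ds = self._ds({"a": 6, "b": 7})
        with pytest.raises(ValueError, match="all features removed"):
            filter_missing(ds, na_cutoff=0.4)


def _sc(values, donors, times, cts, genes=("g1",)):
    meta = pd.DataFrame(
        {DONOR: donors, TIME: [float(t) for t in times], CELLTYPE: cts},
        index=pd.Index([f"c{i}" for i in range(len(donors))], name="barcode"),
    )
    return SingleCellDataset(
        matrix=np.asarray(values, dtype=float), cell_meta=meta,
        gene_ids=pd.Index(genes),
    )


class TestPseudobulk:
    def test_group_mean_includes_zeros(self):
        sc = _sc([[0.0], [4.0]], ["A", "A"], [1, 1], ["T", "T"])
        pb = pseudobulk(sc)
        assert pb.values.iloc[0, 0] == 2.0
        assert pb.n_cells.iloc[0] == 2

    def test_singleton_group(self):
        sc = _sc([[3.5]], ["A"], [1], ["T"])
        assert pseudobulk(sc).values.iloc[0, 0] == 3.5

    def test_absent_group_is_masked_not_zero(self):
        sc = _sc([[1.0], [2.0]], ["A", "B"], [1, 1], ["T", "U"])
        pb = pseudobulk(sc)
        assert ("A", 1.0, "U") not in pb.values.columns
        assert pb.values.shape[1] == 2

    def test_cell_permutation_invariance_and_count_total(self):
        rng = np.random.default_rng(0)
        n = 30
        donors = rng.choice(["A", "B"], n)
        times = rng.choice([1, 2], n)
        cts = rng.choice(["T", "U"], n)
        vals = rng.random((n, 3))
        sc = _sc(vals, donors, times, cts, genes=("g1", "g2", "g3"))
        perm = rng.permutation(n)
        sc_p = _sc(vals[perm], donors[perm], times[perm], cts[perm],
                   genes=("g1", "g2", "g3"))
        a, b = pseudobulk(sc), pseudobulk(sc_p)
        pd.testing.assert_frame_equal(a.values, b.values)
        assert a.n_cells.sum() == n

    def test_sparse_matches_dense(self):
        rng = np.random.default_rng(1)
        vals = rng.random((20, 4)) * (rng.random((20, 4)) > 0.5)
        donors = rng.choice(["A", "B"], 20)
        sc_d = _sc(vals, donors, [1] * 20, ["T"] * 20, genes=list("wxyz"))
        sc_s = SingleCellDataset(
            matrix=sp.csr_matrix(vals), cell_meta=sc_d.cell_meta,
            gene_ids=sc_d.gene_ids,
        )
        pd.testing.assert_frame_equal(pseudobulk(sc_d).values, pseudobulk(sc_s).values)


class TestExpressionFilter:
    def _pb(self, gene_means):
        # 1 donor, 2 timepoints, 1 cell type; per-gene values constant = mean
        sc = _sc(
            [list(gene_means.values())] * 2, ["A", "A"], [1, 2], ["T", "T"],
            genes=tuple(gene_means),
        )
        return pseudobulk(sc)

    def test_boundary_kept_at_exactly_min_avg(self):
        pb = self._pb({"at": 0.1, "below": 0.09, "zero": 0.0})
        out = filter_low_expression(pb, min_avg=0.1)
        assert list(out.values.index) == ["at"]

    def test_best_donor_celltype_decides(self):
        # gene at 0.05 in one cell type but 0.2 in another -> kept
        sc = _sc([[0.05], [0.05], [0.2], [0.2]], ["A"] * 4, [1, 2, 1, 2],
                 ["T", "T", "U", "U"])
        out = filter_low_expression(pseudobulk(sc), min_avg=0.1)
        assert list(out.values.index) == ["g1"]


class TestCellTypeFilter:
    def test_rare_type_removed_and_mean_rule(self):
        # sample 1: 1/500 rare (0.2%); sample 2: 5/500 (1.0%) -> mean 0.6% kept
        donors, times, cts = [], [], []
        for stime, k in ((1, 1), (2, 5)):
            n = 500
            donors += ["A"] * n
            times += [stime] * n
            cts += ["rare"] * k + ["common"] * (n - k)
        sc = _sc(np.ones((1000, 1)), donors, times, cts)
        out = filter_rare_celltypes(sc, min_freq=0.005)
        assert set(out.cell_meta[CELLTYPE]) == {"rare", "common"}
        # 0.4% average -> removed
        donors2 = ["A"] * 1000
        cts2 = (["rare"] * 2 + ["common"] * 498) * 2
        sc2 = _sc(np.ones((1000, 1)), donors2, times, cts2)
        out2 = filter_rare_celltypes(sc2, min_freq=0.005)
        assert set(out2.cell_meta[CELLTYPE]) == {"common"}

    def test_single_celltype_unchanged(self):
        sc = _sc(np.ones((4, 1)), ["A"] * 4, [1] * 4, ["T"] * 4)
        assert filter_rare_celltypes(sc).n_cells == 4


def test_load_single_cell_mtx_matches_dense(tmp_path):
    spec = sim.SimulationSpec(seed=3, n_donors=2, n_timepoints=2, n_features=5,
                              n_celltypes=2, cells_per_group=4,
                              n_celltype_stable=0, n_global_stable=0,
                              n_global_variable=0)
    sc, _ = sim.simulate_single_cell(spec)
    # dense genes x cells TSV
    dense = pd.DataFrame(sc.dense().T, index=sc.gene_ids, columns=sc.cell_meta.index)
    dense.rename_axis("gene").to_csv(tmp_path / "m.tsv", sep="\t")
    sc.cell_meta.rename_axis("barcode").to_csv(tmp_path / "meta.tsv", sep="\t")
    # mtx triple (genes x cells)
    scipy.io.mmwrite(tmp_path / "m.mtx", sp.coo_matrix(sc.dense().T))
    (tmp_path / "features.tsv").write_text("\n".join(sc.gene_ids) + "\n")
    (tmp_path / "barcodes.tsv").write_text("\n".join(sc.cell_meta.index) + "\n")

    a = load_single_cell(tmp_path / "m.tsv", tmp_path / "meta.tsv")
    b = load_single_cell(tmp_path / "m.mtx", tmp_path / "meta.tsv",
                         tmp_path / "features.tsv", tmp_path / "barcodes.tsv")
    np.testing.assert_allclose(a.dense(), b.dense(), rtol=1e-12)
    pd.testing.assert_frame_equal(a.cell_meta, b.cell_meta)
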