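"""Data model and ingest for longitudinal omics data.

Bulk data are a feature x sample matrix bound to a sample-annotation table
(sample id, donor id, timepoint, optional covariates).  Single-cell data are
a cell x gene matrix of normalized expression plus per-cell metadata (donor,
timepoint, cell type).  Pseudo-bulking averages single-cell expression per
(donor, timepoint, cell type) group; absent groups are masked, never zero.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("lomo")

#: canonical annotation column names used internally
DONOR, TIME, CELLTYPE, SAMPLE = "donor", "timepoint", "cell_type", "sample_id"

_TIME_RE = re.compile(r"^\s*[A-Za-z_]*\s*(-?\d+(?:\.\d+)?)\s*$")


def parse_timepoint(label) -> float:
    """Extract the numeric value from a timepoint label.

    Accepts plain numbers and labels with an alphabetic prefix such as
    ``"W2"``, ``"D7"`` or ``"Week6"``.  Raises ``ValueError`` for labels
    without a numeric suffix.
    """
    if isinstance(label, (int, float, np.integer, np.floating)):
        val = float(label)
        if not np.isfinite(val):
            raise ValueError(f"non-finite timepoint: {label!r}")
        return val
    m = _TIME_RE.match(str(label))
    if m is None:
        raise ValueError(f"cannot parse timepoint label {label!r}")
    return float(m.group(1))


@dataclass
class LongitudinalDataset:
    """Bulk longitudinal dataset: annotation rows <-> matrix columns (1:1).

    ``annotation`` is indexed by sample id with at least ``donor`` and
    ``timepoint`` (numeric) columns; ``matrix`` holds features as rows and
    samples as columns, in annotation order.  Missing values are allowed.
    """

    annotation: pd.DataFrame
    matrix: pd.DataFrame
    modality: str = ""

    def __post_init__(self):
        ann, mat = self.annotation, self.matrix
        if not ann.index.is_unique:
            dup = ann.index[ann.index.duplicated()].tolist()
            raise ValueError(f"duplicated sample ids in annotation: {dup}")
        if not self.matrix.index.is_unique:
            raise ValueError("duplicated feature ids in matrix")
        if list(mat.columns) != list(ann.index):
            raise ValueError("matrix columns must match annotation rows 1:1")
        if ann[DONOR].isna().any() or ann[TIME].isna().any():
            raise ValueError("annotation contains missing donor or timepoint")
        if not np.isfinite(ann[TIME].to_numpy(dtype=float)).all():
            raise ValueError("non-finite timepoint values")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[0]

    @property
    def donors(self) -> list:
        return sorted(self.annotation[DONOR].unique())

    def to_tsv(self, outdir: str | Path, prefix: str = "dataset") -> tuple[Path, Path]:
        """Write annotation and matrix TSVs; values round-trip exactly."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ann_path = outdir / f"{prefix}_annotation.tsv"
        mat_path = outdir / f"{prefix}_matrix.tsv"
        self.annotation.rename_axis(SAMPLE).to_csv(ann_path, sep="\t")
        self.matrix.rename_axis("feature").to_csv(mat_path, sep="\t")
        return ann_path, mat_path


@dataclass
class SingleCellDataset:
    """Cell x gene normalized expression with per-cell metadata.

    ``matrix`` is cells x genes (dense ndarray or CSR); ``cell_meta`` is
    indexed by barcode with ``donor``, ``timepoint`` (numeric), ``cell_type``
    columns aligned to matrix rows.
    """

    matrix: np.ndarray | sp.spmatrix
    cell_meta: pd.DataFrame
    gene_ids: pd.Index
    modality: str = ""

    def __post_init__(self):
        self.gene_ids = pd.Index(self.gene_ids)
        if not self.gene_ids.is_unique:
            raise ValueError("duplicated gene ids")
        if self.matrix.shape != (len(self.cell_meta), len(self.gene_ids)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.cell_meta)} cells x {len(self.gene_ids)} genes"
            )
        for col in (DONOR, TIME, CELLTYPE):
            if col not in self.cell_meta.columns:
                raise ValueError(f"cell metadata lacks column {col!r}")
            if self.cell_meta[col].isna().any():
                raise ValueError(f"cell metadata has missing {col!r}")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    def dense(self) -> np.ndarray:
        m = self.matrix
        return m.toarray() if sp.issparse(m) else np.asarray(m)


@dataclass
class PseudoBulkTensor:
    """Mean normalized expression per (donor, timepoint, cell_type) group.

    ``values``: genes x groups (MultiIndex columns donor/timepoint/cell_type);
    a group column exists iff the group had >= 1 cell (the presence mask).
    ``n_cells`` gives the cell count per present group.
    """

    values: pd.DataFrame
    n_cells: pd.Series
    modality: str = ""

    def __post_init__(self):
        if list(self.values.columns.names) != [DONOR, TIME, CELLTYPE]:
            raise ValueError("columns must be a (donor, timepoint, cell_type) MultiIndex")
        if not self.values.columns.equals(self.n_cells.index):
            raise ValueError("n_cells index must match value columns")
        if (self.n_cells < 1).any():
            raise ValueError("present groups must have n_cells >= 1")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def donors(self) -> list:
        return sorted(self.values.columns.get_level_values(DONOR).unique())

    @property
    def cell_types(self) -> list:
        return sorted(self.values.columns.get_level_values(CELLTYPE).unique())


# ---------------------------------------------------------------------------
# ingest


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, index_col=0)


def _normalize_ids(idx) -> pd.Index:
    return pd.Index([str(x).strip() for x in idx])


def from_frames(
    annotation: pd.DataFrame,
    matrix: pd.DataFrame,
    sample_col: str,
    donor_col: str,
    time_col: str,
    modality: str = "",
) -> LongitudinalDataset:
    """Bind an annotation table to a feature x sample matrix.

    Rows missing sample, donor or timepoint are dropped (and counted in the
    log); matrix columns without annotation are dropped with a warning.
    Raises on duplicated sample ids or zero overlapping samples.
    """
    ann = annotation.reset_index() if sample_col == annotation.index.name else annotation.copy()
    if sample_col not in ann.columns:
        ann = annotation.reset_index().rename(columns={"index": sample_col})
    for col in (sample_col, donor_col, time_col):
        if col not in ann.columns:
            raise ValueError(f"annotation lacks column {col!r}")

    n0 = len(ann)
    ann = ann.dropna(subset=[sample_col, donor_col, time_col])
    if n0 - len(ann):
        logger.info("dropped %d annotation rows missing sample/donor/timepoint", n0 - len(ann))

    ann[sample_col] = [str(x).strip() for x in ann[sample_col]]
    if ann[sample_col].duplicated().any():
        dup = sorted(ann[sample_col][ann[sample_col].duplicated()].unique())
        raise ValueError(f"duplicated sample ids: {dup}")

    out = pd.DataFrame(
        {
            DONOR: [str(x).strip() for x in ann[donor_col]],
            TIME: [parse_timepoint(x) for x in ann[time_col]],
        },
        index=pd.Index(ann[sample_col], name=SAMPLE),
    )
    extra = [c for c in ann.columns if c not in (sample_col, donor_col, time_col)]
    for c in extra:
        out[c] = ann[c].to_numpy()

    mat = matrix.copy()
    mat.columns = _normalize_ids(mat.columns)
    mat.index = _normalize_ids(mat.index).rename(matrix.index.name or "feature")
    unmatched = [c for c in mat.columns if c not in out.index]
    if unmatched:
        logger.warning("dropping %d matrix samples absent from annotation", len(unmatched))
        mat = mat.drop(columns=unmatched)
    keep = [s for s in out.index if s in set(mat.columns)]
    if not keep:
        raise ValueError("no overlapping samples between annotation and matrix")
    dropped_ann = len(out) - len(keep)
    if dropped_ann:
        logger.info("dropped %d annotated samples absent from matrix", dropped_ann)
    out = out.loc[keep]
    mat = mat[keep].astype(float)
    mat.columns = out.index
    return LongitudinalDataset(annotation=out, matrix=mat, modality=modality)


def load_bulk_dataset(
    annotation_file: str | Path,
    matrix_file: str | Path,
    sample_col: str = SAMPLE,
    donor_col: str = DONOR,
    time_col: str = TIME,
    modality: str = "",
) -> LongitudinalDataset:
    """Load a bulk dataset from delimited annotation and matrix files.

    Files are TSV (or CSV by extension); the matrix has features as rows and
    samples as columns with a header row.
    """
    ann = pd.read_csv(
        Path(annotation_file),
        sep="," if str(annotation_file).lower().endswith(".csv") else "\t",
    )
    mat = _read_table(matrix_file)
    return from_frames(ann, mat, sample_col, donor_col, time_col, modality=modality)


def load_single_cell(
    matrix_file: str | Path,
    cell_meta_file: str | Path,
    features_file: str | Path | None = None,
    barcodes_file: str | Path | None = None,
    donor_col: str = DONOR,
    time_col: str = TIME,
    celltype_col: str = CELLTYPE,
    modality: str = "",
) -> SingleCellDataset:
    """Load single-cell expression from MTX (genes x cells) or dense TSV.

    MTX input follows the features/barcodes sidecar convention; dense input
    is a genes x cells TSV.  ``cell_meta_file`` maps barcodes to donor,
    timepoint and cell type.
    """
    matrix_file = Path(matrix_file)
    if matrix_file.suffix == ".mtx":
        if features_file is None or barcodes_file is None:
            raise ValueError("MTX input requires features and barcodes files")
        m = scipy.io.mmread(str(matrix_file)).tocsr().T.tocsr()  # -> cells x genes
        genes = pd.Index(pd.read_csv(features_file, sep="\t", header=None)[0].astype(str),
                         name="gene")
        barcodes = pd.Index(pd.read_csv(barcodes_file, sep="\t", header=None)[0].astype(str),
                            name="barcode")
    else:
        df = _read_table(matrix_file)  # genes x cells
        m = df.to_numpy(dtype=float).T
        genes = pd.Index(df.index.astype(str), name="gene")
        barcodes = pd.Index(df.columns.astype(str), name="barcode")

    meta = _read_table(cell_meta_file)
    meta.index = _normalize_ids(meta.index)
    missing = [b for b in barcodes if b not in meta.index]
    if missing:
        raise ValueError(f"{len(missing)} barcodes lack metadata (first: {missing[0]!r})")
    meta = meta.loc[barcodes]
    cm = pd.DataFrame(
        {
            DONOR: [str(x).strip() for x in meta[donor_col]],
            TIME: [parse_timepoint(x) for x in meta[time_col]],
            CELLTYPE: [str(x).strip() for x in meta[celltype_col]],
        },
        index=barcodes,
    )
    return SingleCellDataset(matrix=m, cell_meta=cm, gene_ids=genes, modality=modality)


# ---------------------------------------------------------------------------
# transforms


def collapse_replicates(ds: LongitudinalDataset) -> LongitudinalDataset:
    """Collapse replicated samples (same donor and timepoint) to their median.

    Missing values are ignored within each replicate group.  Idempotent; a
    dataset without replicates is returned unchanged.
    """
    key = list(zip(ds.annotation[DONOR], ds.annotation[TIME]))
    if len(set(key)) == len(key):
        return ds
    groups: dict[tuple, list[str]] = {}
    for samp, k in zip(ds.annotation.index, key):
        groups.setdefault(k, []).append(samp)
    cols, ann_rows, names = [], [], []
    for k, samples in groups.items():
        rep = samples[0]
        if len(samples) > 1:
            logger.info("collapsing %d replicates for donor=%s t=%g", len(samples), *k)
        cols.append(ds.matrix[samples].median(axis=1, skipna=True))
        ann_rows.append(ds.annotation.loc[rep])
        names.append(rep)
    mat = pd.concat(cols, axis=1)
    mat.columns = names
    ann = pd.DataFrame(ann_rows, index=pd.Index(names, name=SAMPLE))
    return LongitudinalDataset(annotation=ann, matrix=mat, modality=ds.modality)


def filter_missing(ds: LongitudinalDataset, na_cutoff: float = 0.4) -> LongitudinalDataset:
    """Drop features whose NA fraction is strictly above ``na_cutoff``."""
    if not 0 <= na_cutoff <= 1:
        raise ValueError("na_cutoff must be in [0, 1]")
    frac = ds.matrix.isna().mean(axis=1)
    removed = ds.matrix.index[frac > na_cutoff]
    if len(removed) == len(ds.matrix):
        raise ValueError("all features removed by NA filter")
    if len(removed):
        logger.info("NA filter removed %d/%d features (cutoff %.2f)",
                    len(removed), ds.n_features, na_cutoff)
    out = replace(ds, matrix=ds.matrix.drop(index=removed))
    out.removed_features = list(removed)  # type: ignore[attr-defined]
    return out


def pseudobulk(sc: SingleCellDataset) -> PseudoBulkTensor:
    """Average expression per (donor, timepoint, cell_type) group.

    The mean runs over *all* cells of the group, zeros included.  Groups with
    no cells are simply absent (masked) — absence is not zero expression.
    """
    meta = sc.cell_meta
    codes, groups = pd.factorize(
        pd.MultiIndex.from_frame(meta[[DONOR, TIME, CELLTYPE]]), sort=True
    )
    n_groups = len(groups)
    counts = np.bincount(codes, minlength=n_groups)
    ind = sp.csr_matrix(
        (np.ones(len(codes)), (codes, np.arange(len(codes)))),
        shape=(n_groups, sc.n_cells),
    )
    sums = ind @ sc.matrix  # groups x genes
    sums = np.asarray(sums.todense()) if sp.issparse(sums) else np.asarray(sums)
    means = sums / counts[:, None]
    cols = pd.MultiIndex.from_tuples(groups, names=[DONOR, TIME, CELLTYPE])
    values = pd.DataFrame(means.T, index=sc.gene_ids, columns=cols)
    n_cells = pd.Series(counts, index=cols, name="n_cells")
    return PseudoBulkTensor(values=values, n_cells=n_cells, modality=sc.modality)


def filter_low_expression(pb: PseudoBulkTensor, min_avg: float = 0.1) -> PseudoBulkTensor:
    """Keep genes whose mean-over-timepoints expression reaches ``min_avg``
    in at least one (donor, cell_type) pair."""
    mean_over_time = pb.values.T.groupby(level=[DONOR, CELLTYPE]).mean().T
    keep = mean_over_time.max(axis=1) >= min_avg
    dropped = int((~keep).sum())
    if dropped:
        logger.info("expression filter removed %d/%d genes (min avg %.3g)",
                    dropped, len(keep), min_avg)
    return replace(pb, values=pb.values.loc[keep])


def filter_rare_celltypes(sc: SingleCellDataset, min_freq: float = 0.005) -> SingleCellDataset:
    """Drop cell types with mean per-sample frequency below ``min_freq``.

    Frequency is cells-of-type / cells-in-sample, computed per (donor,
    timepoint) sample and averaged over samples (samples where the type is
    absent count as 0).
    """
    meta = sc.cell_meta
    tab = meta.groupby([DONOR, TIME, CELLTYPE]).size().unstack(CELLTYPE, fill_value=0)
    freq = tab.div(tab.sum(axis=1), axis=0).mean(axis=0)
    keep_types = freq.index[freq >= min_freq]
    if len(keep_types) == 0:
        raise ValueError("all cell types removed by frequency filter")
    dropped = sorted(set(freq.index) - set(keep_types))
    if dropped:
        logger.info("frequency filter removed cell types: %s", dropped)
    keep_cells = meta[CELLTYPE].isin(keep_types).to_numpy()
    mat = sc.matrix[keep_cells]
    return SingleCellDataset(
        matrix=mat, cell_meta=meta.loc[keep_cells], gene_ids=sc.gene_ids, modality=sc.modality
    )
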