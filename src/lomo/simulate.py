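"""Ground-truth synthetic generators for longitudinal omics data.

These emulate the data shapes the analysis modules are built for — a
multi-donor bulk matrix over weekly timepoints with additive donor / time /
residual variance components, and a multi-donor, multi-cell-type single-cell
dataset with designed stability structure — so every module can be exercised
against known truth.  Two presets mirror typical study designs: ``bulk6x10``
(6 donors x 10 weekly timepoints, 1042 features, the scale of a plasma
proteomics panel) and ``sc4x6x19`` (4 donors x 6 weekly timepoints x 19 cell
types).

Single-cell noise is log-normal signal with Bernoulli dropout; the
downstream modules consume normalized expression and pseudo-bulk means, so
this is the simplest model that exercises every contract (it does not
attempt count-level realism such as library-size or batch effects).
All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from lomo.datasets import (
    CELLTYPE,
    DONOR,
    SAMPLE,
    TIME,
    LongitudinalDataset,
    SingleCellDataset,
)

GENE_CLASSES = ("celltype_stable", "global_stable", "global_variable", "null")


@dataclass
class SimulationSpec:
    """Design and noise parameters for the generators.

    Variances are on the observation scale for bulk data; for single-cell
    data the stability sigmas are log-scale SDs of the per-(donor, timepoint)
    group means, so sigma ~ CV (a sigma of 0.02 targets ~2% across-time CV).
    """

    seed: int
    n_donors: int = 6
    n_timepoints: int = 10
    n_features: int = 100
    n_celltypes: int = 1
    cells_per_group: int = 150
    # bulk variance components
    sigma2_donor: float = 1.0
    sigma2_time: float = 0.25
    sigma2_resid: float = 0.5
    baseline_mean: float = 8.0
    # single-cell stability design
    n_celltype_stable: int = 10
    n_global_stable: int = 10
    n_global_variable: int = 10
    stable_sigma: float = 0.02
    variable_sigma: float = 0.40
    null_sigma: float = 0.15
    cell_sigma: float = 0.25
    detection_prob: float = 0.9

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("sigma2_donor", "sigma2_time", "sigma2_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def bulk6x10(seed: int, **overrides) -> SimulationSpec:
    """6 donors x 10 weekly timepoints, 1042 features (plasma-panel scale)."""
    return replace(
        SimulationSpec(seed=seed, n_donors=6, n_timepoints=10, n_features=1042),
        **overrides,
    )


def sc4x6x19(seed: int, **overrides) -> SimulationSpec:
    """4 donors x 6 weekly timepoints x 19 cell types.

    Designed gene groups default to a sixth of the features each so the
    preset stays valid for any requested gene count.
    """
    spec = replace(
        SimulationSpec(
            seed=seed, n_donors=4, n_timepoints=6, n_celltypes=19,
            n_features=60, cells_per_group=150,
        ),
        **overrides,
    )
    group_defaults = {"n_celltype_stable", "n_global_stable", "n_global_variable"}
    if not group_defaults & overrides.keys():
        n_each = max(1, spec.n_features // 6)
        spec = replace(spec, n_celltype_stable=n_each, n_global_stable=n_each,
                       n_global_variable=n_each)
    return spec


def simulate_bulk_longitudinal(
    spec: SimulationSpec,
) -> tuple[LongitudinalDataset, pd.DataFrame]:
    """Bulk matrix with additive donor/time/residual variance components.

    y[f, d, t] = mu_f + a[f, d] + b[f, t] + eps with a ~ N(0, sigma2_donor),
    b ~ N(0, sigma2_time), eps ~ N(0, sigma2_resid).  The truth table stores
    the expected variance fractions per feature (identical across features by
    construction).
    """
    rng = np.random.default_rng(spec.seed)
    nd, nt, nf = spec.n_donors, spec.n_timepoints, spec.n_features
    donors = [f"D{i + 1}" for i in range(nd)]
    weeks = np.arange(1, nt + 1, dtype=float)
    mu = spec.baseline_mean + rng.normal(0, 1, size=nf)
    a = rng.normal(0, np.sqrt(spec.sigma2_donor), size=(nf, nd))
    b = rng.normal(0, np.sqrt(spec.sigma2_time), size=(nf, nt))
    eps = rng.normal(0, np.sqrt(spec.sigma2_resid), size=(nf, nd, nt))
    y = mu[:, None, None] + a[:, :, None] + b[:, None, :] + eps

    samples, donor_col, time_col = [], [], []
    for i, d in enumerate(donors):
        for t in weeks:
            samples.append(f"{d}_W{int(t)}")
            donor_col.append(d)
            time_col.append(t)
    ann = pd.DataFrame(
        {DONOR: donor_col, TIME: time_col},
        index=pd.Index(samples, name=SAMPLE),
    )
    mat = pd.DataFrame(
        y.reshape(nf, nd * nt),
        index=pd.Index([f"F{i + 1:04d}" for i in range(nf)], name="feature"),
        columns=samples,
    )
    total = spec.sigma2_donor + spec.sigma2_time + spec.sigma2_resid
    truth = pd.DataFrame(
        {
            "feature": mat.index,
            "frac_donor": spec.sigma2_donor / total if total else np.nan,
            "frac_timepoint": spec.sigma2_time / total if total else np.nan,
            "frac_residual": spec.sigma2_resid / total if total else np.nan,
        }
    ).set_index("feature")
    return LongitudinalDataset(annotation=ann, matrix=mat), truth


def simulate_single_cell(
    spec: SimulationSpec,
) -> tuple[SingleCellDataset, pd.DataFrame]:
    """Single-cell dataset with designed stability classes.

    Gene classes (truth table column ``gene_class``):

    * ``celltype_stable`` — low across-time log-SD (``stable_sigma``) in one
      designated cell type for all donors, high (``variable_sigma``)
      elsewhere: the STATIC design;
    * ``global_stable`` — low everywhere (SUS design);
    * ``global_variable`` — high everywhere (SUV design);
    * ``null`` — intermediate (``null_sigma``) everywhere.

    Cell-level expression is lognormal around the group mean times a
    Bernoulli detection indicator.
    """
    rng = np.random.default_rng(spec.seed)
    nd, nt, nc, ng = spec.n_donors, spec.n_timepoints, spec.n_celltypes, spec.n_features
    n_designed = spec.n_celltype_stable + spec.n_global_stable + spec.n_global_variable
    if n_designed > ng:
        raise ValueError("designed gene groups exceed n_features")
    donors = [f"D{i + 1}" for i in range(nd)]
    weeks = np.arange(1, nt + 1, dtype=float)
    cts = [f"CT{i + 1:02d}" for i in range(nc)]
    genes = [f"G{i + 1:04d}" for i in range(ng)]

    classes = np.array(
        ["celltype_stable"] * spec.n_celltype_stable
        + ["global_stable"] * spec.n_global_stable
        + ["global_variable"] * spec.n_global_variable
        + ["null"] * (ng - n_designed)
    )
    static_ct = np.full(ng, "", dtype=object)
    static_ct[: spec.n_celltype_stable] = [
        cts[i % nc] for i in range(spec.n_celltype_stable)
    ]

    # per (gene, cell type) log-scale across-time SD
    sigma = np.full((ng, nc), spec.null_sigma)
    sigma[classes == "global_stable"] = spec.stable_sigma
    sigma[classes == "global_variable"] = spec.variable_sigma
    for g in np.flatnonzero(classes == "celltype_stable"):
        sigma[g] = spec.variable_sigma
        sigma[g, cts.index(static_ct[g])] = spec.stable_sigma

    base_mu = rng.normal(1.0, 0.4, size=(ng, nc))  # log baseline per gene x cell type

    metas, blocks = [], []
    for d in donors:
        for t in weeks:
            for ci, ct in enumerate(cts):
                group_mu = base_mu[:, ci] + rng.normal(0, sigma[:, ci])
                n_cells = spec.cells_per_group
                logex = rng.normal(
                    group_mu[None, :], spec.cell_sigma, size=(n_cells, ng)
                )
                detect = rng.random((n_cells, ng)) < spec.detection_prob
                blocks.append(np.exp(logex) * detect)
                metas.append(
                    pd.DataFrame(
                        {DONOR: d, TIME: t, CELLTYPE: ct}, index=range(n_cells)
                    )
                )
    mat = np.vstack(blocks)
    meta = pd.concat(metas, ignore_index=True)
    meta.index = pd.Index([f"cell{i:07d}" for i in range(len(meta))], name="barcode")
    sc = SingleCellDataset(matrix=mat, cell_meta=meta, gene_ids=pd.Index(genes))
    truth = pd.DataFrame(
        {"gene": genes, "gene_class": classes, "static_celltype": static_ct}
    ).set_index("gene")
    return sc, truth


def inject_outlier_timepoint(
    ds: LongitudinalDataset,
    donor: str,
    timepoint: float,
    fraction: float,
    shift: float,
    seed: int,
) -> tuple[LongitudinalDataset, pd.DataFrame]:
    """Shift a random fraction of features at one (donor, timepoint) sample.

    Each selected feature is moved by ``shift`` donor-SDs (SD of that
    feature across the donor's timepoints, n-1 denominator).  Returns the
    modified dataset and a truth table of affected features.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    ann = ds.annotation
    target = ann.index[(ann[DONOR] == donor) & (ann[TIME] == timepoint)]
    if len(target) == 0:
        raise ValueError(f"no sample for donor={donor!r} t={timepoint!r}")
    rng = np.random.default_rng(seed)
    n_affected = int(round(fraction * ds.n_features))
    affected = rng.choice(ds.matrix.index, size=n_affected, replace=False)
    mat = ds.matrix.copy()
    donor_samples = ann.index[ann[DONOR] == donor]
    sd = mat.loc[affected, donor_samples].std(axis=1, ddof=1)
    for s in target:
        mat.loc[affected, s] = mat.loc[affected, s] + shift * sd
    truth = pd.DataFrame(
        {"feature": affected, "donor": donor, "timepoint": timepoint, "shift": shift}
    ).set_index("feature")
    out = LongitudinalDataset(annotation=ann.copy(), matrix=mat, modality=ds.modality)
    return out, truth


def inject_temporal_trend(
    sc: SingleCellDataset,
    genes: list[str],
    slope: float,
) -> tuple[SingleCellDataset, pd.DataFrame]:
    """Add a linear-in-time shift to expressing cells of the listed genes.

    Expression of detected cells (value > 0) moves by slope * (t - mean t);
    results are floored at a small positive value so detection status is
    unchanged (the truth table records how many cells were clipped).
    """
    idx = []
    for g in genes:
        loc = sc.gene_ids.get_indexer([g])
        if loc[0] < 0:
            raise ValueError(f"unknown gene {g!r}")
        idx.append(loc[0])
    mat = sc.dense().copy()
    t = sc.cell_meta[TIME].to_numpy(dtype=float)
    tc = t - t.mean()
    clipped = []
    floor = 1e-6
    for j in idx:
        col = mat[:, j]
        pos = col > 0
        shifted = col[pos] + slope * tc[pos]
        clipped.append(int((shifted < floor).sum()))
        col[pos] = np.maximum(shifted, floor)
        mat[:, j] = col
    out = SingleCellDataset(
        matrix=mat, cell_meta=sc.cell_meta.copy(), gene_ids=sc.gene_ids,
        modality=sc.modality,
    )
    truth = pd.DataFrame(
        {"gene": genes, "slope": slope, "n_clipped": clipped}
    ).set_index("gene")
    return out, truth
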