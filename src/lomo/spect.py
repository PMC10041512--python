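"""Stability patterns across cell types from single-cell pseudo-bulk.

The coefficient of variation of each gene is computed across timepoints
separately for every (donor, cell type) combination of a pseudo-bulk tensor.
Each defined entry is called stable (CV < cvThreshold) or variable
(CV > cvThreshold); counting calls over the donor x cell-type grid yields
four gene classes:

* SUV / SUS — super variable / super stable: variable (stable) in at least
  ``groupThreshold`` combinations (default ceil(n_donor * n_celltype / 2));
* VATIC / STATIC — variable (stable) across time in cell types: below the
  super threshold but consistently variable (stable) in at least one cell
  type across all donors with a defined entry there.

SUV and SUS are mutually exclusive; VATIC and STATIC can co-occur since a
gene may be consistently variable in one cell type and consistently stable
in another.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from lomo.cvp import cv
from lomo.datasets import CELLTYPE, DONOR, TIME, PseudoBulkTensor

logger = logging.getLogger("lomo")

SUV, SUS, VATIC, STATIC = "SUV", "SUS", "VATIC", "STATIC"


def cv_profile_sc(pb: PseudoBulkTensor, cv_threshold: float = 10.0) -> pd.DataFrame:
    """CV across timepoints per (gene, donor, cell_type), with calls.

    Combinations covered by fewer than 2 timepoints are masked (no row).
    Returns a long DataFrame: gene, donor, cell_type, mean, sd, cv,
    n_timepoints, defined, call ("stable" / "variable" / "" when the CV is
    undefined or exactly at the threshold).
    """
    vals = pb.values
    eps = 1e-8 * float(np.nanmax(np.abs(vals.to_numpy()))) if vals.size else 0.0
    rows = []
    cols = vals.columns.to_frame(index=False)
    for (donor, ct), sub in cols.groupby([DONOR, CELLTYPE], sort=True):
        if len(sub) < 2:
            continue
        block = vals.iloc[:, sub.index.to_numpy()].to_numpy()
        m = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cvs = 100.0 * sd / m
        defined = np.abs(m) > eps
        cvs = np.where(defined, cvs, np.nan)
        call = np.where(
            defined & (cvs < cv_threshold), "stable",
            np.where(defined & (cvs > cv_threshold), "variable", ""),
        )
        rows.append(
            pd.DataFrame(
                {
                    "gene": vals.index,
                    "donor": donor,
                    "cell_type": ct,
                    "mean": m,
                    "sd": sd,
                    "cv": cvs,
                    "n_timepoints": len(sub),
                    "defined": defined,
                    "call": call,
                }
            )
        )
    if not rows:
        raise ValueError("no (donor, cell_type) combination with >= 2 timepoints")
    out = pd.concat(rows, ignore_index=True)
    out.attrs["cv_threshold"] = cv_threshold
    return out


def default_group_threshold(n_donor: int, n_celltype: int) -> int:
    """Half the donor x cell-type combinations, rounded up."""
    return math.ceil(n_donor * n_celltype / 2)


@dataclass
class StabilityClassification:
    """Gene-level SUV/SUS/VATIC/STATIC labels with supporting evidence."""

    table: pd.DataFrame  # gene-indexed
    cv_threshold: float
    group_threshold: int
    n_donor: int
    n_celltype: int


def classify_stability(
    cvt: pd.DataFrame,
    group_threshold: int | None = None,
    min_defined_donors: int = 2,
) -> StabilityClassification:
    """Four-way stability classification from a single-cell CV table.

    ``count_stable`` / ``count_variable`` count calls over all defined
    (donor, cell_type) combinations.  SUV iff count_variable >=
    ``group_threshold``; SUS iff count_stable >= ``group_threshold``.
    VATIC (STATIC) iff not SUV (SUS) and the gene is variable (stable) in
    *all* donors with a defined entry for at least one cell type, requiring
    at least ``min_defined_donors`` defined donors so masked combinations
    cannot satisfy the universal condition vacuously.
    """
    n_donor = cvt["donor"].nunique()
    n_celltype = cvt["cell_type"].nunique()
    if group_threshold is None:
        group_threshold = default_group_threshold(n_donor, n_celltype)
    if group_threshold <= 0:
        raise ValueError("group_threshold must be positive")

    counts = (
        cvt.pivot_table(index="gene", columns="call", values="donor",
                        aggfunc="count", fill_value=0)
        .reindex(columns=["stable", "variable"], fill_value=0)
    )
    # per (gene, cell_type): all defined donors share the call?
    percell = (
        cvt[cvt["defined"]]
        .groupby(["gene", "cell_type"])["call"]
        .agg(n_defined="size",
             n_stable=lambda s: int((s == "stable").sum()),
             n_variable=lambda s: int((s == "variable").sum()))
        .reset_index()
    )
    enough = percell["n_defined"] >= min_defined_donors
    all_stable = enough & (percell["n_stable"] == percell["n_defined"])
    all_variable = enough & (percell["n_variable"] == percell["n_defined"])

    def _support(mask) -> pd.Series:
        sel = percell[mask]
        return sel.groupby("gene")["cell_type"].agg(lambda s: tuple(sorted(s)))

    stable_support = _support(all_stable)
    variable_support = _support(all_variable)

    genes = pd.Index(sorted(cvt["gene"].unique()), name="gene")
    tab = pd.DataFrame(index=genes)
    tab["count_stable"] = counts["stable"].reindex(genes, fill_value=0).astype(int)
    tab["count_variable"] = counts["variable"].reindex(genes, fill_value=0).astype(int)
    tab[SUV] = tab["count_variable"] >= group_threshold
    tab[SUS] = tab["count_stable"] >= group_threshold
    vs = variable_support.reindex(genes)
    ss = stable_support.reindex(genes)
    tab[VATIC] = ~tab[SUV] & vs.notna()
    tab[STATIC] = ~tab[SUS] & ss.notna()
    tab["vatic_celltypes"] = [v if isinstance(v, tuple) else () for v in vs]
    tab["static_celltypes"] = [v if isinstance(v, tuple) else () for v in ss]
    logger.info(
        "SPECT: %d SUV, %d SUS, %d VATIC, %d STATIC of %d genes "
        "(groupThreshold %d over %d x %d combinations)",
        tab[SUV].sum(), tab[SUS].sum(), tab[VATIC].sum(), tab[STATIC].sum(),
        len(tab), group_threshold, n_donor, n_celltype,
    )
    return StabilityClassification(
        table=tab, cv_threshold=float(cvt.attrs.get("cv_threshold", np.nan)),
        group_threshold=group_threshold, n_donor=n_donor, n_celltype=n_celltype,
    )


def select_top_static(
    classification: StabilityClassification,
    cvt: pd.DataFrame,
    per_celltype: int = 25,
) -> pd.DataFrame:
    """Top STATIC genes per supporting cell type, deduplicated into a panel.

    Within each cell type, STATIC genes supported by that cell type are
    ranked by ascending maximum CV across donors there (the most conservative
    stability statistic), ties broken by mean CV then gene id; up to
    ``per_celltype`` are taken.  Returns a long DataFrame (cell_type, gene,
    rank, max_cv, mean_cv); the unique panel is
    ``result["gene"].unique()``.
    """
    tab = classification.table
    static_genes = tab.index[tab[STATIC]]
    rows = []
    for ct in sorted(cvt["cell_type"].unique()):
        supported = [g for g in static_genes if ct in tab.at[g, "static_celltypes"]]
        if not supported:
            logger.warning("cell type %s contributes no STATIC genes", ct)
            continue
        sub = cvt[(cvt["cell_type"] == ct) & cvt["defined"] & cvt["gene"].isin(supported)]
        stats = sub.groupby("gene")["cv"].agg(max_cv="max", mean_cv="mean")
        stats = stats.sort_values(["max_cv", "mean_cv", "gene"]).head(per_celltype)
        for rank, (gene, row) in enumerate(stats.iterrows(), start=1):
            rows.append({"cell_type": ct, "gene": gene, "rank": rank,
                         "max_cv": row["max_cv"], "mean_cv": row["mean_cv"]})
    panel = pd.DataFrame(rows, columns=["cell_type", "gene", "rank", "max_cv", "mean_cv"])
    logger.info("STATIC panel: %d entries, %d unique genes",
                len(panel), panel["gene"].nunique())
    return panel


def overlap_enrichment(
    panel: set | list, reference: set | list, universe_size: int
) -> tuple[int, float]:
    """Overlap size and one-sided (upper-tail) hypergeometric p-value.

    Tests whether ``panel`` and ``reference`` (both subsets of a universe of
    ``universe_size`` genes) overlap more than chance:
    p = P(X >= overlap) with X ~ Hypergeom(universe, |reference|, |panel|).
    """
    panel, reference = set(panel), set(reference)
    if universe_size < len(panel) or universe_size < len(reference):
        raise ValueError("universe smaller than one of the gene sets")
    k = len(panel & reference)
    p = float(hypergeom.sf(k - 1, universe_size, len(reference), len(panel)))
    return k, min(p, 1.0)
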