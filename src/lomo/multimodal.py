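"""Cross-modality gene correlation and circos-style CV displays.

Given two pseudo-bulk tensors on shared genes (e.g., scRNA-seq expression
and scATAC-seq gene scores), the per-gene Pearson correlation is computed
over the matched (donor, timepoint, cell_type) entries present in both
tensors.  A shuffle null — correlating each gene's first-modality profile
with a *different* gene's second-modality profile, repeated over many random
gene permutations — yields the upper bound R0 below which an observed
correlation is no better than that of random, unrelated gene pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from lomo.datasets import PseudoBulkTensor

logger = logging.getLogger("lomo")


def _matched_matrices(pb_a: PseudoBulkTensor, pb_b: PseudoBulkTensor):
    genes = pb_a.values.index.intersection(pb_b.values.index)
    if len(genes) == 0:
        raise ValueError("no shared genes between modalities")
    cols = pb_a.values.columns.intersection(pb_b.values.columns)
    if len(cols) == 0:
        raise ValueError("no shared (donor, timepoint, cell_type) entries")
    A = pb_a.values.loc[genes, cols].to_numpy(dtype=float)
    B = pb_b.values.loc[genes, cols].to_numpy(dtype=float)
    return genes, cols, A, B


def _row_standardize(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows centered/scaled to unit SD; returns (standardized, valid mask)."""
    m = M.mean(axis=1, keepdims=True)
    sd = M.std(axis=1, ddof=1, keepdims=True)
    valid = sd.ravel() > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        Z = (M - m) / sd
    Z[~valid] = np.nan
    return Z, valid


@dataclass
class CrossModalityResult:
    """Per-gene cross-modality correlations with an optional null bound."""

    correlations: pd.DataFrame  # gene-indexed: r, n
    n_entries: int
    r0: float | None = None
    n_shuffles: int | None = None
    quantile: float | None = None
    seed: int | None = None

    def flag_not_better_than_random(self) -> pd.Series:
        if self.r0 is None:
            raise ValueError("null bound not computed")
        return self.correlations["r"] < self.r0


def cross_modality_correlation(
    pb_a: PseudoBulkTensor, pb_b: PseudoBulkTensor, min_entries: int = 3
) -> CrossModalityResult:
    """Per-gene Pearson correlation across matched pseudo-bulk entries.

    Only (donor, timepoint, cell_type) entries present in both tensors are
    used; genes with fewer than ``min_entries`` matched entries, or with zero
    variance in either modality, are excluded.
    """
    genes, cols, A, B = _matched_matrices(pb_a, pb_b)
    m = len(cols)
    Za, va = _row_standardize(A)
    Zb, vb = _row_standardize(B)
    valid = va & vb & (m >= min_entries)
    with np.errstate(invalid="ignore"):
        r = np.einsum("ij,ij->i", Za, Zb) / (m - 1)
    tab = pd.DataFrame({"r": r, "n": m}, index=genes)[valid]
    logger.info("cross-modality: %d/%d genes correlated over %d matched entries",
                len(tab), len(genes), m)
    return CrossModalityResult(correlations=tab, n_entries=m)


def random_pair_null(
    pb_a: PseudoBulkTensor,
    pb_b: PseudoBulkTensor,
    n_shuffles: int = 1000,
    quantile: float = 0.95,
    seed: int = 0,
    min_entries: int = 3,
) -> CrossModalityResult:
    """Cross-modality correlations plus the shuffle-null upper bound R0.

    Gene order in modality B is randomly permuted ``n_shuffles`` times; the
    correlations of all mismatched pairs (self-pairs skipped) are pooled and
    R0 is the pooled distribution's upper ``quantile``.  Deterministic under
    a fixed seed.
    """
    res = cross_modality_correlation(pb_a, pb_b, min_entries=min_entries)
    genes, cols, A, B = _matched_matrices(pb_a, pb_b)
    m = len(cols)
    Za, va = _row_standardize(A)
    Zb, vb = _row_standardize(B)
    valid = np.flatnonzero(va & vb)
    Za, Zb = Za[valid], Zb[valid]
    g = len(valid)
    if g < 2:
        raise ValueError("need >= 2 valid genes for the shuffle null")
    rng = np.random.default_rng(seed)
    pool = []
    for _ in range(n_shuffles):
        perm = rng.permutation(g)
        keep = perm != np.arange(g)  # drop self-pairs
        r = np.einsum("ij,ij->i", Za[keep], Zb[perm[keep]]) / (m - 1)
        pool.append(r)
    null = np.concatenate(pool)
    r0 = float(np.quantile(null, quantile))
    logger.info("shuffle null: R0 = %.4f at quantile %.2f (%d pooled correlations)",
                r0, quantile, len(null))
    res.r0, res.n_shuffles, res.quantile, res.seed = r0, n_shuffles, quantile, seed
    return res


def circos_cv_plot(
    cv_tables: list[pd.DataFrame],
    genes: list[str],
    output: str,
    cell_types: list[str] | None = None,
    donors: list[str] | None = None,
    cv_max: float = 50.0,
    modality_names: tuple[str, ...] = ("modality A", "modality B"),
) -> str:
    """Polar CV heatmap for up to two modalities.

    Angular sectors are (gene, cell type) pairs; radial rings are
    (modality, donor) with the first modality outermost.  Entries absent
    from a CV table (masked combinations) render grey.  Raises if a
    requested gene is absent from every table.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib import cm, colors

    if not 1 <= len(cv_tables) <= 2:
        raise ValueError("provide 1 or 2 CV tables")
    missing = [
        g for g in genes if all(g not in set(t["gene"]) for t in cv_tables)
    ]
    if missing:
        raise ValueError(f"genes absent from all CV tables: {missing}")
    if cell_types is None:
        cell_types = sorted({ct for t in cv_tables for ct in t["cell_type"].unique()})
    if donors is None:
        donors = sorted({d for t in cv_tables for d in t["donor"].unique()})

    lookups = []
    for t in cv_tables:
        d = {
            (r.gene, r.donor, r.cell_type): r.cv
            for r in t.itertuples()
            if r.defined and np.isfinite(r.cv)
        }
        lookups.append(d)

    n_sect = len(genes) * len(cell_types)
    rings = [(mi, d) for mi, _ in enumerate(cv_tables) for d in donors]
    norm = colors.Normalize(vmin=0.0, vmax=cv_max)
    cmap = plt.get_cmap("viridis")
    grey = (0.75, 0.75, 0.75, 1.0)

    fig = plt.figure(figsize=(8, 8))
    ax = fig.add_subplot(projection="polar")
    width = 2 * np.pi / n_sect
    r_outer, ring_h = 1.0, 0.08
    for ri, (mi, donor) in enumerate(rings):
        r0 = r_outer - ri * ring_h
        for si, (gene, ct) in enumerate(
            (g, c) for g in genes for c in cell_types
        ):
            val = lookups[mi].get((gene, donor, ct))
            color = grey if val is None else cmap(norm(min(val, cv_max)))
            ax.bar(
                si * width, ring_h, width=width, bottom=r0 - ring_h,
                color=color, edgecolor="white", linewidth=0.3, align="edge",
            )
    for gi, gene in enumerate(genes):
        ang = (gi + 0.5) * len(cell_types) * width
        ax.text(ang, r_outer + 0.06, gene, ha="center", va="center", fontsize=9)
    ax.set_ylim(0, r_outer + 0.12)
    ax.set_xticks([])
    ax.set_yticks([])
    ax.spines["polar"].set_visible(False)
    sm = cm.ScalarMappable(norm=norm, cmap=cmap)
    cbar = fig.colorbar(sm, ax=ax, shrink=0.6, pad=0.1)
    cbar.set_label("CV (%)")
    title = modality_names[0] if len(cv_tables) == 1 else " / ".join(
        modality_names[: len(cv_tables)]
    )
    ax.set_title(f"CV across timepoints — {title}")
    fig.savefig(output, dpi=150, metadata={"Software": "lomo"})
    plt.close(fig)
    logger.info("circos CV plot written to %s", output)
    return output
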