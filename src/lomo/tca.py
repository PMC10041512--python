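"""Hurdle-model time-course analysis of longitudinal single-cell expression.

Data are analyzed one participant and one cell type at a time.  Each gene's
normalized expression is modelled in two parts: a logistic regression of the
detection indicator (expression > 0) on time plus covariates, and a Gaussian
regression of expression on time plus covariates over expressing cells only.
With at least three timepoints, time enters as a continuous covariate and
the reported slope is the continuous-part time coefficient (expression change
per unit time).  Inference drops the time term from both parts and sums the
two likelihood-ratio statistics; p comes from the chi-square upper tail with
2 degrees of freedom (fewer when a part is degenerate).  With exactly two
timepoints the same machinery runs with a two-group contrast and the
coefficient is the between-timepoint difference.  Per (cell type, donor)
family, p-values are Benjamini-Hochberg adjusted; the default significance
call is adjusted p < 0.05 and |slope| > 0.1.

The standardized per-cell detection rate (fraction of genes detected) is
included as a technical covariate by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from lomo.datasets import CELLTYPE, DONOR, TIME, SingleCellDataset

logger = logging.getLogger("lomo")

#: ridge penalty on standardized logistic coefficients; keeps quasi-separated
#: fits finite without materially changing the likelihood ratio
LOGIT_RIDGE = 1e-6


def _logistic_pll(X: np.ndarray, y: np.ndarray, ridge: float = LOGIT_RIDGE) -> float:
    """Maximized (ridge-penalized) Bernoulli log-likelihood."""

    def nll(b):
        eta = X @ b
        val = float(np.sum(np.logaddexp(0.0, eta) - y * eta)) + 0.5 * ridge * float(b @ b)
        grad = X.T @ (expit(eta) - y) + ridge * b
        return val, grad

    res = minimize(
        nll, np.zeros(X.shape[1]), jac=True, method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10},
    )
    return -float(res.fun), res.x


def _standardize(cols: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Intercept + standardized columns; returns (design, scale per column)."""
    n = len(cols[0])
    out = [np.ones(n)]
    scales = []
    for c in cols:
        sd = c.std()
        if sd > 0:
            out.append((c - c.mean()) / sd)
            scales.append(sd)
        else:
            scales.append(0.0)  # constant column carries no information
    return np.column_stack(out), np.array(scales)


@dataclass
class HurdleFit:
    """Two-part hurdle fit for one gene."""

    gene: str
    slope: float  # continuous-part time coefficient, per unit time
    disc_coef: float  # discrete-part time coefficient (logit scale, per unit time)
    lrt: float
    df: int
    p: float
    frac_expressed: float
    n_cells: int
    flags: tuple[str, ...] = ()


def fit_hurdle(
    expr: np.ndarray,
    time: np.ndarray,
    covariates: pd.DataFrame | None = None,
    gene: str = "",
) -> HurdleFit:
    """Fit the two-part hurdle model for one gene and test the time terms.

    ``expr`` is normalized expression per cell (0 = not detected); ``time``
    the numeric timepoint per cell; ``covariates`` optional numeric columns
    (e.g., the standardized detection rate).  The design is standardized
    internally, which makes the test invariant to affine recoding of time;
    coefficients are reported per original time unit.
    """
    expr = np.asarray(expr, dtype=float)
    time = np.asarray(time, dtype=float)
    n = len(expr)
    detected = (expr > 0).astype(float)
    frac = float(detected.mean())
    flags: list[str] = []

    cov_cols = []
    if covariates is not None:
        cov_cols = [covariates[c].to_numpy(dtype=float) for c in covariates.columns]

    lrt = 0.0
    df = 0
    disc_coef = np.nan
    # --- discrete part: detection ~ time + covariates
    if 0.0 < frac < 1.0 and time.std() > 0:
        X_full, scales = _standardize([time, *cov_cols])
        X_red, _ = _standardize(cov_cols) if cov_cols else (np.ones((n, 1)), np.array([]))
        ll_full, b_full = _logistic_pll(X_full, detected)
        ll_red, _ = _logistic_pll(X_red, detected)
        stat = max(0.0, 2.0 * (ll_full - ll_red))
        lrt += stat
        df += 1
        disc_coef = float(b_full[1] / scales[0]) if scales[0] > 0 else np.nan
        if frac * n < 5 or (1 - frac) * n < 5:
            flags.append("few cells in one detection class")
    else:
        flags.append("constant detection; discrete part dropped")

    # --- continuous part: expression ~ time + covariates over expressing cells
    slope = np.nan
    pos = expr > 0
    y = expr[pos]
    t_pos = time[pos]
    if len(y) >= 2 and np.unique(t_pos).size >= 2 and y.std() > 0:
        cols_full = [t_pos] + [c[pos] for c in cov_cols]
        X_full = np.column_stack([np.ones(len(y)), *cols_full])
        X_red = np.column_stack([np.ones(len(y))] + [c[pos] for c in cov_cols])
        beta_full, rss_full = _ols(X_full, y)
        _, rss_red = _ols(X_red, y)
        if rss_full <= 0:
            flags.append("perfect continuous fit")
            rss_full = np.finfo(float).tiny
        stat = len(y) * np.log(max(rss_red, rss_full) / rss_full)
        lrt += max(0.0, stat)
        df += 1
        slope = float(beta_full[1])
    else:
        flags.append("continuous part degenerate")

    p = float(chi2.sf(lrt, df)) if df > 0 else 1.0
    return HurdleFit(
        gene=gene, slope=slope, disc_coef=disc_coef, lrt=float(lrt), df=df,
        p=min(max(p, np.finfo(float).tiny), 1.0), frac_expressed=frac,
        n_cells=n, flags=tuple(flags),
    )


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def cellular_detection_rate(matrix, standardize: bool = True) -> np.ndarray:
    """Per-cell fraction of genes detected, optionally standardized."""
    if sp.issparse(matrix):
        det = np.asarray((matrix > 0).sum(axis=1)).ravel() / matrix.shape[1]
    else:
        det = (np.asarray(matrix) > 0).mean(axis=1)
    if standardize:
        sd = det.std()
        det = (det - det.mean()) / sd if sd > 0 else det - det.mean()
    return det


def time_course_deg(
    sc: SingleCellDataset,
    donor: str,
    mincellsexpressed: float = 0.1,
    adjfac: tuple[str, ...] = (),
    use_cdr: bool = True,
    alpha: float = 0.05,
    slope_cutoff: float = 0.1,
) -> pd.DataFrame:
    """Per-gene time-course tests for one donor, split by cell type.

    Genes detected in fewer than ``mincellsexpressed`` of the subset's cells
    are removed before fitting.  Cell types with >= 3 distinct timepoints use
    continuous time (mode ``"slope"``); exactly 2 use a two-group contrast
    (mode ``"contrast"``, coefficient = between-timepoint difference); < 2
    are skipped with a warning.  BH adjustment runs within each (cell type,
    donor) family.  ``adjfac`` names additional per-cell covariate columns in
    ``sc.cell_meta`` to adjust for.
    """
    meta = sc.cell_meta
    in_donor = (meta[DONOR] == donor).to_numpy()
    if not in_donor.any():
        raise ValueError(f"donor {donor!r} not present")
    if meta.loc[in_donor, TIME].nunique() < 2:
        raise ValueError(f"donor {donor!r} has < 2 timepoints")
    dense = sc.dense()
    results = []
    for ct in sorted(meta.loc[in_donor, CELLTYPE].unique()):
        mask = in_donor & (meta[CELLTYPE] == ct).to_numpy()
        sub_meta = meta.loc[mask]
        n_tp = sub_meta[TIME].nunique()
        if n_tp < 2:
            logger.warning("cell type %s: < 2 timepoints for donor %s; skipped", ct, donor)
            continue
        mode = "slope" if n_tp >= 3 else "contrast"
        X = dense[mask]
        time = sub_meta[TIME].to_numpy(dtype=float)
        if mode == "contrast":
            time = (time == np.max(time)).astype(float)
        cov = {}
        if use_cdr:
            cov["cdr"] = cellular_detection_rate(X)
        for c in adjfac:
            cov[c] = pd.to_numeric(sub_meta[c], errors="coerce").to_numpy()
        covariates = pd.DataFrame(cov, index=range(mask.sum())) if cov else None

        frac = (X > 0).mean(axis=0)
        keep = np.flatnonzero(frac >= mincellsexpressed)
        if keep.size == 0:
            logger.warning("cell type %s: no gene passes mincellsexpressed", ct)
            continue
        logger.info("TCA donor %s / %s: %d cells, %d genes, mode=%s",
                    donor, ct, int(mask.sum()), keep.size, mode)
        fits = [
            fit_hurdle(X[:, j], time, covariates, gene=str(sc.gene_ids[j]))
            for j in keep
        ]
        sub = pd.DataFrame(
            {
                "cell_type": ct,
                "donor": donor,
                "gene": [f.gene for f in fits],
                "mode": mode,
                "slope": [f.slope for f in fits],
                "disc_coef": [f.disc_coef for f in fits],
                "lrt": [f.lrt for f in fits],
                "df": [f.df for f in fits],
                "p": [f.p for f in fits],
                "frac_expressed": [f.frac_expressed for f in fits],
                "n_cells": [f.n_cells for f in fits],
            }
        )
        sub["p_adj"] = multipletests(sub["p"], method="fdr_bh")[1]
        results.append(sub)
    if not results:
        raise ValueError(f"no analyzable cell type for donor {donor!r}")
    res = pd.concat(results, ignore_index=True)
    res["significant"] = (res["p_adj"] < alpha) & (res["slope"].abs() > slope_cutoff)
    res["direction"] = np.where(
        res["slope"] > 0, "up", np.where(res["slope"] < 0, "down", "flat")
    )
    logger.info("TCA donor %s: %d significant gene calls", donor, int(res["significant"].sum()))
    return res


def volcano_table(res: pd.DataFrame, slope_cutoff: float = 0.1) -> pd.DataFrame:
    """Plot-ready long table: slope vs -log10 adjusted p, colored by call."""
    if res.empty:
        return pd.DataFrame(columns=["cell_type", "gene", "slope", "neg_log10_p_adj", "color"])
    out = res[["cell_type", "gene", "slope", "p_adj", "significant"]].copy()
    out["neg_log10_p_adj"] = -np.log10(out["p_adj"].clip(lower=np.finfo(float).tiny))
    out["color"] = "grey"
    out.loc[out["significant"] & (out["slope"] > slope_cutoff), "color"] = "red"
    out.loc[out["significant"] & (out["slope"] < -slope_cutoff), "color"] = "blue"
    return out.drop(columns=["p_adj"])
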