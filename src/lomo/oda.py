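"""Outlier-sample detection for longitudinal bulk data.

Each analyte is standardized within donor: z = (value - mean) / SD with the
mean and SD taken across all of that donor's timepoints (the evaluated point
included, SD on the n-1 denominator).  This "leave-in" z is bounded,
|z| <= (n - 1) / sqrt(n) for n timepoints.  At each (donor, timepoint) the
number of analytes with |z| > z0 is compared against the chance expectation
r = 2 * (1 - Phi(z0)) by an upper-tail binomial test; p-values are
Benjamini-Hochberg adjusted and timepoints with adjusted p < 0.05 are
flagged as abnormal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom, norm
from statsmodels.stats.multitest import multipletests

from lomo.datasets import DONOR, TIME, LongitudinalDataset

logger = logging.getLogger("lomo")


def sample_correlation(ds: LongitudinalDataset, method: str = "pearson") -> pd.DataFrame:
    """Sample x sample correlation across analytes, pairwise complete.

    Rows/columns are ordered by donor then timepoint so intra-donor blocks
    are contiguous in a heatmap.  Pairs sharing fewer than 3 non-missing
    analytes get a missing entry.
    """
    if ds.n_samples < 2:
        raise ValueError("need >= 2 samples")
    order = ds.annotation.sort_values([DONOR, TIME]).index
    corr = ds.matrix[order].corr(method=method, min_periods=3)
    np.fill_diagonal(corr.to_numpy(), 1.0)
    return corr


@dataclass
class ZScoreTable:
    """Long-format within-donor z-scores plus bookkeeping."""

    table: pd.DataFrame  # feature, donor, timepoint, sample_id, value, z
    n_timepoints: pd.Series  # per donor
    skipped_donors: tuple = ()


def zscores(ds: LongitudinalDataset, min_timepoints: int = 3) -> ZScoreTable:
    """Leave-in z-scores per (analyte, donor, timepoint).

    Donors with fewer than ``min_timepoints`` timepoints are skipped with a
    warning.  Analytes with zero within-donor SD (or missing values leaving
    < 2 points) get undefined z, excluded from downstream counting.
    """
    rows = []
    skipped = []
    n_tp = {}
    for donor, ann in ds.annotation.groupby(DONOR, sort=True):
        n = ann[TIME].nunique()
        if n < min_timepoints:
            logger.warning("donor %s has %d timepoints (< %d); skipped", donor, n, min_timepoints)
            skipped.append(donor)
            continue
        n_tp[donor] = n
        sub = ds.matrix[ann.index]
        vals = sub.to_numpy(dtype=float)
        m = np.nanmean(vals, axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            sd = np.nanstd(vals, axis=1, ddof=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (vals - m) / sd
        z[~np.isfinite(z)] = np.nan
        for j, samp in enumerate(ann.index):
            rows.append(
                pd.DataFrame(
                    {
                        "feature": sub.index,
                        "donor": donor,
                        "timepoint": ann.loc[samp, TIME],
                        "sample_id": samp,
                        "value": vals[:, j],
                        "z": z[:, j],
                    }
                )
            )
    if not rows:
        raise ValueError(f"no donor with >= {min_timepoints} timepoints")
    return ZScoreTable(
        table=pd.concat(rows, ignore_index=True),
        n_timepoints=pd.Series(n_tp, name="n_timepoints"),
        skipped_donors=tuple(skipped),
    )


def expected_outlier_rate(z0: float, sided: str = "two") -> float:
    """Chance probability that a standard-normal z exceeds the cutoff.

    two-sided: P(|z| > z0) = 2 * (1 - Phi(z0)); one-sided: 1 - Phi(z0).
    """
    if z0 < 0:
        raise ValueError("z0 must be >= 0")
    tail = float(norm.sf(z0))
    if sided == "two":
        return 2.0 * tail
    if sided == "one":
        return tail
    raise ValueError(f"sided must be 'one' or 'two', got {sided!r}")


def detect_outlier_samples(
    zt: ZScoreTable,
    z0: float = 2.5,
    sided: str = "two",
    alpha: float = 0.05,
    family: str = "all",
) -> pd.DataFrame:
    """Binomial test on per-timepoint outlier counts, BH-adjusted.

    For each (donor, timepoint), counts analytes with |z| > z0 (two-sided;
    one-sided counts the positive tail) among analytes with a defined z,
    and computes the upper-tail binomial p-value at success probability
    ``expected_outlier_rate(z0, sided)``.  ``family`` selects the BH family:
    ``"all"`` adjusts across every (donor, timepoint) pair in the run,
    ``"donor"`` within each donor separately.  Rows with adjusted p < alpha
    are flagged.
    """
    r = expected_outlier_rate(z0, sided)
    t = zt.table
    rows = []
    for (donor, tp), sub in t.groupby(["donor", "timepoint"], sort=True):
        zv = sub["z"].to_numpy()
        ok = np.isfinite(zv)
        n_eval = int(ok.sum())
        if n_eval == 0:
            logger.warning("donor %s t=%g: no analyte with defined z; skipped", donor, tp)
            continue
        n_pos = int((zv[ok] > z0).sum())
        n_neg = int((zv[ok] < -z0).sum())
        count = n_pos + n_neg if sided == "two" else n_pos
        p = float(binom.sf(count - 1, n_eval, r))
        rows.append(
            {
                "donor": donor,
                "timepoint": tp,
                "n_high": n_pos,
                "n_low": n_neg,
                "n_outlier": count,
                "n_evaluated": n_eval,
                "expected_rate": r,
                "p": min(p, 1.0),
            }
        )
    rep = pd.DataFrame(rows)
    if family == "all":
        rep["p_adj"] = multipletests(rep["p"], method="fdr_bh")[1]
    elif family == "donor":
        rep["p_adj"] = np.nan
        for donor, sub in rep.groupby("donor"):
            rep.loc[sub.index, "p_adj"] = multipletests(sub["p"], method="fdr_bh")[1]
    else:
        raise ValueError(f"family must be 'all' or 'donor', got {family!r}")
    rep["flagged"] = rep["p_adj"] < alpha
    n_flag = int(rep["flagged"].sum())
    if n_flag:
        logger.info("ODA flagged %d/%d (donor, timepoint) pairs", n_flag, len(rep))
    return rep
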