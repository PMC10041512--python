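"""Coefficient-of-variation profiling for bulk longitudinal data.

For each feature and donor, CV = 100 * SD / mean across that donor's
timepoints (SD with the n-1 denominator).  Features are called consistently
stable (CV < cvThreshold in at least donorThreshold donors) or consistently
variable (CV > cvThreshold likewise); everything else is unclassified.  The
per-feature median CV across donors supports choosing cvThreshold at the
mode of the CV distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from lomo.datasets import DONOR, TIME, LongitudinalDataset

logger = logging.getLogger("lomo")

STABLE, VARIABLE, UNCLASSIFIED = "stable", "variable", "unclassified"


def cv(values, eps: float = 1e-12) -> tuple[float, bool]:
    """Percent coefficient of variation of a vector, with a defined flag.

    Returns ``(100 * SD / mean, True)`` with SD on the n-1 denominator, or
    ``(nan, False)`` when fewer than 2 non-missing values remain or the mean
    magnitude is at or below ``eps`` (CV is meaningless around a zero mean).
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 2:
        return np.nan, False
    m = v.mean()
    if abs(m) <= eps:
        return np.nan, False
    return float(100.0 * v.std(ddof=1) / m), True


def cv_profile_bulk(ds: LongitudinalDataset) -> pd.DataFrame:
    """One CV record per (feature, donor) across that donor's timepoints.

    Donors with a single timepoint are skipped with a warning.  Returns a
    long DataFrame with columns feature, donor, mean, sd, cv, n_timepoints,
    defined.  The near-zero-mean guard scales with the data
    (eps = 1e-8 * max |value|).
    """
    eps = 1e-8 * float(np.nanmax(np.abs(ds.matrix.to_numpy()))) if ds.matrix.size else 0.0
    rows = []
    for donor, ann in ds.annotation.groupby(DONOR, sort=True):
        if ann[TIME].nunique() < 2:
            logger.warning("donor %s has a single timepoint; skipped in CV profile", donor)
            continue
        sub = ds.matrix[ann.index]
        for feat, vals in sub.iterrows():
            v = vals.to_numpy(dtype=float)
            v = v[np.isfinite(v)]
            c, defined = cv(v, eps=eps)
            rows.append(
                {
                    "feature": feat,
                    "donor": donor,
                    "mean": v.mean() if len(v) else np.nan,
                    "sd": v.std(ddof=1) if len(v) > 1 else np.nan,
                    "cv": c,
                    "n_timepoints": len(v),
                    "defined": defined,
                }
            )
    if not rows:
        raise ValueError("no donor with >= 2 timepoints")
    return pd.DataFrame(rows)


def cv_histogram(records: pd.DataFrame, bins: int = 50) -> pd.DataFrame:
    """Histogram of per-feature median CV (defined records only), for picking
    cvThreshold at the distribution mode."""
    med = records[records["defined"]].groupby("feature")["cv"].median()
    counts, edges = np.histogram(med.dropna(), bins=bins)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


@dataclass
class CvpResult:
    """Per-feature stability calls plus the thresholds that produced them."""

    table: pd.DataFrame  # feature-indexed: median_cv, n_stable, n_variable, n_defined, call
    cv_threshold: float
    donor_threshold: int


def classify_consistent_features(
    records: pd.DataFrame,
    cv_threshold: float = 5.0,
    donor_threshold: int | None = None,
) -> CvpResult:
    """Call features consistently stable / variable across donors.

    A feature is stable iff CV < ``cv_threshold`` in at least
    ``donor_threshold`` donors, variable iff CV > ``cv_threshold`` likewise
    (strict inequalities; a CV exactly at the threshold supports neither
    call).  ``donor_threshold`` defaults to the number of donors in
    ``records``.  Undefined CVs are excluded from counts and medians;
    features with fewer than ``donor_threshold`` defined CVs stay
    unclassified.
    """
    n_donors = records["donor"].nunique()
    if donor_threshold is None:
        donor_threshold = n_donors
    if donor_threshold > n_donors:
        raise ValueError(f"donor_threshold {donor_threshold} exceeds {n_donors} donors")
    rec = records[records["defined"]]
    g = rec.groupby("feature")["cv"]
    tab = pd.DataFrame(
        {
            "median_cv": g.median(),
            "n_stable": g.apply(lambda s: int((s < cv_threshold).sum())),
            "n_variable": g.apply(lambda s: int((s > cv_threshold).sum())),
            "n_defined": g.size(),
        }
    )
    # features with no defined CV at all still get a row
    all_feats = pd.Index(records["feature"].unique(), name="feature")
    tab = tab.reindex(all_feats)
    tab[["n_stable", "n_variable", "n_defined"]] = (
        tab[["n_stable", "n_variable", "n_defined"]].fillna(0).astype(int)
    )
    is_stable = (tab["n_stable"] >= donor_threshold).to_numpy()
    is_variable = (tab["n_variable"] >= donor_threshold).to_numpy()
    call = np.full(len(tab), UNCLASSIFIED, dtype=object)
    # both calls can qualify only at permissive donor thresholds; treat as
    # ambiguous rather than picking a side
    call[is_stable & ~is_variable] = STABLE
    call[is_variable & ~is_stable] = VARIABLE
    tab["call"] = call
    logger.info(
        "CVP: %d stable, %d variable, %d unclassified (cvThreshold %.3g, donorThreshold %d)",
        (tab["call"] == STABLE).sum(), (tab["call"] == VARIABLE).sum(),
        (tab["call"] == UNCLASSIFIED).sum(), cv_threshold, donor_threshold,
    )
    return CvpResult(table=tab.sort_index(), cv_threshold=cv_threshold,
                     donor_threshold=donor_threshold)
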