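"""Group inference on regional SDI maps.

Per-region covariate-adjusted group comparison (OLS t on the group
coefficient, reducing exactly to the pooled two-sample t when no
covariates are supplied), Bonferroni masking over regions, symptom
severity correlations under the 1/N threshold, and the degree-SDI
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TMap",
    "group_glm_tmap",
    "bonferroni_mask",
    "severity_correlation",
    "degree_sdi_correlation",
]


@dataclass
class TMap:
    """Per-region group-difference statistics.

    Positive t means patient > control.
    """

    t: np.ndarray
    p: np.ndarray
    df: int
    covariates: tuple[str, ...] = ()

    @property
    def n_regions(self) -> int:
        return len(self.t)


def _design_matrix(covars: pd.DataFrame, covariates: tuple[str, ...]) -> np.ndarray:
    cols = [np.ones(len(covars)), covars["group"].to_numpy(dtype=float)]
    for c in covariates:
        cols.append(covars[c].to_numpy(dtype=float))
    return np.column_stack(cols)


def group_glm_tmap(
    sdi_by_subject: np.ndarray,
    covars: pd.DataFrame,
    covariates: tuple[str, ...] = ("gender", "mean_fd"),
) -> TMap:
    """Per-region t statistic for the group effect, adjusted for covariates.

    Fits ``sdi ~ 1 + group + covariates`` by OLS in every region
    (vectorized across regions; the design matrix is shared) and returns
    the t statistic and two-sided p of the group coefficient with
    ``df = n_subjects - n_parameters``.  With ``covariates=()`` this is
    exactly the classical pooled-variance two-sample t test.

    Parameters
    ----------
    sdi_by_subject : (n_subjects, n_regions) ndarray
    covars : DataFrame
        Must contain a binary ``group`` column (patient=1) and every
        requested covariate column.
    """
    Y = np.asarray(sdi_by_subject, dtype=float)
    if Y.ndim != 2 or len(covars) != Y.shape[0]:
        raise ValueError("sdi_by_subject must be subjects x regions matching the covariate table")
    X = _design_matrix(covars, covariates)
    n, p = X.shape
    if n < p + 4:
        raise ValueError(f"need at least {p + 4} subjects for a {p}-parameter model, got {n}")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        names = ("intercept", "group", *covariates)
        # identify a collinear column by rank drop on removal
        for j in range(p):
            reduced = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                raise ValueError(f"design matrix is rank deficient; column '{names[j]}' is collinear")
        raise ValueError("design matrix is rank deficient")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y  # (p, regions)
    resid = Y - X @ beta
    df = n - p
    sigma2 = (resid**2).sum(axis=0) / df
    se_group = np.sqrt(sigma2 * XtX_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[1] / se_group
    pvals = 2 * sps.t.sf(np.abs(t), df)
    return TMap(t=t, p=pvals, df=df, covariates=covariates)


def bonferroni_mask(tmap: TMap, alpha: float = 0.05) -> dict:
    """Bonferroni-corrected significance mask and direction split.

    A region is significant iff ``p < alpha / n_regions``; the mask is
    split into patient>control (t > 0) and patient<control (t < 0) sets.
    Returns a dict with ``mask``, ``higher``, ``lower`` boolean arrays and
    the per-region ``threshold``.
    """
    p = np.asarray(tmap.p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    thr = alpha / tmap.n_regions
    mask = p < thr
    return {
        "mask": mask,
        "higher": mask & (tmap.t > 0),
        "lower": mask & (tmap.t < 0),
        "threshold": thr,
    }


def severity_correlation(
    sdi_by_subject: np.ndarray,
    covars: pd.DataFrame,
    regions: np.ndarray,
) -> pd.DataFrame:
    """Pearson correlation of severity with SDI in selected regions, patients only.

    Significance uses the 1/N rule: a region is flagged iff its two-sided
    p is below ``1 / len(regions)`` -- the reciprocal of the number of
    correlations, bounding the expected false positives per battery at one.

    Parameters
    ----------
    regions : int array
        Zero-based region indices (e.g. the Bonferroni-significant set).
    """
    regions = np.asarray(regions, dtype=int)
    if regions.size == 0:
        raise ValueError("regions must be non-empty")
    Y = np.asarray(sdi_by_subject, dtype=float)
    pat = covars["group"].to_numpy() == 1
    sev = covars.loc[pat, "severity"].to_numpy(dtype=float)
    ok = np.isfinite(sev)
    sev = sev[ok]
    if len(sev) < 3:
        raise ValueError(f"need at least 3 patients with severity scores, got {len(sev)}")
    sub = Y[pat][ok][:, regions]
    rows = []
    p_max = 1.0 / len(regions)
    for j, r in enumerate(regions):
        res = sps.pearsonr(sev, sub[:, j])
        rows.append(
            {
                "region": int(r),
                "r": res.statistic,
                "p": res.pvalue,
                "significant": res.pvalue < p_max,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["p_max"] = p_max
    return out


def degree_sdi_correlation(degree: np.ndarray, mean_sdi: np.ndarray) -> tuple[float, float]:
    """Pearson correlation across regions between nodal degree and mean SDI."""
    degree = np.asarray(degree, dtype=float)
    mean_sdi = np.asarray(mean_sdi, dtype=float)
    if degree.shape != mean_sdi.shape or degree.size < 3:
        raise ValueError("degree and mean_sdi must have equal length >= 3")
    if degree.std() == 0 or mean_sdi.std() == 0:
        raise ValueError("zero variance in degree or SDI vector; correlation undefined")
    res = sps.pearsonr(degree, mean_sdi)
    return float(res.statistic), float(res.pvalue)
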