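"""Covariate screening and trait correlation.

Candidate confounders (BMI, age, cold ischemic time, ICU days, islet purity)
are screened one at a time: for each protein the R^2 of a single-covariate
least-squares fit is computed, and a covariate is selected when its *median*
R^2 across proteins reaches the threshold (default 1%) in at least one
tissue. Trait correlations (HbA1c, GSIS, BMI) are Spearman on pairwise-
complete cases; partial correlations residualize ranks on the covariates
before correlating, allowing a with/without-BMI comparison of trait
associations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import IntensityMatrix
from .differential import fdr_adjust

__all__ = [
    "ExplainedVariance",
    "explained_variance",
    "select_covariates",
    "correlate_to_trait",
    "partial_correlation",
    "compare_r_to_teststat",
]

logger = logging.getLogger(__name__)

#: covariates only defined for one tissue (islet preparation purity)
TISSUE_RESTRICTED = {"purity": "islets"}


@dataclass
class ExplainedVariance:
    """Per-protein R^2 of one covariate in one tissue."""

    tissue: str
    covariate: str
    r2: pd.Series
    median_r2: float = field(init=False)

    def __post_init__(self) -> None:
        self.median_r2 = float(self.r2.median())


def _r2_continuous(Y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of each row of Y with x (single-regressor
    OLS identity)."""
    xc = x - x.mean()
    ssx = float(xc @ xc)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    ssy = np.einsum("ij,ij->i", Yc, Yc)
    cov = Yc @ xc
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = cov**2 / (ssy * ssx)
    return np.where(ssy > 0, r2, 0.0)


def _r2_categorical(Y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """R^2 of the group-means model: between-group SS over total SS."""
    levels = pd.unique(x)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sst = np.einsum("ij,ij->i", Yc, Yc)
    ssb = np.zeros(Y.shape[0])
    grand = Y.mean(axis=1)
    for lev in levels:
        sel = x == lev
        ssb += sel.sum() * (Y[:, sel].mean(axis=1) - grand) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = ssb / sst
    return np.where(sst > 0, r2, 0.0)


def explained_variance(
    m: IntensityMatrix, covariate: pd.Series, name: str = ""
) -> ExplainedVariance:
    """Per-protein R^2 of a single covariate plus the across-protein median.

    Continuous covariates use the least-squares line (R^2 = squared Pearson
    r); categorical covariates use the group-means model. Samples with a
    missing covariate value are dropped.
    """
    name = name or str(covariate.name)
    cov = covariate.loc[[s for s in m.sample_ids if s in covariate.index]].dropna()
    if cov.nunique() < 2:
        raise ValueError(f"covariate {name!r} is constant; R^2 undefined")
    Y = m.values.loc[:, cov.index].to_numpy()
    if np.isnan(Y).any():
        raise ValueError("explained variance expects a complete (imputed) matrix")
    if pd.api.types.is_numeric_dtype(cov):
        r2 = _r2_continuous(Y, cov.to_numpy(dtype=float))
    else:
        r2 = _r2_categorical(Y, cov.to_numpy())
    return ExplainedVariance(m.tissue, name, pd.Series(r2, index=m.protein_ids))


def select_covariates(
    reports: Sequence[ExplainedVariance], threshold: float = 0.01
) -> list[str]:
    """Covariates whose median R^2 >= threshold in at least one tissue.

    Tissue-restricted covariates (islet purity) are only eligible in their
    own tissue; reports from other tissues are ignored for them.
    """
    if not reports:
        raise ValueError("need at least one explained-variance report")
    selected: set[str] = set()
    for rep in reports:
        home = TISSUE_RESTRICTED.get(rep.covariate)
        if home is not None and rep.tissue != home:
            continue
        if rep.median_r2 >= threshold:
            selected.add(rep.covariate)
    order = list(dict.fromkeys(r.covariate for r in reports))
    return [c for c in order if c in selected]


def correlate_to_trait(
    m: IntensityMatrix,
    trait: pd.Series,
    method: str = "spearman",
    min_pairs: int = 5,
    fdr_method: str = "bh",
) -> pd.DataFrame:
    """Per-protein correlation to a clinical trait on pairwise-complete cases.

    Returns r, two-sided p and FDR-adjusted q per protein; proteins with
    fewer than ``min_pairs`` complete pairs are reported as NA and logged.
    """
    trait = trait.loc[[s for s in m.sample_ids if s in trait.index]].dropna()
    if trait.nunique() < 2:
        raise ValueError("trait is constant")
    Y = m.values.loc[:, trait.index]
    r = np.full(m.n_proteins, np.nan)
    p = np.full(m.n_proteins, np.nan)
    tvals = trait.to_numpy(dtype=float)
    for i in range(m.n_proteins):
        y = Y.iloc[i].to_numpy(dtype=float)
        ok = ~np.isnan(y)
        if int(ok.sum()) < min_pairs:
            logger.warning(
                "protein %s: %d complete pairs (< %d); correlation set to NA",
                m.protein_ids[i], int(ok.sum()), min_pairs,
            )
            continue
        if method == "spearman":
            res = stats.spearmanr(y[ok], tvals[ok])
        elif method == "pearson":
            res = stats.pearsonr(y[ok], tvals[ok])
        else:
            raise ValueError(f"unknown correlation method {method!r}")
        r[i], p[i] = res.statistic, res.pvalue
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = fdr_adjust(p[ok], method=fdr_method)
    return pd.DataFrame({"r": r, "p": p, "q": q}, index=m.protein_ids)


def partial_correlation(
    m: IntensityMatrix,
    trait: pd.Series,
    covariates: pd.DataFrame,
    include_bmi: bool = True,
) -> pd.Series:
    """Rank-based partial correlation of each protein to a trait.

    Ranks are taken first (matching the Spearman choice of the marginal
    correlations), then the covariates are removed from both protein and
    trait by least squares, and the residuals are correlated. With an empty
    covariate set this reduces to the Spearman correlation.
    """
    cols = [c for c in covariates.columns if include_bmi or c != "BMI"]
    samples = [s for s in m.sample_ids if s in trait.index]
    trait = trait.loc[samples]
    Z = covariates.loc[samples, cols].to_numpy(dtype=float) if cols else None
    if Z is not None:
        X = np.column_stack([np.ones(len(samples)), Z])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            _, rmat = np.linalg.qr(X)
            dep = [(["intercept"] + cols)[i] for i in range(X.shape[1])
                   if abs(rmat[i, i]) < 1e-10]
            raise ValueError(f"collinear covariate columns: {dep}")
    Y = m.values.loc[:, samples]
    if Y.isna().any().any():
        raise ValueError("partial correlation expects a complete (imputed) matrix")
    t_rank = stats.rankdata(trait.to_numpy(dtype=float))
    out = np.empty(m.n_proteins)
    if Z is None:
        for i in range(m.n_proteins):
            y_rank = stats.rankdata(Y.iloc[i].to_numpy(dtype=float))
            out[i] = np.corrcoef(y_rank, t_rank)[0, 1]
        return pd.Series(out, index=m.protein_ids, name="partial_r")
    H = X @ np.linalg.solve(X.T @ X, X.T)
    resid_t = t_rank - H @ t_rank
    t_center = t_rank - t_rank.mean()
    if (resid_t @ resid_t) <= 1e-12 * (t_center @ t_center):
        # trait fully explained by the covariates: no residual association
        return pd.Series(0.0, index=m.protein_ids, name="partial_r")
    Yr = np.apply_along_axis(stats.rankdata, 1, Y.to_numpy(dtype=float))
    resid_Y = Yr - Yr @ H.T
    num = resid_Y @ resid_t
    den = np.sqrt(np.einsum("ij,ij->i", resid_Y, resid_Y) * (resid_t @ resid_t))
    # zero residual variation (fully explained) contributes no association
    out = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    return pd.Series(out, index=m.protein_ids, name="partial_r")


def compare_r_to_teststat(
    trait_r: pd.Series, differential: pd.DataFrame
) -> tuple[float, float]:
    """Rank correlation between trait-correlation r and logFC/SE.

    Checks the internal consistency of the two analyses: both statistics
    respond to the same underlying group/trait signal, so on real and
    planted-effect synthetic data they agree strongly.
    """
    shared = trait_r.index.intersection(differential.index)
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} shared proteins (< 10)")
    stat = (differential.loc[shared, "logFC"] / differential.loc[shared, "SE"])
    r = trait_r.loc[shared]
    ok = ~(r.isna() | stat.isna())
    res = stats.spearmanr(r[ok], stat[ok])
    return float(res.statistic), float(res.pvalue)
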