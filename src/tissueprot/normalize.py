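"""Median-sweeping normalization and QRILC left-censored imputation.

Median sweeping shifts each sample so that all sample medians coincide with
the cohort target (the median of the pre-normalization sample medians) —
appropriate for log-scale proteomics where loading differences act additively.

QRILC ("quantile regression imputation of left-censored data") treats each
sample's observed values as the upper quantiles of a latent normal whose
lower tail fell below the detection limit. With fraction ``f`` missing, the
i-th of m sorted observed values is assigned the plotting position

    p_i = f + (1 - f) * (i - 0.375) / (m + 0.25)        (Blom, shifted by f)

and an ordinary least-squares fit of the observed values against the standard
normal quantiles Phi^-1(p_i) yields the latent mean (intercept) and sd
(slope). Missing cells are drawn from Normal(mu, tune_sigma * sd) truncated
above at the latent f-quantile Q = mu + sd * Phi^-1(f), so imputations
represent the censored lower tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import IntensityMatrix

__all__ = ["ImputeParams", "median_sweep", "qrilc_impute", "halfmin_impute"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ImputeParams:
    """QRILC knobs.

    tune_sigma
        Multiplier on the estimated sd of the truncated draw; 1.0 uses the
        fitted spread unchanged.
    fit_quantile_range
        Probability window of plotting positions used in the quantile fit;
        ``None`` uses every observed position, which under left-censoring
        already spans only the upper range [f, 1).
    """

    tune_sigma: float = 1.0
    fit_quantile_range: tuple[float, float] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.tune_sigma <= 0:
            raise ValueError("tune_sigma must be > 0")
        if self.fit_quantile_range is not None:
            lo, hi = self.fit_quantile_range
            if not 0 < lo < hi < 1:
                raise ValueError("fit_quantile_range must satisfy 0 < lo < hi < 1")


def median_sweep(m: IntensityMatrix, target: float | None = None) -> IntensityMatrix:
    """Equalize sample medians; the default target is the median of the
    pre-normalization sample medians."""
    if m.scale != "log2":
        raise ValueError("median sweeping operates on the log2 scale")
    n_obs = m.mask.sum(axis=0)
    empty = n_obs.index[n_obs == 0].tolist()
    if empty:
        raise ValueError(f"samples with zero observed values: {empty}")
    medians = m.values.median(axis=0, skipna=True)
    if target is None:
        target = float(medians.median())
    swept = m.values + (target - medians)
    return IntensityMatrix(swept, tissue=m.tissue, scale=m.scale)


def fit_censored_normal(
    observed: np.ndarray,
    frac_missing: float,
    fit_quantile_range: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Estimate the latent (mu, sd) of a left-censored normal sample.

    Least-squares fit of sorted observed values against Phi^-1 of shifted
    Blom plotting positions; returns (intercept, slope).
    """
    x = np.sort(observed)
    m = x.size
    i = np.arange(1, m + 1)
    p = frac_missing + (1.0 - frac_missing) * (i - 0.375) / (m + 0.25)
    if fit_quantile_range is not None:
        lo, hi = fit_quantile_range
        sel = (p >= lo) & (p <= hi)
        if sel.sum() < 2:
            raise ValueError("fit_quantile_range leaves fewer than 2 positions")
        x, p = x[sel], p[sel]
    z = stats.norm.ppf(p)
    slope, intercept = np.polyfit(z, x, 1)
    return float(intercept), float(slope)


def qrilc_impute(m: IntensityMatrix, params: ImputeParams | None = None) -> IntensityMatrix:
    """Impute missing cells per sample from a fitted truncated normal.

    Observed cells are bit-identical before and after. Columns where the
    quantile fit degenerates (slope <= 0) fall back to half-minimum
    imputation with a logged warning.
    """
    params = params or ImputeParams()
    params.validate()
    rng = np.random.default_rng(params.seed)
    values = m.values.to_numpy(copy=True)
    n = values.shape[0]
    for j, sample in enumerate(m.sample_ids):
        col = values[:, j]
        miss = np.isnan(col)
        n_miss = int(miss.sum())
        if n_miss == 0:
            continue
        observed = col[~miss]
        if observed.size < 10:
            raise ValueError(
                f"sample {sample!r} has {observed.size} observed values; "
                "QRILC needs at least 10"
            )
        f = n_miss / n
        mu, sd = fit_censored_normal(observed, f, params.fit_quantile_range)
        if sd <= 0:
            logger.warning(
                "QRILC fit degenerate in sample %s (slope %.3g); "
                "falling back to half-minimum imputation", sample, sd
            )
            col[miss] = _halfmin_value(observed.min(), m.scale)
            continue
        upper = mu + sd * stats.norm.ppf(f)
        scale = params.tune_sigma * sd
        b = (upper - mu) / scale
        draws = stats.truncnorm.rvs(
            -np.inf, b, loc=mu, scale=scale, size=n_miss, random_state=rng
        )
        col[miss] = draws
    out = pd.DataFrame(values, index=m.values.index, columns=m.values.columns)
    return IntensityMatrix(out, tissue=m.tissue, scale=m.scale)


def _halfmin_value(observed_min: float, scale: str) -> float:
    # half the intensity: min/2 on the raw scale is min - 1 on log2
    return observed_min - 1.0 if scale == "log2" else observed_min / 2.0


def halfmin_impute(m: IntensityMatrix) -> IntensityMatrix:
    """Replace each sample's missing cells by half its observed minimum
    intensity (minimum minus one on the log2 scale)."""
    values = m.values.to_numpy(copy=True)
    for j in range(values.shape[1]):
        col = values[:, j]
        miss = np.isnan(col)
        if miss.any():
            if miss.all():
                raise ValueError(f"sample {m.sample_ids[j]!r} has no observed values")
            col[miss] = _halfmin_value(np.nanmin(col), m.scale)
    out = pd.DataFrame(values, index=m.values.index, columns=m.values.columns)
    return IntensityMatrix(out, tissue=m.tissue, scale=m.scale)
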