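"""Covariate-adjusted per-protein linear models with empirical-Bayes variance
moderation, FDR control, and pi-value ranking.

Per protein g the model is ordinary least squares on the (imputed, complete)
log2 abundances with design columns [intercept, group indicator, covariates].
Residual variances s2_g on d_g degrees of freedom are shrunk toward a prior
via the conjugate scaled-inverse-chi-square hierarchy: with prior degrees of
freedom d0 and prior variance s0^2, the posterior variance is

    s~2_g = (d0 * s0^2 + d_g * s2_g) / (d0 + d_g)

and the moderated t-statistic t_g = beta_g / (s~_g * sqrt(v_g)) is referred to
a t distribution on d0 + d_g df. The hyperparameters (d0, s0^2) are estimated
by method of moments on e_g = log s2_g using digamma/trigamma identities of
the log chi-square distribution (Smyth-style closed form): the excess
dispersion of e_g over trigamma(d_g/2) determines trigamma(d0/2); no excess
means d0 = infinity and complete shrinkage to s0^2.

Significance is ranked for enrichment by the signed pi-value

    pi_g = logFC_g * (-log10 q_g)

combining effect size with FDR-adjusted significance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .containers import IntensityMatrix

__all__ = [
    "Contrast",
    "DEFAULT_CONTRASTS",
    "ModeratedFit",
    "build_design",
    "fit_linear_models",
    "ebayes_moderate",
    "fdr_adjust",
    "pi_value",
    "run_differential",
]

GROUPS = ("CTRL", "PD", "T2D")


@dataclass(frozen=True)
class Contrast:
    """Group contrast B vs A; each side may merge several groups."""

    name: str
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.group_a or not self.group_b:
            raise ValueError(f"contrast {self.name!r}: both sides must be non-empty")
        if set(self.group_a) & set(self.group_b):
            raise ValueError(f"contrast {self.name!r}: sides overlap")


#: Pairwise comparisons among the three glycemic groups plus the two
#: merged-group comparisons (T2D vs CTRL+PD, PD+T2D vs CTRL).
DEFAULT_CONTRASTS: tuple[Contrast, ...] = (
    Contrast("PD-CTRL", ("CTRL",), ("PD",)),
    Contrast("T2D-CTRL", ("CTRL",), ("T2D",)),
    Contrast("T2D-PD", ("PD",), ("T2D",)),
    Contrast("T2D-(CTRL+PD)", ("CTRL", "PD"), ("T2D",)),
    Contrast("(PD+T2D)-CTRL", ("CTRL",), ("PD", "T2D")),
)


def build_design(
    meta: pd.DataFrame,
    contrast: Contrast,
    covariates: Sequence[str] = (),
) -> tuple[pd.DataFrame, np.ndarray]:
    """Design matrix and contrast vector for one comparison.

    Rows cover only the samples in the contrast's groups. Columns: intercept,
    a B-vs-A group indicator, one centered column per continuous covariate,
    and dummy columns (first level dropped) per categorical covariate.
    Returns ``(design, cvec)`` with ``cvec`` selecting the group column.
    """
    groups = set(contrast.group_a) | set(contrast.group_b)
    sub = meta[meta["group"].isin(groups)].copy()
    for side, members in (("A", contrast.group_a), ("B", contrast.group_b)):
        n = int(sub["group"].isin(members).sum())
        if n < 2:
            raise ValueError(
                f"contrast {contrast.name!r}: side {side} has {n} samples (< 2)"
            )
    design = pd.DataFrame(index=sub["sample_id"])
    design["intercept"] = 1.0
    design["group"] = sub["group"].isin(contrast.group_b).astype(float).to_numpy()
    for cov in covariates:
        if cov not in sub.columns:
            raise ValueError(f"covariate {cov!r} missing from metadata")
        col = sub[cov]
        if pd.api.types.is_numeric_dtype(col):
            x = col.to_numpy(dtype=float)
            if np.isnan(x).any():
                raise ValueError(f"covariate {cov!r} has missing values")
            design[cov] = x - x.mean()
        else:
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            for c in dummies.columns:
                design[c] = dummies[c].to_numpy()
    X = design.to_numpy()
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns involved in the deficiency
        _, r = np.linalg.qr(X)
        dep = [design.columns[i] for i in range(X.shape[1]) if abs(r[i, i]) < 1e-10]
        raise ValueError(f"design matrix is rank deficient; suspect columns: {dep}")
    cvec = np.zeros(X.shape[1])
    cvec[design.columns.get_loc("group")] = 1.0
    return design, cvec


@dataclass
class ModeratedFit:
    """Per-protein fit plus empirical-Bayes globals."""

    protein_ids: pd.Index
    coef: np.ndarray          # contrast estimate (logFC, log2 units)
    s2: np.ndarray            # residual variance
    df_residual: np.ndarray   # d_g
    v: np.ndarray             # unscaled variance factor c'(X'X)^-1 c
    df_prior: float = np.nan
    s2_prior: float = np.nan
    s2_post: np.ndarray = field(default_factory=lambda: np.empty(0))
    t: np.ndarray = field(default_factory=lambda: np.empty(0))
    p: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def se(self) -> np.ndarray:
        """Moderated standard error of the contrast estimate."""
        return np.sqrt(self.s2_post * self.v)


def fit_linear_models(
    m: IntensityMatrix, design: pd.DataFrame, cvec: np.ndarray
) -> ModeratedFit:
    """OLS per protein on complete (post-imputation) data, vectorized.

    beta_g = c' (X'X)^-1 X' y_g, s2_g = RSS_g / (n - rank), shared variance
    factor v = c'(X'X)^-1 c.
    """
    samples = design.index
    missing = [s for s in samples if s not in m.sample_ids]
    if missing:
        raise ValueError(f"design samples absent from matrix: {missing[:5]}")
    Y = m.values.loc[:, samples].to_numpy()  # P x n
    if np.isnan(Y).any():
        raise ValueError("matrix contains missing values; impute before fitting")
    X = design.to_numpy()
    n, k = X.shape
    rank = np.linalg.matrix_rank(X)
    if n <= rank:
        raise ValueError(f"n = {n} <= rank(design) = {rank}; no residual df")
    xtx_inv = np.linalg.inv(X.T @ X)
    B = Y @ X @ xtx_inv.T                     # P x k coefficient matrix
    resid = Y - B @ X.T
    rss = np.einsum("ij,ij->i", resid, resid)
    d = n - rank
    s2 = rss / d
    coef = B @ cvec
    v = float(cvec @ xtx_inv @ cvec)
    return ModeratedFit(
        protein_ids=m.protein_ids,
        coef=coef,
        s2=s2,
        df_residual=np.full(len(coef), float(d)),
        v=np.full(len(coef), v),
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (trigamma is strictly decreasing)."""
    if y <= 0:
        raise ValueError("trigamma inverse needs y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    f = lambda x: float(special.polygamma(1, x)) - y
    return float(optimize.brentq(f, 1e-5, 1e7, xtol=1e-12, rtol=1e-14))


def ebayes_moderate(fit: ModeratedFit) -> ModeratedFit:
    """Estimate (d0, s0^2) and compute moderated t and p in place.

    Method of moments on e_g = log s2_g - digamma(d_g/2) + log(d_g/2):
    E[e] = log s0^2 - digamma(d0/2) + log(d0/2) and
    Var[e] = trigamma(d_g/2) + trigamma(d0/2). Excess variance <= 0 implies
    d0 = infinity (all proteins share s0^2). Proteins with s2 = 0 are
    excluded from estimation but still moderated.
    """
    s2, d = fit.s2, fit.df_residual
    ok = s2 > 0
    if int(ok.sum()) < 10:
        raise ValueError("need >= 10 proteins with positive residual variance")
    e = np.log(s2[ok]) - special.digamma(d[ok] / 2) + np.log(d[ok] / 2)
    emean = float(e.mean())
    evar = float(e.var(ddof=1))
    excess = evar - float(special.polygamma(1, d[ok] / 2).mean())
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_2 = float(np.exp(emean + special.digamma(d0 / 2) - np.log(d0 / 2)))
    else:
        d0 = np.inf
        s0_2 = float(np.exp(emean))
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.full_like(d, np.inf)
    else:
        s2_post = (d0 * s0_2 + d * s2) / (d0 + d)
        df_total = d0 + d
    with np.errstate(divide="ignore"):
        t = fit.coef / np.sqrt(s2_post * fit.v)
    p = np.where(
        np.isinf(df_total),
        2.0 * stats.norm.sf(np.abs(t)),
        2.0 * stats.t.sf(np.abs(t), df_total),
    )
    fit.df_prior = d0
    fit.s2_prior = s0_2
    fit.s2_post = s2_post
    fit.t = t
    fit.p = p
    return fit


def fdr_adjust(p: np.ndarray, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; ``method="storey"`` additionally
    scales by the pi0 estimate at the fixed lambda = 0.5."""
    p = np.asarray(p, dtype=float)
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = multipletests(p, method="fdr_bh")[1]
    if method == "bh":
        return q
    if method == "storey":
        lam = 0.5
        pi0 = min(1.0, float((p > lam).sum()) / (len(p) * (1.0 - lam)))
        return np.minimum(pi0 * q, 1.0)
    raise ValueError(f"unknown FDR method {method!r}")


def pi_value(logfc: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Signed ranking statistic pi = logFC * (-log10 q).

    q = 0 (numerically exhausted) is clamped to the smallest positive float
    with a warning; q = 1 gives pi = 0.
    """
    logfc = np.asarray(logfc, dtype=float)
    q = np.asarray(q, dtype=float)
    if (q < 0).any() or (q > 1).any():
        raise ValueError("q-values must lie in [0, 1]")
    if (q == 0).any():
        warnings.warn("q-value of 0 clamped to the smallest positive float")
        q = np.where(q == 0, np.finfo(float).tiny, q)
    return logfc * (-np.log10(q))


def run_differential(
    m: IntensityMatrix,
    meta: pd.DataFrame,
    contrast: Contrast,
    covariates: Sequence[str] = (),
    fdr_method: str = "bh",
) -> pd.DataFrame:
    """Full differential table for one tissue x contrast.

    Returns a DataFrame indexed by protein with columns logFC, SE, t, p, q,
    pi, sorted by the input protein order.
    """
    tissue_meta = meta[meta["sample_id"].isin(m.sample_ids)]
    design, cvec = build_design(tissue_meta, contrast, covariates)
    fit = fit_linear_models(m, design, cvec)
    fit = ebayes_moderate(fit)
    q = fdr_adjust(fit.p, method=fdr_method)
    pi = pi_value(fit.coef, q)
    return pd.DataFrame(
        {
            "logFC": fit.coef,
            "SE": fit.se,
            "t": fit.t,
            "p": fit.p,
            "q": q,
            "pi": pi,
        },
        index=fit.protein_ids,
    )
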