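"""Design construction, OLS fits, empirical-Bayes moderation, FDR, pi-values."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from tissueprot.containers import IntensityMatrix
from tissueprot.differential import (
    Contrast,
    ModeratedFit,
    build_design,
    ebayes_moderate,
    fdr_adjust,
    fit_linear_models,
    pi_value,
    run_differential,
)


def meta_for(groups, tissue="liver", **covariates):
    n = len(groups)
    meta = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "subject": [f"p{i}" for i in range(n)],
            "tissue": tissue,
            "group": groups,
        }
    )
    for name, vals in covariates.items():
        meta[name] = vals
    return meta


def matrix_for(values, sample_ids=None):
    arr = np.asarray(values, dtype=float)
    return IntensityMatrix(
        pd.DataFrame(
            arr,
            index=[f"P{i}" for i in range(arr.shape[0])],
            columns=sample_ids or [f"s{j}" for j in range(arr.shape[1])],
        ),
        tissue="liver",
    )


T2D_CTRL = Contrast("T2D-CTRL", ("CTRL",), ("T2D",))


class TestDesign:
    def test_two_group_shape(self):
        meta = meta_for(["CTRL"] * 3 + ["T2D"] * 3)
        design, cvec = build_design(meta, T2D_CTRL)
        assert design.shape == (6, 2)
        assert cvec.tolist() == [0.0, 1.0]
        assert design["group"].tolist() == [0, 0, 0, 1, 1, 1]

    def test_merged_groups_pooled(self):
        meta = meta_for(["CTRL", "CTRL", "PD", "PD", "T2D", "T2D"])
        merged = Contrast("T2D-(CTRL+PD)", ("CTRL", "PD"), ("T2D",))
        design, _ = build_design(meta, merged)
        assert design["group"].tolist() == [0, 0, 0, 0, 1, 1]

    def test_duplicate_covariate_rank_deficient(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        meta = meta_for(["CTRL"] * 3 + ["T2D"] * 3, a=x, b=x)
        with pytest.raises(ValueError, match="rank deficient"):
            build_design(meta, T2D_CTRL, covariates=["a", "b"])

    def test_small_group_rejected(self):
        meta = meta_for(["CTRL", "T2D", "T2D"])
        with pytest.raises(ValueError, match="< 2"):
            build_design(meta, T2D_CTRL)


class TestOls:
    def test_coef_is_mean_difference(self):
        meta = meta_for(["CTRL"] * 3 + ["T2D"] * 3)
        m = matrix_for([[1.0, 2.0, 3.0, 5.0, 6.0, 7.0]])
        design, cvec = build_design(meta, T2D_CTRL)
        fit = fit_linear_models(m, design, cvec)
        assert fit.coef[0] == pytest.approx(4.0)

    def test_exact_fit_zero_variance(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        meta = meta_for(["CTRL"] * 3 + ["T2D"] * 3, x=x)
        m = matrix_for([x])
        design, cvec = build_design(meta, T2D_CTRL, covariates=["x"])
        fit = fit_linear_models(m, design, cvec)
        assert fit.s2[0] == pytest.approx(0.0, abs=1e-20)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(40)
        n = 20
        meta = meta_for(["CTRL"] * 10 + ["T2D"] * 10,
                        x=rng.normal(size=n), z=rng.normal(size=n))
        Y = rng.normal(size=(30, n))
        m = matrix_for(Y)
        design, cvec = build_design(meta, T2D_CTRL, covariates=["x", "z"])
        fit = fit_linear_models(m, design, cvec)
        X = design.to_numpy()
        for g in range(30):
            beta = np.linalg.solve(X.T @ X, X.T @ Y[g])
            resid = Y[g] - X @ beta
            s2 = resid @ resid / (n - X.shape[1])
            assert abs(fit.coef[g] - cvec @ beta) < 1e-10
            assert abs(fit.s2[g] - s2) < 1e-10

    def test_orthogonal_covariate_leaves_coef_unchanged(self):
        rng = np.random.default_rng(41)
        n = 12
        group = np.array([0.0] * 6 + [1.0] * 6)
        # covariate orthogonal to intercept and group indicator
        w = rng.normal(size=n)
        for basis in (np.ones(n), group - group.mean()):
            w -= (w @ basis) / (basis @ basis) * basis
        meta = meta_for(["CTRL"] * 6 + ["T2D"] * 6, w=w)
        m = matrix_for(rng.normal(size=(15, n)))
        d0, c0 = build_design(meta, T2D_CTRL)
        d1, c1 = build_design(meta, T2D_CTRL, covariates=["w"])
        f0 = fit_linear_models(m, d0, c0)
        f1 = fit_linear_models(m, d1, c1)
        assert np.allclose(f0.coef, f1.coef, atol=1e-10)


def make_fit(coef, s2, d, v=0.25):
    n = len(coef)
    return ModeratedFit(
        protein_ids=pd.Index([f"P{i}" for i in range(n)]),
        coef=np.asarray(coef, dtype=float),
        s2=np.asarray(s2, dtype=float),
        df_residual=np.full(n, float(d)),
        v=np.full(n, v),
    )


class TestEbayes:
    def test_equal_variances_give_infinite_prior_df(self):
        fit = make_fit(np.zeros(50), np.full(50, 2.0), d=10)
        out = ebayes_moderate(fit)
        assert np.isinf(out.df_prior)
        # complete shrinkage: one shared posterior variance
        assert np.allclose(out.s2_post, out.s2_post[0])

    def test_hyperparameter_recovery(self):
        rng = np.random.default_rng(42)
        d0_true, s0_true, d = 8.0, 1.5, 6
        n = 5000
        true_var = s0_true * d0_true / rng.chisquare(d0_true, size=n)
        s2 = true_var * rng.chisquare(d, size=n) / d
        fit = make_fit(np.zeros(n), s2, d=d)
        out = ebayes_moderate(fit)
        assert abs(out.df_prior - d0_true) / d0_true < 0.20
        assert abs(out.s2_prior - s0_true) / s0_true < 0.10

    def test_moderated_p_matches_formula_oracle(self):
        rng = np.random.default_rng(43)
        n = 200
        s2 = rng.chisquare(5, size=n) / 5
        coef = rng.normal(size=n)
        fit = make_fit(coef, s2, d=5, v=0.3)
        out = ebayes_moderate(fit)
        # independent implementation of the closed-form moderation
        d0, s0 = out.df_prior, out.s2_prior
        post = (d0 * s0 + 5 * s2) / (d0 + 5)
        t = coef / np.sqrt(post * 0.3)
        p = 2 * stats.t.sf(np.abs(t), d0 + 5)
        assert np.allclose(out.t, t, atol=1e-8)
        assert np.allclose(out.p, p, atol=1e-8)

    def test_moment_identities_hold(self):
        # the estimated prior reproduces the observed mean/variance of log s2
        rng = np.random.default_rng(44)
        s2 = rng.chisquare(4, size=3000) / 4 * (2.0 * 10 / rng.chisquare(10, 3000))
        fit = make_fit(np.zeros(3000), s2, d=4)
        out = ebayes_moderate(fit)
        e = np.log(s2) - special.digamma(2.0) + np.log(2.0)
        lhs = float(np.var(e, ddof=1)) - float(special.polygamma(1, 2.0))
        assert special.polygamma(1, out.df_prior / 2) == pytest.approx(lhs, rel=1e-6)

    def test_all_zero_variance_rejected(self):
        fit = make_fit(np.ones(20), np.zeros(20), d=4)
        with pytest.raises(ValueError):
            ebayes_moderate(fit)


class TestFdr:
    def test_hand_evaluated_step_up(self):
        q = fdr_adjust(np.array([0.01, 0.02, 0.03]))
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert fdr_adjust(np.ones(5)).tolist() == [1.0] * 5

    def test_matches_stepup_oracle_on_random_p(self):
        rng = np.random.default_rng(45)
        p = rng.uniform(size=200)
        q = fdr_adjust(p)
        # hand-rolled BH step-up
        order = np.argsort(p)
        m = len(p)
        adj = p[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        oracle = np.empty(m)
        oracle[order] = np.minimum(adj, 1.0)
        assert np.allclose(q, oracle, atol=1e-12)

    def test_monotone_in_sorted_p(self):
        rng = np.random.default_rng(46)
        p = np.sort(rng.uniform(size=100))
        q = fdr_adjust(p)
        assert (np.diff(q) >= -1e-15).all()

    def test_storey_scales_by_pi0(self):
        rng = np.random.default_rng(47)
        p = rng.uniform(size=1000)
        q_bh = fdr_adjust(p, "bh")
        q_st = fdr_adjust(p, "storey")
        pi0 = min(1.0, (p > 0.5).sum() / (1000 * 0.5))
        assert np.allclose(q_st, np.minimum(pi0 * q_bh, 1.0))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            fdr_adjust(np.array([0.5, 1.5]))


class TestPiValue:
    def test_printed_formula(self):
        assert pi_value(np.array([2.0]), np.array([0.01]))[0] == pytest.approx(4.0)

    def test_zero_cases(self):
        assert pi_value(np.array([0.0]), np.array([0.5]))[0] == 0.0
        assert pi_value(np.array([3.0]), np.array([1.0]))[0] == 0.0

    def test_sign_matches_logfc(self):
        rng = np.random.default_rng(48)
        logfc = rng.normal(size=100)
        q = rng.uniform(0.001, 1.0, size=100)
        pi = pi_value(logfc, q)
        nonzero = q < 1.0
        assert (np.sign(pi[nonzero]) == np.sign(logfc[nonzero])).all()

    def test_zero_q_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            pi = pi_value(np.array([1.0]), np.array([0.0]))
        assert np.isfinite(pi[0]) and pi[0] > 300


class TestRunDifferential:
    def test_planted_effect_recovered(self, small_cohort, small_sets, small_proteome):
        mats, truth = small_proteome
        table = run_differential(mats["liver"], small_cohort, T2D_CTRL)
        affected = truth.group_shift.index[truth.group_shift["T2D"] != 0]
        nulls = truth.group_shift.index[truth.group_shift["T2D"] == 0]
        assert table.loc[affected, "logFC"].mean() == pytest.approx(1.0, abs=0.2)
        assert abs(table.loc[nulls, "logFC"].mean()) < 0.1
        assert (table.loc[affected, "pi"] > 0).mean() > 0.9
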