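"""Repeated-measures ANOVA and Holm correction: definitional oracles,
algebraic identities, and cross-checks against independent packages."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from rsnet.stats import (RepeatedMeasuresDesign, holm_adjust, holm_posthoc,
                         rm_anova, run_full_stats)


def oracle_rm_anova(x):
    """Definitional sums-of-squares computation, written independently."""
    n, k = x.shape
    grand = x.mean()
    ss_cond = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_subj = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ss_tot = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_cond - ss_subj
    df_c, df_e = k - 1, (k - 1) * (n - 1)
    F = (ss_cond / df_c) / (ss_err / df_e)
    eta = ss_cond / (ss_cond + ss_err)
    return F, eta, float(sps.f.sf(F, df_c, df_e))


def oracle_sphericity(x):
    """Mauchly's W and GG epsilon from the contrast-projected covariance."""
    n, k = x.shape
    cov = np.cov(x, rowvar=False, ddof=1)
    # orthonormal basis of the contrast space
    m = np.linalg.svd(np.eye(k) - np.ones((k, k)) / k)[0][:, : k - 1].T
    t = m @ cov @ m.T
    eig = np.clip(np.linalg.eigvalsh(t), 0, None)
    W = np.prod(eig) / (eig.mean() ** (k - 1))
    gg = eig.sum() ** 2 / ((k - 1) * (eig ** 2).sum())
    return float(W), float(gg)


def design(x, outcome="y"):
    x = np.asarray(x, dtype=float)
    return RepeatedMeasuresDesign(
        values=x, conditions=[f"C{j}" for j in range(x.shape[1])],
        outcome=outcome)


class TestRmAnova:
    def test_matches_definitional_oracle(self, rng):
        for _ in range(25):
            x = rng.standard_normal((16, 6))
            res = rm_anova(design(x))
            F, eta, p = oracle_rm_anova(x)
            assert abs(res.F - F) < 1e-10
            assert abs(res.partial_eta2 - eta) < 1e-12
            assert abs(res.p - p) < 1e-12
            W, gg = oracle_sphericity(x)
            assert abs(res.mauchly_W - W) < 1e-10
            assert abs(res.gg_epsilon - gg) < 1e-10

    def test_equal_condition_means_give_zero_F(self, rng):
        base = rng.standard_normal(8)
        # each subject's scores are a permutation-balanced Latin-square-free
        # construction: identical condition means by explicit centering
        x = rng.standard_normal((8, 4))
        x = x - x.mean(axis=0, keepdims=True)  # every condition mean now 0
        res = rm_anova(design(x + base[:, None]))
        assert res.F == pytest.approx(0.0, abs=1e-20)
        assert res.partial_eta2 == pytest.approx(0.0, abs=1e-20)

    def test_two_conditions_F_equals_t_squared(self, rng):
        x = rng.standard_normal((12, 2))
        res = rm_anova(design(x))
        t, p = sps.ttest_rel(x[:, 0], x[:, 1])
        assert abs(res.F - t ** 2) < 1e-10
        assert abs(res.p - p) < 1e-12

    def test_result_invariants(self, rng):
        x = rng.standard_normal((10, 5)) + rng.standard_normal((10, 1))
        res = rm_anova(design(x))
        assert 0 <= res.partial_eta2 <= 1
        assert 1 / (5 - 1) <= res.gg_epsilon <= 1 + 1e-12
        assert res.df_effect == 4 and res.df_error == 36
        assert res.df_effect_gg == pytest.approx(res.gg_epsilon * 4)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        x = rng.standard_normal((9, 4))
        long = pd.DataFrame({
            "y": x.ravel(),
            "subject": np.repeat(np.arange(9), 4),
            "condition": np.tile(np.arange(4), 9),
        })
        res = rm_anova(design(x))
        aov = pg.rm_anova(long, dv="y", within="condition", subject="subject",
                          correction=True, detailed=True)
        assert res.F == pytest.approx(float(aov["F"].iloc[0]), rel=1e-9)
        assert res.p == pytest.approx(float(aov["p_unc"].iloc[0]), rel=1e-9)
        assert res.p_gg == pytest.approx(float(aov["p_GG_corr"].iloc[0]),
                                         rel=1e-6)
        sph = pg.sphericity(long, dv="y", within="condition",
                            subject="subject")
        assert res.mauchly_W == pytest.approx(float(sph.W), rel=1e-9)
        assert res.mauchly_p == pytest.approx(float(sph.pval), rel=1e-6)
        assert res.gg_epsilon == pytest.approx(
            float(pg.epsilon(long, dv="y", within="condition",
                             subject="subject", correction="gg")), rel=1e-9)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError):
            rm_anova(design(np.ones((5, 3))))
        with pytest.raises(ValueError):
            design(np.ones((2, 3)))  # too few subjects


def oracle_holm(p_raw, alpha=0.05):
    """Literal step-down procedure: reject smallest p at alpha/m, then
    alpha/(m-1), ... stop at the first failure."""
    m = len(p_raw)
    order = np.argsort(p_raw)
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p_raw[idx] <= alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject


class TestHolm:
    def test_single_comparison_unchanged(self):
        assert holm_adjust([0.03])[0] == pytest.approx(0.03)

    def test_worked_example(self):
        adj = holm_adjust([0.01, 0.02, 0.20])
        assert np.allclose(adj, [0.03, 0.04, 0.20])

    def test_monotone_and_geq_raw(self, rng):
        for _ in range(20):
            p = rng.uniform(0, 1, rng.integers(2, 8))
            adj = holm_adjust(p)
            assert np.all(adj >= p - 1e-15)
            order = np.argsort(p)
            assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_decisions_match_step_down_enumeration(self):
        # all orderings of small p-value sets, m <= 4
        grids = [
            [0.01, 0.02, 0.03, 0.2], [0.001, 0.012, 0.04, 0.9],
            [0.012, 0.013, 0.014], [0.04, 0.05], [0.2, 0.01, 0.03, 0.049],
        ]
        for base in grids:
            for perm in permutations(base):
                p = np.array(perm)
                assert np.array_equal(holm_adjust(p) < 0.05, oracle_holm(p))

    def test_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        p = rng.uniform(0, 0.3, 10)
        _, adj, _, _ = sm.multipletests(p, method="holm")
        assert np.allclose(holm_adjust(p), adj)


class TestPosthoc:
    def test_pair_count_for_six_conditions(self, rng):
        x = rng.standard_normal((16, 6))
        ph = holm_posthoc(design(x))
        assert len(ph) == 15

    def test_zero_variance_pair_reported_not_raised(self, rng):
        x = rng.standard_normal((8, 3))
        x[:, 1] = x[:, 0] + 1.0  # constant difference
        ph = holm_posthoc(design(x))
        bad = [c for c in ph if c.pair == ("C0", "C1")][0]
        assert bad.p_raw == 1.0 and bad.note

    def test_raw_p_match_paired_t(self, rng):
        x = rng.standard_normal((10, 3))
        ph = holm_posthoc(design(x))
        for comp in ph:
            i = int(comp.pair[0][1:])
            j = int(comp.pair[1][1:])
            t, p = sps.ttest_rel(x[:, i], x[:, j])
            assert comp.p_raw == pytest.approx(p)


class TestRunFullStats:
    def make_table(self, rng, effect=0.0):
        rows = []
        for s in range(8):
            for ci, c in enumerate(["A", "B", "C"]):
                for b in ["theta", "alpha2"]:
                    y = rng.standard_normal() * 0.1 + 1.0
                    if b == "theta" and c == "C":
                        y += effect
                    rows.append({"subject": f"S{s}", "condition": c,
                                 "band": b, "swi": y, "cc_norm": y,
                                 "pl_norm": 1.0 + 0.1 * rng.standard_normal()})
        return pd.DataFrame(rows)

    def test_posthoc_only_on_significant_main_effect(self, rng):
        table = self.make_table(rng, effect=1.5)
        res = run_full_stats(table, ["swi:theta", "swi:alpha2"])
        assert res["swi:theta"].p_selected < 0.05
        assert len(res["swi:theta"].posthoc) == 3
        assert res["swi:alpha2"].posthoc == []

    def test_metric_column_resolution(self, rng):
        table = self.make_table(rng)
        res = run_full_stats(table, ["cc:theta", "pl:alpha2"],
                             alpha=1e-9)
        assert set(res) == {"cc:theta", "pl:alpha2"}
        with pytest.raises(ValueError):
            run_full_stats(table, ["bogus:theta"])
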