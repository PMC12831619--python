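"""Generic statistics: Pearson CI, paired t, RM-ANOVA/GG, p adjustment."""

import numpy as np
import pytest

from neonirs import (
    adjust_pvalues,
    build_crossparadigm_table,
    paired_ttest,
    pearson_ci,
    rm_anova_gg,
    run_crossparadigm,
)


class TestPearsonCi:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        r, n, ci, p = pearson_ci(x, x)
        assert r == pytest.approx(1.0)
        assert n == 10

    def test_type_i_rate(self):
        hits = 0
        n_sims = 1000
        rng = np.random.default_rng(0)
        for _ in range(n_sims):
            x = rng.standard_normal(100)
            y = rng.standard_normal(100)
            _, _, _, p = pearson_ci(x, y)
            hits += p < 0.05
        assert abs(hits / n_sims - 0.05) < 0.02

    def test_ci_coverage_at_n32(self):
        # bivariate normal rho = 0.45, n = 32: the Fisher interval covers
        # the true value in ~95% of draws
        rho = 0.45
        cov = np.array([[1, rho], [rho, 1]])
        rng = np.random.default_rng(1)
        covered = 0
        n_sims = 1000
        for _ in range(n_sims):
            xy = rng.multivariate_normal([0, 0], cov, size=32)
            _, _, (lo, hi), _ = pearson_ci(xy[:, 0], xy[:, 1])
            covered += lo <= rho <= hi
        assert abs(covered / n_sims - 0.95) < 0.025

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_ci(np.ones(10), np.arange(10.0))


class TestPairedT:
    def test_identical_samples(self):
        t, df, p = paired_ttest(np.arange(5.0), np.arange(5.0))
        assert (t, p) == (0.0, 1.0)
        assert df == 4

    def test_hand_arithmetic(self):
        # differences [1, 2, 3]: t = 2 / (1/sqrt(3)) = 3.4641, df = 2
        t, df, p = paired_ttest(np.array([2.0, 4.0, 6.0]), np.array([1.0, 2.0, 3.0]))
        assert t == pytest.approx(2 * np.sqrt(3), rel=1e-9)
        assert df == 2

    def test_matches_scipy_on_random_data(self):
        from scipy import stats as ss

        rng = np.random.default_rng(2)
        for _ in range(100):
            n = rng.integers(3, 30)
            a = rng.standard_normal(n)
            b = rng.standard_normal(n)
            t, df, p = paired_ttest(a, b)
            ref = ss.ttest_rel(a, b)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_zero_variance_nonzero_mean_capped(self):
        t, df, p = paired_ttest(np.full(5, 2.0), np.full(5, 1.0))
        assert t == 1e6 and p == 0.0


class TestRmAnovaGg:
    def test_identical_conditions_f_zero(self):
        rng = np.random.default_rng(0)
        col = rng.standard_normal(8)
        data = np.tile(col[:, None], (1, 4))
        out = rm_anova_gg(data)
        assert out["F"] == pytest.approx(0.0, abs=1e-20)

    def test_compound_symmetry_epsilon_one(self):
        # exchangeable covariance across conditions => sphericity holds
        rng = np.random.default_rng(1)
        n, k = 2000, 4
        subj = rng.standard_normal(n)[:, None]
        data = subj + 0.5 * rng.standard_normal((n, k))
        out = rm_anova_gg(data)
        assert out["epsilon_gg"] == pytest.approx(1.0, abs=0.01)
        # exact sphericity: plug in an exactly compound-symmetric matrix
        S = 0.5 * np.eye(k) + 0.5
        # eps formula on S directly via a synthetic dataset with that cov
        L = np.linalg.cholesky(S)
        z = rng.standard_normal((5000, k)) @ L.T
        z = (z - z.mean(0)) / z.std(0)
        # construct data with *sample* covariance exactly S
        q, _ = np.linalg.qr(z - z.mean(0))
        q /= q.std(0)
        exact = q @ L.T
        out = rm_anova_gg(exact)
        assert out["epsilon_gg"] == pytest.approx(1.0, abs=1e-6)

    def test_matches_sums_of_squares_oracle(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((8, 4))
        out = rm_anova_gg(data)
        # brute-force sums of squares
        grand = data.mean()
        ss_cond = 8 * sum((data[:, j].mean() - grand) ** 2 for j in range(4))
        ss_subj = 4 * sum((data[i].mean() - grand) ** 2 for i in range(8))
        ss_tot = ((data - grand) ** 2).sum()
        ss_err = ss_tot - ss_cond - ss_subj
        F_ref = (ss_cond / 3) / (ss_err / 21)
        eta_ref = ss_cond / (ss_cond + ss_subj + ss_err)
        assert out["F"] == pytest.approx(F_ref, abs=1e-8)
        assert out["eta2_g"] == pytest.approx(eta_ref, abs=1e-8)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(3)
        data = rng.standard_normal((10, 4)) + np.array([0.0, 0.2, 0.4, 0.1])
        out = rm_anova_gg(data)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(10), 4),
                "cond": np.tile(np.arange(4), 10),
                "y": data.ravel(),
            }
        )
        ref = pg.rm_anova(data=long, dv="y", within="cond", subject="subject",
                          correction=True, effsize="ng2", detailed=True)
        assert out["F"] == pytest.approx(float(ref["F"].iloc[0]), rel=1e-6)
        assert out["epsilon_gg"] == pytest.approx(float(ref["eps"].iloc[0]), rel=1e-6)
        assert out["eta2_g"] == pytest.approx(float(ref["ng2"].iloc[0]), rel=1e-6)

    def test_missing_cells_rejected(self):
        data = np.ones((5, 3))
        data[0, 0] = np.nan
        with pytest.raises(ValueError):
            rm_anova_gg(data)


class TestAdjustPvalues:
    def test_single_p_unchanged(self):
        assert adjust_pvalues([0.01], "bonferroni") == [0.01]

    def test_bonferroni_closed_form(self):
        assert adjust_pvalues([0.01, 0.04], "bonferroni") == [0.02, 0.08]

    def test_bh_matches_brute_force(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            m = int(rng.integers(1, 30))
            p = rng.uniform(size=m)
            mine = np.array(adjust_pvalues(p.tolist(), "bh"))
            # brute force: adj_(k) = min over j >= k of m p_(j) / j, capped
            order = np.argsort(p)
            sorted_p = p[order]
            adj = np.empty(m)
            running = 1.0
            for k in range(m - 1, -1, -1):
                running = min(running, m * sorted_p[k] / (k + 1))
                adj[k] = running
            ref = np.empty(m)
            ref[order] = adj
            np.testing.assert_allclose(mine, ref, atol=1e-12)

    def test_adjusted_geq_raw_and_monotone(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=20)
        for method in ("bh", "bonferroni"):
            adj = np.array(adjust_pvalues(p.tolist(), method))
            assert np.all(adj >= p - 1e-12)
        order = np.argsort(p)
        bh = np.array(adjust_pvalues(p.tolist(), "bh"))
        assert np.all(np.diff(bh[order]) >= -1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([], "bh")


class TestCrossParadigm:
    def _table(self, n=40, rho=0.0, seed=0):
        rng = np.random.default_rng(seed)
        sel = rng.standard_normal(n)
        hab = rho * sel + np.sqrt(1 - rho**2) * rng.standard_normal(n)

        class FakeFc:
            def __init__(s, i):
                s.inter_mean = {"HbO": rng.normal(0.6, 0.1)}
                s.intra_mean = {"HbO": rng.normal(0.3, 0.1)}
                import pandas as pd

                s.pair_values = pd.DataFrame(
                    {
                        "chromophore": ["HbO"] * 6,
                        "pair": ["LF-RF", "LT-RT", "LF-RT", "LT-RF", "LF-LT", "RF-RT"],
                        "kind": ["inter"] * 4 + ["intra"] * 2,
                        "r": rng.uniform(0, 0.8, 6),
                        "z": rng.uniform(0, 1.0, 6),
                    }
                )

        ids = [f"s{i}" for i in range(n)]
        return build_crossparadigm_table(
            ids,
            dict(zip(ids, sel)),
            dict(zip(ids, hab)),
            {i: FakeFc(i) for i in ids},
        )

    def test_planted_association_detected(self):
        hits = 0
        for seed in range(100):
            table = self._table(n=32, rho=0.45, seed=seed)
            out = run_crossparadigm(table)
            row = out[(out.metric_x == "selectivity") & (out.metric_y == "habituation")]
            hits += float(row.p_raw.iloc[0]) < 0.05
        assert hits >= 70

    def test_joint_validity_filtering(self):
        table = self._table(n=10)
        table.loc[0, "inter_mean"] = np.nan  # subject invalid in FC only
        out = run_crossparadigm(table)
        n_selhab = int(out[(out.metric_x == "selectivity")
                           & (out.metric_y == "habituation")].n.iloc[0])
        n_selfc = int(out[(out.metric_x == "selectivity")
                          & (out.metric_y == "inter_mean")].n.iloc[0])
        assert n_selhab == 10
        assert n_selfc == 9

    def test_adjusted_geq_raw(self):
        out = run_crossparadigm(self._table(n=20, seed=1))
        assert np.all(out.p_adjusted.to_numpy() >= out.p_raw.to_numpy() - 1e-12)

    def test_missing_metric_rejected(self):
        table = self._table(n=10)
        with pytest.raises(ValueError, match="absent"):
            run_crossparadigm(table, [("selectivity", "nonexistent", "none")])
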