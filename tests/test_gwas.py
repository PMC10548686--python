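import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from csfgwas import gwas, synthetic
from csfgwas.gwas import (
    QCThresholds,
    delta_r2,
    genomic_lambda,
    hwe_test,
    ld_r2_matrix,
    qc_filter,
    run_gwas,
    select_independent_hits,
)


class TestHWE:
    def test_exact_equilibrium_gives_p_one(self):
        assert hwe_test(25, 50, 25) == pytest.approx(1.0)

    def test_total_heterozygote_deficit_fails_filter(self):
        p = hwe_test(50, 0, 50)
        # chi-square is exactly 100 here
        assert p == pytest.approx(stats.chi2.sf(100, 1), rel=1e-10)
        assert p < 5e-6

    def test_monomorphic_convention(self):
        assert hwe_test(0, 0, 100) == 1.0
        assert hwe_test(100, 0, 0) == 1.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            hwe_test(0, 0, 0)


class TestQCFilter:
    def test_per_study_maf_rule(self):
        rng = np.random.default_rng(0)
        n = 2000
        study = np.repeat([0, 1], n // 2)
        # SNP rare in study 0 only; SNP common everywhere
        g_rare = np.concatenate(
            [rng.binomial(2, 0.005, n // 2), rng.binomial(2, 0.05, n // 2)]
        )
        g_common = rng.binomial(2, 0.3, n)
        dos = np.column_stack([g_rare, g_common]).astype(float)
        meta = pd.DataFrame(
            {"snp": ["a", "b"], "imp_quality": [0.9, 0.9]}
        )
        keep, report = qc_filter(dos, meta, study=study)
        assert list(keep) == [False, True]

    def test_imputation_quality_boundary_is_strict(self, rng):
        dos = rng.binomial(2, 0.3, size=(500, 2)).astype(float)
        meta = pd.DataFrame({"snp": ["a", "b"], "imp_quality": [0.30, 0.301]})
        keep, _ = qc_filter(dos, meta)
        assert list(keep) == [False, True]

    def test_toy_panel_with_one_violation_each(self, rng):
        n = 1000
        clean1 = rng.binomial(2, 0.3, n)
        clean2 = rng.binomial(2, 0.2, n)
        low_maf = rng.binomial(2, 0.002, n)
        bad_hwe = np.repeat([0, 2], n // 2)  # no heterozygotes
        low_r2 = rng.binomial(2, 0.25, n)
        dos = np.column_stack([clean1, low_maf, bad_hwe, low_r2, clean2]).astype(float)
        meta = pd.DataFrame(
            {
                "snp": list("abcde"),
                "imp_quality": [0.9, 0.9, 0.9, 0.1, 0.8],
            }
        )
        keep, report = qc_filter(dos, meta)
        assert list(keep) == [True, False, False, False, True]
        counts = dict(zip(report["criterion"], report["n_excluded"]))
        assert counts["retained"] == 2

    def test_idempotent(self, rng):
        dos = rng.binomial(2, rng.uniform(0.05, 0.5, 20), size=(400, 20)).astype(float)
        meta = pd.DataFrame(
            {"snp": [f"s{j}" for j in range(20)],
             "imp_quality": rng.uniform(0.2, 1.0, 20)}
        )
        keep1, _ = qc_filter(dos, meta)
        keep2, _ = qc_filter(dos[:, keep1], meta.loc[keep1].reset_index(drop=True))
        assert keep2.all()

    def test_thresholds_validated(self):
        with pytest.raises(ValueError):
            QCThresholds(maf_min=0.0)


class TestRunGwas:
    def test_exact_linear_relationship(self):
        g = np.array([0.0, 1.0, 2.0, 1.0, 0.0])
        y = 0.1 + 0.5 * g
        res = run_gwas(g, y)
        assert res["beta"].iloc[0] == pytest.approx(0.5, abs=1e-12)
        assert res["se"].iloc[0] == pytest.approx(0.0, abs=1e-6)

    def test_interaction_equals_female_minus_male_slope(self):
        g = np.tile([0.0, 1.0, 2.0, 1.0, 0.0], 20)
        s = np.repeat([0.0, 1.0], 50)
        y = 0.2 * g + 0.3 * g * s + 0.1 * s
        res = run_gwas(g, y, sex=s, model="interaction")
        assert res["beta"].iloc[0] == pytest.approx(0.3, abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        n = 18
        g = rng.binomial(2, 0.4, n).astype(float)
        cov = rng.standard_normal((n, 3))
        sexv = rng.integers(0, 2, n).astype(float)
        y = 0.3 * g + cov @ [0.1, -0.2, 0.05] + rng.standard_normal(n)
        res = run_gwas(g, y, covariates=cov, sex=sexv, model="main")
        X = np.column_stack([np.ones(n), cov, sexv, g])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        df = n - X.shape[1]
        sigma2 = resid @ resid / df
        se = np.sqrt(np.linalg.inv(X.T @ X)[-1, -1] * sigma2)
        p = 2 * stats.t.sf(abs(beta[-1]) / se, df)
        assert res["beta"].iloc[0] == pytest.approx(beta[-1], abs=1e-8)
        assert res["se"].iloc[0] == pytest.approx(se, abs=1e-8)
        assert res["p"].iloc[0] == pytest.approx(p, abs=1e-8)

    def test_stratified_and_interaction_betas_are_consistent(self, rng):
        n = 2000
        g = rng.binomial(2, 0.3, n).astype(float)
        s = rng.integers(0, 2, n).astype(float)
        y = 0.2 * g + 0.25 * g * s + rng.standard_normal(n)
        bm = run_gwas(g, y, sex=s, model="male")["beta"].iloc[0]
        bf = run_gwas(g, y, sex=s, model="female")["beta"].iloc[0]
        bi = run_gwas(g, y, sex=s, model="interaction")["beta"].iloc[0]
        assert bi == pytest.approx(bf - bm, abs=1e-10)

    def test_monomorphic_in_stratum_dropped(self, rng):
        g = np.concatenate([np.zeros(50), rng.binomial(2, 0.4, 50)])
        s = np.repeat([0.0, 1.0], 50)
        y = rng.standard_normal(100)
        res = run_gwas(g, y, sex=s, model="male")
        assert len(res) == 0

    def test_planted_effect_and_se_match_ols_variance(self):
        betas, ses = [], []
        for seed in range(30):
            cfg = synthetic.SimConfig(
                n_samples=973, n_snps=1, maf_range=(0.3, 0.3),
                snp_effects=[synthetic.SnpEffect(0, 1, -0.50)],
                missing_rate=0.0, seed=seed,
            )
            co = synthetic.simulate_cohort(cfg)
            res = run_gwas(co.dosages, co.pc_scores_true[:, 1])
            betas.append(res["beta"].iloc[0])
            ses.append(res["se"].iloc[0])
        assert np.mean(betas) == pytest.approx(-0.50, abs=0.03)
        # closed-form sqrt(sigma^2 / (n 2pq)) with sigma^2 = 0.895
        expect = np.sqrt(0.895 / (973 * 2 * 0.3 * 0.7))
        assert np.mean(ses) == pytest.approx(expect, rel=0.05)


class TestLambda:
    def test_uniform_pvalues_give_unit_lambda(self, rng):
        p = rng.uniform(size=100_000)
        assert genomic_lambda(p) == pytest.approx(1.0, abs=0.02)

    def test_all_half_is_exactly_one(self):
        assert genomic_lambda(np.full(200, 0.5)) == pytest.approx(1.0, abs=1e-12)

    def test_halved_pvalues_inflate(self, rng):
        p = rng.uniform(size=10_000)
        assert genomic_lambda(p / 2) > genomic_lambda(p)


class TestDeltaR2:
    def test_orthogonal_snp_explains_nothing(self, rng):
        g = rng.binomial(2, 0.3, 5000).astype(float)
        y = rng.standard_normal(5000)
        assert delta_r2(g, y) < 0.005

    def test_equals_squared_correlation_without_covariates(self, rng):
        g = rng.binomial(2, 0.3, 300).astype(float)
        y = 0.4 * g + rng.standard_normal(300)
        r2 = np.corrcoef(g, y)[0, 1] ** 2
        assert delta_r2(g, y) == pytest.approx(r2, abs=1e-12)

    def test_matches_variance_partition_oracle(self):
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            p, beta = 0.15, -0.31
            g = rng.binomial(2, p, 2000).astype(float)
            resid = np.sqrt(1 - 2 * p * (1 - p) * beta**2)
            y = beta * g + resid * rng.standard_normal(2000)
            vals.append(delta_r2(g, y))
        assert np.mean(vals) == pytest.approx(2 * 0.15 * 0.85 * 0.31**2, abs=0.005)


class TestClumping:
    def _records(self, ps):
        return pd.DataFrame(
            {"snp": [f"s{i}" for i in range(len(ps))], "p": ps}
        )

    def test_correlated_pair_keeps_smaller_p(self):
        rec = self._records([1e-10, 1e-9])
        ld = pd.DataFrame([[1.0, 0.9], [0.9, 1.0]],
                          index=["s0", "s1"], columns=["s0", "s1"])
        kept = select_independent_hits(rec, ld)
        assert list(kept["snp"]) == ["s0"]

    def test_uncorrelated_all_kept(self):
        rec = self._records([1e-10, 1e-9, 1e-12])
        ld = pd.DataFrame(np.eye(3), index=["s0", "s1", "s2"],
                          columns=["s0", "s1", "s2"])
        kept = select_independent_hits(rec, ld)
        assert set(kept["snp"]) == {"s0", "s1", "s2"}

    def test_chained_ld_matches_exhaustive_search(self):
        # chain: s0-s1 and s1-s2 correlated, s3 free
        ps = [1e-12, 1e-11, 1e-10, 1e-9]
        r2 = np.eye(4)
        r2[0, 1] = r2[1, 0] = 0.9
        r2[1, 2] = r2[2, 1] = 0.8
        rec = self._records(ps)
        ids = [f"s{i}" for i in range(4)]
        ld = pd.DataFrame(r2, index=ids, columns=ids)
        kept = list(select_independent_hits(rec, ld)["snp"])

        # oracle: best admissible subset by greedy p-rank definition
        def admissible(subset):
            return all(r2[i, j] <= 0.6 for i, j in itertools.combinations(subset, 2))

        greedy = []
        for i in np.argsort(ps):
            if admissible(greedy + [i]):
                greedy.append(i)
        assert kept == [f"s{i}" for i in greedy]
        assert kept == ["s0", "s2", "s3"]

    def test_threshold_filters_non_significant(self):
        rec = self._records([1e-9, 1e-4])
        ld = pd.DataFrame(np.eye(2), index=["s0", "s1"], columns=["s0", "s1"])
        kept = select_independent_hits(rec, ld)
        assert list(kept["snp"]) == ["s0"]


def test_type_one_error_calibrated(rng):
    dos, meta = synthetic.simulate_genotypes(600, 5000, (0.05, 0.5), seed=17)
    y = rng.standard_normal(600)
    res = run_gwas(dos, y)
    assert (res["p"] < 0.05).mean() == pytest.approx(0.05, abs=0.01)


def test_ld_matrix_diagonal_and_range(rng):
    dos = rng.binomial(2, 0.3, size=(200, 5)).astype(float)
    r2 = ld_r2_matrix(dos)
    assert np.allclose(np.diag(r2), 1.0)
    assert (r2 >= 0).all() and (r2 <= 1 + 1e-12).all()
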