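"""Kinship, score test, inflation factor, PC selection, q-values, Var%."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from metaboqtl.gwas import (
    CHI2_1DF_MEDIAN,
    GwasConfig,
    KinshipMatrix,
    _best_k,
    chi2_1df_median,
    explained_variance,
    genomic_kinship,
    inflation_factor,
    kinship_pcs,
    qvalues,
    run_gwas,
    scan_snps,
    score_test,
    select_pc_count,
)
from metaboqtl.simdata import SimConfig, simulate_dataset, simulate_panel
from tests.test_genotype import make_panel


class TestKinship:
    def test_duplicate_samples_share_diagonal_value(self, rng):
        d = rng.binomial(2, rng.uniform(0.2, 0.8, 50), (6, 50)).astype(float)
        d[5] = d[0]  # sample 5 duplicates sample 0
        K = genomic_kinship(make_panel(d)).values
        assert K[0, 5] == pytest.approx(K[0, 0], abs=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        d = rng.binomial(2, rng.uniform(0.2, 0.8, 20), (5, 20)).astype(float)
        d[rng.random(d.shape) < 0.1] = np.nan
        K = genomic_kinship(make_panel(d)).values
        p = np.nansum(d, axis=0) / (2 * (~np.isnan(d)).sum(axis=0))
        expect = np.zeros((5, 5))
        for i in range(5):
            for j in range(5):
                vals = []
                for s in range(20):
                    if np.isnan(d[i, s]) or np.isnan(d[j, s]) or not 0 < p[s] < 1:
                        continue
                    vals.append(
                        (d[i, s] - 2 * p[s]) * (d[j, s] - 2 * p[s])
                        / (2 * p[s] * (1 - p[s]))
                    )
                expect[i, j] = np.mean(vals)
        np.testing.assert_allclose(K, expect, atol=1e-12)

    def test_leading_pc_separates_subpopulations(self):
        cfg = SimConfig(n_snps=1500, seed=21, stratification="two_subpop",
                        divergence=0.4)
        panel, labels = simulate_panel(cfg)
        K = genomic_kinship(panel)
        pc1 = kinship_pcs(K, 1)[:, 0]
        lab = np.array([labels[s] == "B" for s in panel.sample_ids], dtype=float)
        assert abs(np.corrcoef(pc1, lab)[0, 1]) >= 0.9

    def test_monomorphic_snps_skipped(self, rng):
        d = np.column_stack(
            [rng.binomial(2, 0.5, 10).astype(float), np.zeros(10), np.full(10, 2.0)]
        )
        K = genomic_kinship(make_panel(d))
        assert np.isfinite(K.values).all()

    def test_symmetry_enforced(self):
        with pytest.raises(ValueError, match="symmetric"):
            KinshipMatrix(np.array([[1.0, 0.5], [0.2, 1.0]]), ["a", "b"])


class TestScoreTest:
    def test_perfectly_correlated_trait(self):
        g = np.array([0, 1, 2, 0, 1, 2, 0, 1, 2, 1], dtype=float)
        chi2, eff, se, p, n = score_test(g.copy(), g)
        assert chi2 == pytest.approx(9.0)  # (n-1) r^2 with r=1
        assert eff == pytest.approx(1.0)

    def test_four_point_hand_example(self):
        """y=(1,2,3,4), g=(0,1,1,2): r^2 = 0.9 so chi2 = 3 * 0.9 = 2.7."""
        chi2, eff, *_ = score_test(
            np.array([1.0, 2, 3, 4]), np.array([0.0, 1, 1, 2])
        )
        assert chi2 == pytest.approx(2.7, abs=1e-12)
        assert eff == pytest.approx(1.5, abs=1e-12)  # sgy/sgg = 3/2

    def test_permutation_null_mean_chi2(self, rng):
        """Mean chi2 over 2,000 trait permutations is 1.0 +/- 0.07."""
        n = 97
        y = rng.normal(size=n)
        g = rng.binomial(2, 0.4, n).astype(float)
        chis = []
        for _ in range(2000):
            perm = rng.permutation(n)
            chis.append(score_test(y[perm], g)[0])
        assert np.mean(chis) == pytest.approx(1.0, abs=0.07)

    def test_equals_explicit_pc_regression(self, rng):
        """chi2 from residual correlation equals (n-k-1) * partial R^2 from an
        explicit OLS with PC covariates, on 100 random instances."""
        for _ in range(100):
            n = int(rng.integers(30, 80))
            k = int(rng.integers(0, 4))
            y = rng.normal(size=n)
            g = rng.binomial(2, 0.4, n).astype(float)
            pcs = rng.normal(size=(n, k)) if k else None
            chi2, *_ = score_test(y, g, pcs)
            X0 = np.column_stack([np.ones(n)] + ([pcs] if k else []))
            X1 = np.column_stack([X0, g])
            rss0 = y @ y - y @ X0 @ np.linalg.lstsq(X0, y, rcond=None)[0]
            rss1 = y @ y - y @ X1 @ np.linalg.lstsq(X1, y, rcond=None)[0]
            r2_partial = (rss0 - rss1) / rss0
            assert chi2 == pytest.approx((n - k - 1) * r2_partial, abs=1e-8)

    def test_missing_dosages_mean_imputed(self, rng):
        n = 50
        y = rng.normal(size=n)
        g = rng.binomial(2, 0.5, n).astype(float)
        gm = g.copy()
        gm[:5] = np.nan
        gi = gm.copy()
        gi[:5] = np.nanmean(gm)
        assert score_test(y, gm)[0] == pytest.approx(score_test(y, gi)[0], abs=1e-12)

    def test_constant_dosage_skipped(self):
        res = scan_snps(np.arange(10.0), np.ones((10, 1)))
        assert not res.tested[0]
        with pytest.raises(ValueError, match="zero dosage residual"):
            score_test(np.arange(10.0), np.ones(10))


class TestInflationFactor:
    def test_unit_lambda_at_chi2_median(self):
        assert inflation_factor(np.full(200, 0.4549)) == pytest.approx(1.0)

    def test_scaling(self):
        assert inflation_factor(np.full(200, 0.9098)) == pytest.approx(2.0)

    def test_chi2_draws_give_unit_lambda(self, rng):
        draws = stats.chi2.rvs(df=1, size=20000, random_state=rng)
        assert inflation_factor(draws) == pytest.approx(1.0, abs=0.03)

    def test_denominator_is_chi2_median(self):
        assert chi2_1df_median() == CHI2_1DF_MEDIAN

    def test_small_vector_warns(self):
        with pytest.warns(UserWarning, match="unstable"):
            inflation_factor(np.full(50, 0.4549))


class TestPCSelection:
    def test_tie_goes_to_smaller_k(self):
        profile = {0: 2.0, 3: 1.25, 7: 0.75, 5: 1.5}
        assert _best_k(profile) == 3  # |1.25-1| == |0.75-1|, smaller k wins

    def test_null_panel_lambda_near_one(self):
        cfg = SimConfig(n_snps=1500, seed=31, stratification="off",
                        n_causal_snps=0)
        ds = simulate_dataset(cfg)
        y = np.random.default_rng(31).normal(size=97)
        sel = select_pc_count(y, ds.panel.dosages, genomic_kinship(ds.panel))
        assert 0.9 <= sel.lam <= 1.1

    def test_stratified_trait_corrected_below_uncorrected(self):
        """Confounded two-subpopulation traits: corrected lambda < lambda(0)
        and <= 1.05 in >= 2/3 small replicates."""
        ok = 0
        for seed in range(3):
            cfg = SimConfig(n_snps=1500, seed=seed, stratification="two_subpop",
                            divergence=0.3, n_causal_snps=0)
            panel, labels = simulate_panel(cfg)
            rng = np.random.default_rng(seed)
            y = rng.normal(size=97) + np.array(
                [1.0 if labels[s] == "B" else 0.0 for s in panel.sample_ids]
            )
            sel = select_pc_count(y, panel.dosages, genomic_kinship(panel))
            ok += sel.lam < sel.profile[0] and sel.lam <= 1.05
        assert ok >= 2


class TestQvalues:
    def test_all_ones(self):
        q, pi0 = qvalues(np.ones(50))
        assert (q == 1.0).all() and pi0 == 1.0

    def test_pi0_one_equals_benjamini_hochberg(self, rng):
        p = rng.uniform(1e-6, 1, 500)
        q, _ = qvalues(p, pi0=1.0)
        bh = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(q, bh, atol=1e-12)

    def test_pi0_estimate_on_uniform(self, rng):
        p = rng.uniform(1e-12, 1, 5000)
        _, pi0 = qvalues(p)
        assert pi0 == pytest.approx(1.0, abs=0.1)

    def test_monotone_in_p_and_dominates_bh(self, rng):
        p = np.concatenate([rng.uniform(1e-8, 0.01, 50), rng.uniform(0, 1, 450)])
        p = np.clip(p, 1e-12, 1.0)
        q, pi0 = qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()
        bh = multipletests(p, method="fdr_bh")[1]
        assert pi0 <= 1.0
        assert (q <= bh + 1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            qvalues(np.array([0.0, 0.5]))
        with pytest.raises(ValueError):
            qvalues(np.array([0.5, 1.5]))


class TestExplainedVariance:
    def test_endpoints(self):
        assert explained_variance(0.0, 97) == 0.0
        assert explained_variance(95.0, 97) == pytest.approx(50.0)

    def test_worked_value(self):
        assert explained_variance(16.05, 97) == pytest.approx(14.45, abs=0.005)


@pytest.fixture(scope="module")
def gwas_result(small_dataset):
    from metaboqtl.genotype import apply_qc
    from metaboqtl.traits import TraitTable, residualize_all

    panel, _ = apply_qc(small_dataset.panel)
    table = TraitTable(
        small_dataset.traits.set_index("sample_id").join(
            small_dataset.metabotypes.iloc[:, :3]
        )
    )
    adj = residualize_all(table)
    traits = list(adj.residual_frame.columns)
    return panel, adj.residual_frame, run_gwas(
        traits, adj.residual_frame, panel, GwasConfig(k_max=4)
    )


class TestRunGwas:
    def test_summary_counts_match_scan(self, gwas_result):
        panel, _, result = gwas_result
        for _, row in result.summaries.iterrows():
            sub = result.associations[result.associations.trait_id == row.trait_id]
            assert len(sub) == panel.n_snps
            assert row.n_snps_tested == sub.p_value.notna().sum()
            assert row.n_q10 == (sub.q_value <= 0.1).sum()

    def test_var_pct_consistent_with_chi2(self, gwas_result):
        _, _, result = gwas_result
        a = result.associations.dropna(subset=["chi2"])
        expect = 100 * a.chi2 / (a.n_used - 2 + a.chi2)
        np.testing.assert_allclose(a.var_explained_pct, expect, rtol=1e-10)

    def test_lambda_invariant_to_snp_order(self, gwas_result, rng):
        panel, residuals, result = gwas_result
        perm = rng.permutation(panel.n_snps)
        shuffled = panel.subset_snps(np.sort(perm))  # keep map order valid
        y = residuals.iloc[:, 0].to_numpy()
        lam1 = inflation_factor(scan_snps(y, panel.dosages).chi2)
        lam2 = inflation_factor(scan_snps(y, panel.dosages[:, perm]).chi2)
        assert lam1 == pytest.approx(lam2, abs=1e-12)

    def test_affine_trait_rescale_leaves_chi2_p_q_unchanged(self, gwas_result):
        panel, residuals, _ = gwas_result
        y = residuals.iloc[:, 0].to_numpy()
        a = scan_snps(y, panel.dosages)
        b = scan_snps(3.0 * y + 2.0, panel.dosages)
        np.testing.assert_allclose(b.chi2, a.chi2, rtol=1e-9)
        np.testing.assert_allclose(b.effect, 3.0 * a.effect, rtol=1e-9)

    def test_unknown_trait_rejected(self, gwas_result):
        panel, residuals, _ = gwas_result
        with pytest.raises(KeyError, match="absent"):
            run_gwas(["nope"], residuals, panel)
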