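"""Condition coding, robust outlier rule, mixed models, permutation FWER."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq
from scipy.stats import norm, spearmanr

from stsroi.glmm_inference import (
    EFFECTS,
    add_condition_coding,
    code_conditions,
    detect_outliers,
    exclude_outliers,
    fit_glmm,
    min_t_conjunction,
    outlier_cutoff,
    permutation_fwer,
    scale_predictors,
    subject_ols_tscores,
)
from stsroi.synthetic_data import DesignSpec, EffectSpec, gen_block_psc


class TestConditionCoding:
    @pytest.mark.parametrize(
        "label,expected",
        [("A", (1, 0, 1)), ("V", (0, 1, 1)), ("AV", (1, 1, 1)),
         ("R", (1, 0, 0)), ("G", (0, 1, 0))],
    )
    def test_coding_table(self, label, expected):
        row = code_conditions([label]).iloc[0]
        assert tuple(row[list(EFFECTS)]) == expected

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown condition"):
            code_conditions(["X"])


class TestOutlierRule:
    @pytest.mark.parametrize("n,alpha_expected", [(150, 4.35), (1000, 4.75)])
    def test_alpha_matches_bisection_oracle(self, n, alpha_expected):
        """alpha = Phi^-1(1 - 0.001/N), checked by bisecting the normal CDF."""
        oracle = brentq(lambda z: norm.cdf(z) - (1 - 0.001 / n), 0, 10, xtol=1e-10)
        assert outlier_cutoff(n) == pytest.approx(oracle, abs=1e-8)
        assert round(outlier_cutoff(n), 2) == alpha_expected

    def test_cutoff_with_unit_mad(self):
        # MAD = 1 at N = 150: C = alpha * pi/2 ~ 6.84
        assert outlier_cutoff(150) * np.pi / 2 == pytest.approx(6.84, abs=0.01)

    def test_degenerate_constant_data(self):
        """MAD = 0: every point off the median is flagged."""
        x = np.array([1.0] * 10 + [1.5])
        keep = detect_outliers(x)
        assert keep[:10].all() and not keep[10]

    def test_flags_gross_outlier_only(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 149).tolist() + [50.0]
        keep = detect_outliers(np.asarray(x))
        assert not keep[-1] and keep[:-1].all()

    def test_gaussian_false_flag_rate_is_tiny(self):
        """The N-adjusted quantile makes false flags rare: the expected count
        per 150-point Gaussian sample is ~0.002, i.e. a vanishing fraction."""
        rng = np.random.default_rng(1)
        total, flagged = 0, 0
        for _ in range(2000):
            x = rng.normal(0, 1, 150)
            keep = detect_outliers(x)
            total += x.size
            flagged += (~keep).sum()
        assert flagged / total < 5e-4  # well under 0.1% of points

    def test_exclude_outliers_per_subject(self):
        d = DesignSpec(n_subjects=3, n_runs=10, seed=2)
        tab = gen_block_psc(d, EffectSpec(noise_sd=0.3))
        tab.loc[0, "psc"] = 99.0
        cleaned = exclude_outliers(tab)
        assert len(cleaned) == len(tab) - 1
        assert not (cleaned.psc == 99.0).any()


class TestScalePredictors:
    def _coded(self, **kw):
        d = DesignSpec(n_subjects=3, n_runs=2, seed=1)
        return add_condition_coding(gen_block_psc(d, EffectSpec(**kw)))

    def test_per_stratum_moments(self):
        scaled = scale_predictors(self._coded())
        g = scaled.groupby(["subject_id", "subregion_id"])
        for e in EFFECTS:
            assert g[e].mean().abs().max() < 1e-12
            assert (g[e].std(ddof=1) - 1).abs().max() < 1e-12

    def test_balanced_design_two_symmetric_values(self):
        scaled = scale_predictors(self._coded())
        vals = np.sort(scaled["AP"].unique())
        assert len(vals) == 2
        # two-point standardized variable: values are -sqrt(q/p), sqrt(p/q)
        assert vals[0] < 0 < vals[1]

    def test_unbalanced_stratum_still_centered(self):
        tab = self._coded().iloc[3:]  # drop a block from the first stratum
        scaled = scale_predictors(tab)
        g = scaled.groupby(["subject_id", "subregion_id"])
        assert g["AP"].mean().abs().max() < 1e-12

    def test_zero_variance_stratum_rejected(self):
        tab = self._coded()
        tab = tab[tab.condition == "AV"]
        with pytest.raises(ValueError, match="zero-variance"):
            scale_predictors(tab)


class TestMixedModel:
    def test_deterministic_limit_recovers_beta_exactly(self):
        d = DesignSpec(n_subjects=4, n_runs=2, seed=1)
        tab = add_condition_coding(gen_block_psc(d, EffectSpec(beta_AP=0.5)))
        fit = fit_glmm(tab, subregion=1)
        assert fit.estimates["AP"] == pytest.approx(0.5, abs=1e-6)
        assert fit.estimates["VP"] == pytest.approx(0.0, abs=1e-6)

    def test_zero_random_variance_matches_pooled_ols(self):
        import statsmodels.formula.api as smf

        d = DesignSpec(n_subjects=6, n_runs=3, seed=2)
        tab = add_condition_coding(
            gen_block_psc(d, EffectSpec(beta_AP=0.4, beta_SP=0.2, noise_sd=0.3))
        )
        fit = fit_glmm(tab, subregion=1)
        ols = smf.ols("psc ~ AP + VP + SP", tab).fit()
        for e in EFFECTS:
            assert fit.estimates[e] == pytest.approx(ols.params[e], abs=1e-4)

    def test_needs_two_subjects(self):
        d = DesignSpec(n_subjects=1, n_runs=2, seed=1)
        tab = add_condition_coding(gen_block_psc(d, EffectSpec(noise_sd=0.1)))
        with pytest.raises(ValueError, match="2 subjects"):
            fit_glmm(tab, subregion=1)

    def test_subject_relabeling_invariance(self):
        d = DesignSpec(n_subjects=6, n_runs=2, seed=8)
        tab = add_condition_coding(gen_block_psc(
            d, EffectSpec(beta_VP=0.3, noise_sd=0.3, random_effect_sd=(0.1, 0, 0, 0))
        ))
        fit_a = fit_glmm(tab, subregion=1)
        relabel = {1: 4, 2: 6, 3: 1, 4: 5, 5: 2, 6: 3}
        tab2 = tab.assign(subject_id=tab.subject_id.map(relabel))
        tab2 = tab2.sort_values(["subject_id", "run_id", "condition"]).reset_index(drop=True)
        fit_b = fit_glmm(tab2, subregion=1)
        for e in EFFECTS:
            assert fit_a.estimates[e] == pytest.approx(fit_b.estimates[e], abs=1e-6)


class TestPermutationFwer:
    def _null_table(self, seed, n_subjects=4, n_subregions=2):
        d = DesignSpec(n_subjects=n_subjects, n_runs=2, seed=seed)
        return gen_block_psc(
            d, [EffectSpec(noise_sd=0.3, random_effect_sd=(0.1, 0, 0, 0))] * n_subregions
        )

    def test_observed_matches_direct_fast_scores(self):
        """The engine's observed t equals an independent per-subregion score."""
        tab = self._null_table(3)
        res = permutation_fwer(tab, n_permutations=10, seed=1, method="subject_ols")
        coded = scale_predictors(add_condition_coding(tab))
        for sr in (1, 2):
            direct = subject_ols_tscores(coded[coded.subregion_id == sr])
            for e in EFFECTS:
                assert res.observed.loc[sr, e] == pytest.approx(direct[e], abs=1e-10)

    def test_identity_permutation_reproduces_observed(self):
        """Exhaustive nulls contain the identity: its extrema equal the
        observed per-effect extrema exactly."""
        d = DesignSpec(n_subjects=2, n_runs=1, blocks_per_condition_per_run=1, seed=5)
        tab = gen_block_psc(d, [EffectSpec(noise_sd=0.5)] * 2)
        res = permutation_fwer(tab, method="subject_ols", exhaustive=True)
        obs_max = res.observed.max(axis=0).to_numpy()
        null_max = res.max_t.to_numpy()
        for j in range(len(EFFECTS)):
            assert np.any(np.abs(null_max[:, j] - obs_max[j]) < 1e-10)

    def test_exhaustive_matches_bruteforce_enumeration(self):
        """Tiny instance: engine p-values equal independent full enumeration."""
        d = DesignSpec(n_subjects=2, n_runs=1, blocks_per_condition_per_run=1, seed=5)
        tab = gen_block_psc(d, [EffectSpec(noise_sd=0.5)] * 2)
        res = permutation_fwer(tab, method="subject_ols", exhaustive=True)

        df = scale_predictors(add_condition_coding(tab)).sort_values(
            ["subregion_id", "subject_id", "run_id", "condition", "block_index"]
        ).reset_index(drop=True)
        perms = list(itertools.permutations(range(5)))
        # per subject x subregion: betas for every single-subject permutation
        beta = {}
        for sr in (1, 2):
            for s in (1, 2):
                sub = df[(df.subregion_id == sr) & (df.subject_id == s)]
                y = sub["psc"].to_numpy()
                cols = [sub[e].to_numpy() for e in EFFECTS]
                beta[(sr, s)] = np.array([
                    np.linalg.lstsq(
                        np.column_stack([np.ones(5)] + [c[list(p)] for c in cols]),
                        y, rcond=None)[0][1:]
                    for p in perms
                ])
        n_p = len(perms)
        maxs = np.empty((n_p * n_p, 3))
        mins = np.empty((n_p * n_p, 3))
        k = 0
        for i1 in range(n_p):
            for i2 in range(n_p):
                t = np.empty((2, 3))
                for r, sr in enumerate((1, 2)):
                    B = np.vstack([beta[(sr, 1)][i1], beta[(sr, 2)][i2]])
                    t[r] = B.mean(0) / (B.std(0, ddof=1) / np.sqrt(2))
                maxs[k] = t.max(0)
                mins[k] = t.min(0)
                k += 1
        ident = perms.index(tuple(range(5)))
        obs = np.empty((2, 3))
        for r, sr in enumerate((1, 2)):
            B = np.vstack([beta[(sr, 1)][ident], beta[(sr, 2)][ident]])
            obs[r] = B.mean(0) / (B.std(0, ddof=1) / np.sqrt(2))
        pv = np.empty((2, 3))
        for i in range(2):
            for j in range(3):
                t0 = obs[i, j]
                pv[i, j] = ((maxs[:, j] >= t0 - 1e-8).mean() if t0 >= 0
                            else (mins[:, j] <= t0 + 1e-8).mean())
        assert np.array_equal(pv, res.pvalues.to_numpy())

    def test_seed_reproducibility_and_seed_required(self):
        tab = self._null_table(4)
        a = permutation_fwer(tab, n_permutations=50, seed=9, method="subject_ols")
        b = permutation_fwer(tab, n_permutations=50, seed=9, method="subject_ols")
        pd.testing.assert_frame_equal(a.pvalues, b.pvalues)
        with pytest.raises(ValueError, match="seed"):
            permutation_fwer(tab, n_permutations=50, method="subject_ols")

    def test_power_strong_visual_effect_detected(self):
        """beta_VP = 1.0 at noise 0.3, n = 18: VP significant in every run."""
        rng = np.random.default_rng(17)
        detected = 0
        n_sims = 10
        for _ in range(n_sims):
            d = DesignSpec(n_subjects=18, n_runs=2, seed=int(rng.integers(2**31 - 1)))
            tab = gen_block_psc(
                d, [EffectSpec(beta_VP=1.0, noise_sd=0.3,
                               random_effect_sd=(0.1, 0.05, 0.05, 0.05))] * 2
            )
            res = permutation_fwer(tab, n_permutations=200,
                                   seed=int(rng.integers(2**31 - 1)),
                                   method="subject_ols")
            if (res.pvalues["VP"] < 0.05).any():
                detected += 1
        assert detected >= 0.95 * n_sims

    def test_fast_score_rank_agreement_with_mixed_model(self):
        """Validation set of 20 fits: the subject-OLS score preserves the
        rank ordering of mixed-model t-scores."""
        rng = np.random.default_rng(7)
        t_mixed, t_fast = [], []
        for _ in range(20):
            d = DesignSpec(n_subjects=10, n_runs=3, seed=int(rng.integers(2**31 - 1)))
            tab = gen_block_psc(d, EffectSpec(
                beta_AP=rng.uniform(-0.3, 0.3), beta_VP=rng.uniform(-0.3, 0.3),
                beta_SP=rng.uniform(-0.3, 0.3), noise_sd=0.3,
                random_effect_sd=(0.1, 0.05, 0.05, 0.05),
            ))
            coded = scale_predictors(add_condition_coding(tab))
            fit = fit_glmm(coded, subregion=1)
            fast = subject_ols_tscores(coded)
            t_mixed.extend(fit.tscores[e] for e in EFFECTS)
            t_fast.extend(fast[e] for e in EFFECTS)
        rho = spearmanr(t_mixed, t_fast).statistic
        assert rho > 0.9

    def test_mixed_method_agrees_with_fast_on_small_instance(self):
        """Both refit methods produce valid, similar p-values on one table."""
        tab = self._null_table(21, n_subjects=4)
        fast = permutation_fwer(tab, n_permutations=30, seed=2, method="subject_ols")
        mixed = permutation_fwer(tab, n_permutations=30, seed=2, method="mixed")
        assert fast.pvalues.shape == mixed.pvalues.shape
        assert ((mixed.pvalues > 0) & (mixed.pvalues <= 1)).all().all()


class TestConjunction:
    def test_min_t_properties(self, rng):
        a = rng.normal(size=(4, 5))
        b = rng.normal(size=(4, 5))
        m = min_t_conjunction(a, b)
        assert np.array_equal(min_t_conjunction(a, a), a)
        assert min_t_conjunction(np.array([3.2]), np.array([2.1]))[0] == 2.1
        assert (m <= a).all() and (m <= b).all()

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="aligned"):
            min_t_conjunction(np.zeros(3), np.zeros(4))
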