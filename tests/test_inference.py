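"""Comparative inference: t-tests, REML mixed models, LR sequence, correlation."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from thermopair import (
    difference_correlation,
    generate_pair_dataset,
    lr_test_sequence,
    nested_taxonomy_lmm,
    normality_diagnostics,
    paired_lmm,
    residual_diagnostics,
    status_t_test,
)
from thermopair.exceptions import ValidationError
from thermopair.inference import plot_residuals
from thermopair.pairs import long_from_pairs_frame
from thermopair.simulate import SimulationConfig


def make_paired_long(n_pairs, sd_pair, sd_res, effect, seed):
    rng = np.random.default_rng(seed)
    base = rng.normal(10, sd_pair, n_pairs)
    lo = base + rng.normal(0, sd_res, n_pairs)
    hi = base + effect + rng.normal(0, sd_res, n_pairs)
    return pd.DataFrame(
        {
            "pair_id": np.repeat([f"P{i}" for i in range(n_pairs)], 2),
            "status": np.tile([0, 1], n_pairs),
            "value": np.column_stack([lo, hi]).ravel(),
        }
    )


class TestStatusTTest:
    def test_pooled_hand_computation(self):
        # groups {1,2,3} (status 1) vs {2,3,4} (status 0): pooled s2 = 1
        values = np.array([1.0, 2, 3, 2, 3, 4])
        status = np.array([1, 1, 1, 0, 0, 0])
        res = status_t_test(values, status, variant="pooled_two_sample")
        assert res.statistic_t == pytest.approx(-1.22474487, abs=1e-6)
        assert res.df == 4
        assert res.mean_difference == pytest.approx(-1.0)

    def test_identical_groups_degenerate(self):
        values = np.array([5.0, 5, 5, 5])
        status = np.array([0, 0, 1, 1])
        res = status_t_test(values, status, variant="pooled_two_sample")
        assert res.statistic_t == 0.0 and res.p_value == 1.0

    def test_paired_matches_scipy_ttest_rel(self):
        rng = np.random.default_rng(1)
        n = 30
        lo, hi = rng.normal(10, 2, n), rng.normal(11, 2, n)
        values = np.column_stack([lo, hi]).ravel()
        status = np.tile([0, 1], n)
        pairing = np.repeat(np.arange(n), 2)
        res = status_t_test(values, status, pairing, variant="paired_differences")
        t_ref, p_ref = stats.ttest_rel(hi, lo)
        assert res.statistic_t == pytest.approx(t_ref, abs=1e-10)
        assert res.p_value == pytest.approx(p_ref, abs=1e-10)
        assert res.df == n - 1

    def test_paired_requires_pairing(self):
        with pytest.raises(ValidationError):
            status_t_test(np.arange(4.0), np.array([0, 1, 0, 1]),
                          variant="paired_differences")


class TestPairedLMM:
    def test_matches_statsmodels_mixedlm(self):
        long = make_paired_long(80, sd_pair=1.5, sd_res=1.0, effect=1.0, seed=2)
        fit = paired_lmm(long)
        import statsmodels.formula.api as smf

        ref = smf.mixedlm("value ~ status", long, groups=long["pair_id"]).fit(reml=True)
        assert fit.fixed_effect_status == pytest.approx(ref.params["status"], abs=1e-5)
        assert fit.se_fixed == pytest.approx(ref.bse["status"], abs=1e-5)
        assert fit.var_between == pytest.approx(ref.cov_re.iloc[0, 0], rel=1e-3)
        assert fit.var_residual == pytest.approx(ref.scale, rel=1e-3)
        assert fit.log_likelihood == pytest.approx(ref.llf, abs=1e-4)

    def test_variance_components_match_anova_moments_oracle(self):
        # balanced one-way layout: MoM from within/between mean squares
        long = make_paired_long(200, sd_pair=np.sqrt(3), sd_res=1.0, effect=0.0, seed=3)
        fit = paired_lmm(long)
        wide = long.pivot(index="pair_id", columns="status", values="value")
        diffs = wide[1] - wide[0]
        sums_mean = wide.mean(axis=1)
        ms_within = float((diffs**2).sum() / (2 * len(wide)))  # per-obs within MS
        # centred differences estimate sigma2; pair means estimate sigma_b^2 + sigma2/2
        sigma2_mom = float(diffs.var(ddof=1) / 2)
        sigma_b2_mom = float(sums_mean.var(ddof=1) - sigma2_mom / 2)
        assert fit.var_residual == pytest.approx(sigma2_mom, rel=0.15)
        assert fit.var_between == pytest.approx(sigma_b2_mom, rel=0.15)
        assert ms_within > 0

    def test_zero_between_pair_variance_boundary(self):
        long = make_paired_long(100, sd_pair=0.0, sd_res=1.0, effect=0.8, seed=4)
        fit = paired_lmm(long)
        assert fit.icc == pytest.approx(0.0, abs=0.05)
        assert abs(fit.fixed_effect_status - 0.8) < 2 * fit.se_fixed

    def test_paired_df_equals_npairs_minus_one_when_balanced(self):
        long = make_paired_long(50, sd_pair=2.0, sd_res=1.0, effect=1.0, seed=5)
        fit = paired_lmm(long)
        assert fit.satterthwaite_df == pytest.approx(49, abs=0.5)

    def test_icc_recovery_across_generating_values(self):
        for target in (0.1, 0.2, 0.5):
            iccs = []
            for rep in range(20):
                cfg = SimulationConfig(
                    seed=1000 + rep, n_pairs=500, target_icc=target, effect_ldt=1.0
                )
                _, pairs = generate_pair_dataset(cfg)
                iccs.append(paired_lmm(long_from_pairs_frame(pairs, "ldt")).icc)
            assert np.mean(iccs) == pytest.approx(target, abs=0.05)


class TestNestedTaxonomyLMM:
    def test_none_equals_pooled_t(self, species_long_table):
        fit = nested_taxonomy_lmm(species_long_table, "none")
        ref = status_t_test(
            species_long_table["value"].to_numpy(),
            species_long_table["status"].to_numpy(),
            variant="pooled_two_sample",
        )
        assert fit.statistic_t == pytest.approx(ref.statistic_t, abs=1e-6)
        assert fit.satterthwaite_df == pytest.approx(ref.df, abs=1e-6)

    def test_family_effect_detected_and_inflates_status_se(self, species_long_table):
        full = nested_taxonomy_lmm(species_long_table, "family_in_order")
        assert full.var_components["family_in_order"] > 0
        # permuting family labels destroys the family variance signal
        rng = np.random.default_rng(0)
        permuted = species_long_table.assign(
            family=rng.permutation(species_long_table["family"].to_numpy())
        )
        perm_fit = nested_taxonomy_lmm(permuted, "family_in_order")
        assert full.var_components["family_in_order"] > perm_fit.var_components[
            "family_in_order"
        ]

    def test_matches_lmertest_oracle(self, species_long_table, tmp_path):
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        csv = tmp_path / "d.csv"
        species_long_table.to_csv(csv, index=False)
        script = textwrap.dedent(
            f"""
            suppressMessages(library(lmerTest))
            d <- read.csv("{csv}")
            m <- lmer(value ~ status + (1|order) + (1|order:family), data=d, REML=TRUE)
            s <- summary(m)$coefficients["status", ]
            cat(s["Estimate"], s["Std. Error"], s["df"], as.numeric(logLik(m)), sep="\\n")
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        beta, se, df, llf = map(float, out.stdout.split())
        fit = nested_taxonomy_lmm(species_long_table, "family_in_order")
        assert fit.fixed_effect_status == pytest.approx(beta, abs=1e-4)
        assert fit.se_fixed == pytest.approx(se, abs=1e-4)
        assert fit.satterthwaite_df == pytest.approx(df, abs=0.5)
        assert fit.log_likelihood == pytest.approx(llf, abs=1e-3)

    def test_single_order_falls_back(self, species_long_table):
        single = species_long_table.assign(order="only")
        fit = nested_taxonomy_lmm(single, "order")
        assert fit.grouping == "none"


class TestLRSequence:
    def test_relabeling_invariance(self, species_long_table):
        base = lr_test_sequence(species_long_table)
        relabeled = species_long_table.assign(
            order=species_long_table["order"].map(lambda s: f"xx_{s}"),
            family=species_long_table["family"].map(lambda s: f"yy_{s}"),
        )
        other = lr_test_sequence(relabeled)
        for a, b in zip(base, other):
            assert a.statistic_L == pytest.approx(b.statistic_L, abs=1e-5)

    def test_null_variance_keeps_lr_small(self):
        # no order/family variance: both steps conservative at the boundary
        n_exceed = 0
        reps = 40
        rng = np.random.default_rng(9)
        for rep in range(reps):
            n = 120
            table = pd.DataFrame(
                {
                    "value": rng.normal(10, 2, n) + 0.5 * np.tile([0, 1], n // 2),
                    "status": np.tile([0, 1], n // 2),
                    "order": np.repeat([f"O{i}" for i in range(6)], n // 6),
                    "family": np.repeat([f"F{i}" for i in range(24)], n // 24),
                }
            )
            for lr in lr_test_sequence(table):
                if lr.statistic_L > stats.chi2.ppf(0.95, 1):
                    n_exceed += 1
                    break
        assert n_exceed <= 0.10 * reps + 2

    def test_statistics_nonnegative(self, species_long_table):
        for lr in lr_test_sequence(species_long_table):
            assert lr.statistic_L >= 0
            assert 0 <= lr.p_value <= 1


class TestDifferenceCorrelation:
    def test_hand_computed_r(self):
        diffs = pd.DataFrame({"d_ldt": [1, 2, 3], "d_set": [-1, -3, -2]})
        res = difference_correlation(diffs)
        assert res.r == pytest.approx(-0.5)
        assert res.n == 3

    def test_perfect_anticorrelation(self):
        d_ldt = np.array([0.5, -1.0, 2.0, 3.0])
        diffs = pd.DataFrame({"d_ldt": d_ldt, "d_set": -40.0 * d_ldt})
        res = difference_correlation(diffs)
        assert res.r == pytest.approx(-1.0)
        assert res.concordance_fraction == 1.0

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(21)
        x, y = rng.normal(size=50), rng.normal(size=50)
        res = difference_correlation(pd.DataFrame({"d_ldt": x, "d_set": y}))
        xc, yc = x - x.mean(), y - y.mean()
        r_textbook = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        assert res.r == pytest.approx(r_textbook, abs=1e-12)

    def test_zero_variance_rejected(self):
        diffs = pd.DataFrame({"d_ldt": [1.0, 1.0, 1.0], "d_set": [1.0, 2.0, 3.0]})
        with pytest.raises(ValidationError):
            difference_correlation(diffs)

    def test_missing_pairs_dropped(self):
        diffs = pd.DataFrame(
            {"d_ldt": [1.0, 2, 3, 4], "d_set": [-1.0, np.nan, -2, -3]}
        )
        assert difference_correlation(diffs).n == 3


class TestNormalityDiagnostics:
    def test_symmetric_vector_zero_skew(self):
        rep = normality_diagnostics(np.array([1.0, 2.0, 3.0, 4.0]))
        assert rep.skewness == pytest.approx(0.0, abs=1e-12)

    def test_single_large_value_positive_skew(self):
        rep = normality_diagnostics(np.array([0.0, 0, 0, 10]))
        # standard sample skewness of {0,0,0,10}: m3/m2^1.5 = 2/sqrt(3)
        assert rep.skewness == pytest.approx(2 / np.sqrt(3), abs=1e-9)

    def test_gaussian_samples_pass_shapiro_mostly(self):
        rng = np.random.default_rng(3)
        n_pass = sum(
            normality_diagnostics(rng.normal(size=100)).shapiro_p > 0.05
            for _ in range(100)
        )
        assert n_pass >= 90

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError):
            normality_diagnostics(np.full(10, 3.0))


class TestResidualDiagnostics:
    def test_noise_free_data_zero_residuals(self):
        n = 40
        table = pd.DataFrame(
            {
                "pair_id": np.repeat([f"P{i}" for i in range(n)], 2),
                "status": np.tile([0, 1], n),
            }
        )
        group_effect = np.repeat(np.linspace(-2, 2, n), 2)
        table["value"] = 10.0 + 1.5 * table["status"] + group_effect
        fit = paired_lmm(table)
        diag, _ = residual_diagnostics(fit)
        # the residual variance is floored at a tiny positive value, so
        # conditional residuals vanish only to numerical precision
        assert np.abs(diag["residual"]).max() < 1e-4

    def test_mean_residual_near_zero_and_blup_shrinkage(self):
        long = make_paired_long(60, sd_pair=2.0, sd_res=1.0, effect=1.0, seed=8)
        fit = paired_lmm(long)
        diag, blups = residual_diagnostics(fit)
        assert abs(diag["residual"].mean()) < 1e-6 * long["value"].abs().mean() + 1e-8
        # BLUPs shrink toward zero relative to raw group-mean deviations
        beta0, beta1 = fit._fit.beta
        resid_marginal = long["value"] - (beta0 + beta1 * long["status"])
        raw_dev = resid_marginal.groupby(long["pair_id"]).mean()
        for level, blup in blups[0].items():
            assert abs(blup) <= abs(raw_dev[level]) + 1e-10

    def test_plot_written(self, tmp_path):
        long = make_paired_long(20, sd_pair=1.0, sd_res=1.0, effect=1.0, seed=9)
        fit = paired_lmm(long)
        out = tmp_path / "resid.png"
        plot_residuals(fit, str(out))
        assert out.stat().st_size > 0
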