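"""One-way ANOVA engine, LSmean contrasts, Storey q-values, DE screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from synscreen import (
    SimulationConfig,
    differential_screen,
    fit_gene_anova,
    fit_genotype_anova,
    grand_mean_weights,
    lsmean_contrast,
    pfdr_qvalues,
    simulate_expression,
)
from tests.conftest import matrix_from_means


class TestFitGeneAnova:
    def test_identical_groups_give_null_f(self):
        fit = fit_gene_anova({"WT": [1, 2, 3], "A": [1, 2, 3]})
        assert fit.f_stat == 0.0
        assert fit.p_value == 1.0
        assert not fit.degenerate

    def test_zero_residual_variance_flagged(self):
        fit = fit_gene_anova({"WT": [0.0, 0.0], "A": [1.0, 1.0]})
        assert fit.s2 == 0.0
        assert fit.degenerate
        assert np.isnan(fit.p_value)

    def test_three_group_oracle(self):
        """Frozen against scipy.stats.f_oneway on the same data."""
        groups = {"WT": [3, 4, 5], "A": [5, 6, 7], "B": [7, 8, 9]}
        fit = fit_gene_anova(groups)
        f_ref, p_ref = stats.f_oneway(*groups.values())
        assert fit.f_stat == pytest.approx(f_ref)
        assert fit.p_value == pytest.approx(p_ref)
        assert fit.f_stat == pytest.approx(12.0)
        assert fit.p_value == pytest.approx(0.008, abs=5e-4)
        assert fit.df_resid == 6

    def test_all_identical_values(self):
        fit = fit_gene_anova({"WT": [2.0, 2.0], "A": [2.0, 2.0]})
        assert fit.f_stat == 0.0 and fit.p_value == 1.0

    def test_zero_df_flagged(self):
        fit = fit_gene_anova({"WT": [1.0], "A": [2.0]})
        assert fit.degenerate and fit.df_resid == 0

    @settings(max_examples=30, deadline=None)
    @given(
        data=st.lists(
            st.lists(
                st.floats(min_value=-50, max_value=50, allow_nan=False),
                min_size=3,
                max_size=6,
            ),
            min_size=2,
            max_size=5,
        )
    )
    def test_matches_scipy_f_oneway(self, data):
        groups = {f"G{i}": np.round(vals, 3) for i, vals in enumerate(data)}
        fit = fit_gene_anova(groups)
        if fit.degenerate or fit.s2 == 0:
            return  # conventions for degenerate data are fixed elsewhere
        f_ref, p_ref = stats.f_oneway(*groups.values())
        if not np.isfinite(f_ref):
            return  # scipy declines exactly-tied group means
        assert fit.f_stat == pytest.approx(f_ref, rel=1e-9, abs=1e-9)
        assert fit.p_value == pytest.approx(p_ref, rel=1e-9, abs=1e-12)

    def test_vectorised_fit_matches_scalar(self):
        cfg = SimulationConfig(n_genes=25, seed=12)
        matrix, _ = simulate_expression(cfg)
        frame = fit_genotype_anova(matrix)
        groups = matrix.groups()
        for gene in list(matrix.genes)[:10]:
            fit = fit_gene_anova(
                {g: matrix.values.loc[gene, cols].to_numpy() for g, cols in groups.items()},
                gene=gene,
            )
            row = frame.loc[gene]
            assert row["mu_WT"] == pytest.approx(fit.lsmeans["WT"])
            assert row["s2"] == pytest.approx(fit.s2)
            assert row["f_stat"] == pytest.approx(fit.f_stat)
            assert row["p_value"] == pytest.approx(fit.p_value)


class TestLsmeanContrast:
    def test_equal_means_give_zero_estimate_unit_p(self):
        matrix = matrix_from_means({"WT": 9.0, "A": 9.0, "B": 9.0, "AB": 9.0}, jitter=0.2)
        frame = fit_genotype_anova(matrix)
        fit = _fit_from_frame(frame.iloc[0])
        res = lsmean_contrast(fit, {"WT": 1.0, "A": -1.0})
        assert res.estimate == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_se_formula_balanced(self):
        fit = fit_gene_anova(
            {
                "WT": [10.0, 10.2, 9.8],
                "A": [9.0, 9.2, 8.8],
                "B": [9.0, 9.2, 8.8],
                "AB": [8.0, 8.2, 7.8],
            }
        )
        res = lsmean_contrast(fit, {"WT": 1, "A": -1, "B": -1, "AB": 1})
        assert res.se == pytest.approx(np.sqrt(fit.s2 * 4 / 3))
        # the reference arithmetic: s2 = 0.04 gives SE = 0.2 * sqrt(4/3)
        assert np.sqrt(0.04 * 4 / 3) == pytest.approx(0.2309, abs=1e-4)

    def test_grand_mean_contrast_zero_when_flat(self):
        matrix = matrix_from_means({"WT": 9.0, "A": 9.0, "B": 9.0, "AB": 9.0}, jitter=0.2)
        frame = fit_genotype_anova(matrix)
        fit = _fit_from_frame(frame.iloc[0])
        res = lsmean_contrast(fit, grand_mean_weights(["WT", "A", "B", "AB"], "AB"))
        assert res.estimate == pytest.approx(0.0)

    def test_balanced_contrast_equals_difference_of_sample_means(self):
        cfg = SimulationConfig(n_genes=5, seed=13)
        matrix, _ = simulate_expression(cfg)
        groups = matrix.groups()
        gene = matrix.genes[0]
        fit = fit_gene_anova(
            {g: matrix.values.loc[gene, cols].to_numpy() for g, cols in groups.items()}
        )
        res = lsmean_contrast(fit, {"AB": 1.0, "WT": -1.0})
        expected = (
            matrix.values.loc[gene, groups["AB"]].mean()
            - matrix.values.loc[gene, groups["WT"]].mean()
        )
        assert res.estimate == pytest.approx(expected, rel=1e-12)

    def test_degenerate_fit_rejected(self):
        fit = fit_gene_anova({"WT": [0.0, 0.0], "A": [1.0, 1.0]})
        with pytest.raises(ValueError):
            lsmean_contrast(fit, {"WT": 1, "A": -1})


def _fit_from_frame(row: pd.Series):
    from synscreen import GeneFit

    genotypes = [c[3:] for c in row.index if c.startswith("mu_")]
    return GeneFit(
        gene=str(row.name),
        lsmeans={g: row[f"mu_{g}"] for g in genotypes},
        counts={g: int(row[f"n_{g}"]) for g in genotypes},
        s2=row["s2"],
        df_resid=int(row["df_resid"]),
        f_stat=row["f_stat"],
        p_value=row["p_value"],
        degenerate=bool(row["degenerate"]),
    )


class TestPfdrQvalues:
    def test_all_unit_pvalues(self):
        np.testing.assert_array_equal(pfdr_qvalues([1.0] * 5), np.ones(5))

    def test_pi0_one_equals_benjamini_hochberg(self):
        rng = np.random.default_rng(20)
        p = np.concatenate([rng.uniform(size=400), rng.uniform(0, 1e-3, 50)])
        q = pfdr_qvalues(p, pi0=1.0)
        _, bh, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, bh, rtol=1e-12)

    def test_rank_one_bound(self):
        p = np.array([0.001, 0.8, 0.9, 0.95])
        q = pfdr_qvalues(p)
        assert q[0] <= 4 * 1.0 * 0.001  # pi0 <= 1 always

    @settings(max_examples=25, deadline=None)
    @given(
        p=st.lists(
            st.floats(min_value=0, max_value=1, allow_nan=False),
            min_size=1,
            max_size=60,
        )
    )
    def test_monotone_in_p(self, p):
        p = np.asarray(p)
        q = pfdr_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= 0).all() and (q <= 1).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pfdr_qvalues([0.5, 1.2])

    def test_empty_input(self):
        assert pfdr_qvalues([]).size == 0


class TestDifferentialScreen:
    def test_magnitude_filter_excludes_small_shifts(self):
        # one gene confidently shifted by only 0.2: significant but too small
        matrix = matrix_from_means(
            {"WT": 9.0, "A": 9.0, "B": 9.0, "AB": 9.2}, jitter=0.01, n_genes=1
        )
        under, over = differential_screen(matrix, "AB", baseline="wt")
        assert len(under) == 0 and len(over) == 0

    def test_strong_shift_recovered(self):
        matrix = matrix_from_means(
            {"WT": 9.0, "A": 9.0, "B": 9.0, "AB": 8.0}, jitter=0.05, n_genes=1
        )
        under, over = differential_screen(matrix, "AB", baseline="wt")
        assert under.genes == ["gene_1"] and len(over) == 0

    def test_unknown_genotype_rejected(self, factorial_matrix):
        with pytest.raises(ValueError):
            differential_screen(factorial_matrix, "XX")

    def test_screen_invariant_to_gene_order(self):
        cfg = SimulationConfig(n_genes=300, frac_synergistic=0.1, seed=14)
        matrix, _ = simulate_expression(cfg)
        under1, _ = differential_screen(matrix, "AB", baseline="grand_mean")
        shuffled = matrix.copy()
        rng = np.random.default_rng(0)
        perm = rng.permutation(matrix.n_genes)
        shuffled.values = shuffled.values.iloc[perm]
        under2, _ = differential_screen(shuffled, "AB", baseline="grand_mean")
        assert sorted(under1.genes) == sorted(under2.genes)

    def test_matches_independent_ols_oracle(self):
        """Dual route: per-gene OLS contrast + BH must select the same genes."""
        import statsmodels.api as sm

        cfg = SimulationConfig(
            n_genes=150,
            frac_synergistic=0.2,
            synergy_shift=-1.0,
            single_shift_a=-0.6,
            single_shift_b=0.0,
            noise_sd=0.3,
            seed=15,
        )
        matrix, _ = simulate_expression(cfg)
        under, over = differential_screen(
            matrix, "AB", baseline="wt", multiple_testing="bh"
        )

        design = pd.get_dummies(matrix.genotypes, dtype=float)[["WT", "A", "B", "AB"]]
        est, pvals = [], []
        for gene in matrix.genes:
            fit = sm.OLS(matrix.values.loc[gene].to_numpy(), design.to_numpy()).fit()
            tt = fit.t_test([-1.0, 0.0, 0.0, 1.0])
            est.append(float(tt.effect[0]))
            pvals.append(float(tt.pvalue))
        est = np.asarray(est)
        bh = multipletests(pvals, method="fdr_bh")[1]
        oracle_under = set(
            matrix.genes[(bh <= 0.05) & (np.abs(est) > 0.35) & (est < 0)]
        )
        assert set(under.genes) == oracle_under

    def test_false_discoveries_controlled(self):
        """1000 null + 50 strongly shifted genes: every call is a true effect."""
        cfg = SimulationConfig(
            n_genes=1050,
            frac_synergistic=50 / 1050,
            synergy_shift=-1.0,
            single_shift_a=0.0,
            single_shift_b=0.0,
            noise_sd=0.3,
            seed=16,
        )
        matrix, truth = simulate_expression(cfg)
        under, _ = differential_screen(matrix, "AB", baseline="wt")
        members = truth.loc[under.genes]
        n_false = int((~members["is_synergistic"]).sum())
        assert len(under) > 0
        assert n_false <= max(1, int(np.ceil(0.05 * len(under))))


def test_global_null_type_one_error_calibrated():
    """ANOVA p-values are uniform under the no-effect null."""
    cfg = SimulationConfig(
        n_genes=10_000, frac_synergistic=0.0, noise_sd=0.3, n_reps=3, seed=17
    )
    matrix, _ = simulate_expression(cfg)
    fits = fit_genotype_anova(matrix)
    frac = (fits["p_value"] < 0.05).mean()
    band = 3 * np.sqrt(0.05 * 0.95 / 10_000)
    assert abs(frac - 0.05) < band
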