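import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fabrynet import (
    ModerationPrior,
    SimulationConfig,
    simulate_cohort,
    preprocess,
    fit_linear_models,
    estimate_prior,
    apply_moderation,
    ebayes_moderate,
    adjust_benjamini_yekutieli,
    differential_pipeline,
)
from conftest import tiny_matrix, tiny_metadata, tiny_annotation


def make_meta(n, half_fabry=True):
    groups = ["control"] * (n // 2) + ["fabry"] * (n - n // 2)
    return tiny_metadata(groups)


class TestLinearModels:
    def test_metabolite_equal_to_group_indicator_fits_exactly(self):
        meta = make_meta(12)
        g = (meta.table["group"] == "fabry").astype(float).to_numpy()
        mat = tiny_matrix(np.column_stack([g, 2 * g + 1]), scale="log-pareto")
        fits = fit_linear_models(mat, meta)
        assert fits["logFC"].to_numpy() == pytest.approx([1.0, 2.0])
        assert fits["s2"].to_numpy() == pytest.approx([0.0, 0.0], abs=1e-20)
        assert (fits["df"] == 12 - 4).all()

    def test_coefficients_match_direct_normal_equations(self):
        rng = np.random.default_rng(0)
        meta = make_meta(20)
        y = rng.normal(size=(20, 7))
        mat = tiny_matrix(y, scale="log-pareto")
        fits = fit_linear_models(mat, meta)
        # independent oracle: statsmodels OLS per metabolite
        import statsmodels.api as sm

        x = np.column_stack(
            [
                (meta.table["group"] == "fabry").astype(float),
                (meta.table["sex"] == "M").astype(float),
                meta.table["age"] - meta.table["age"].mean(),
            ]
        )
        x = sm.add_constant(x)
        for j in range(7):
            res = sm.OLS(y[:, j], x).fit()
            assert fits["logFC"].iloc[j] == pytest.approx(res.params[1], rel=1e-10)
            assert fits["s2"].iloc[j] == pytest.approx(res.mse_resid, rel=1e-10)

    def test_single_sex_design_reports_collinearity(self):
        meta = make_meta(10)
        meta.table["sex"] = "F"
        mat = tiny_matrix(np.random.default_rng(1).normal(size=(10, 3)), scale="log-pareto")
        with pytest.raises(ValueError, match="sex"):
            fit_linear_models(mat, meta)


class TestEbayes:
    def fits_frame(self, s2, df=10.0, beta=None, v=0.1):
        m = len(s2)
        return pd.DataFrame(
            {
                "logFC": np.zeros(m) if beta is None else beta,
                "s2": s2,
                "df": df,
                "v": v,
            },
            index=[f"m{i}" for i in range(m)],
        )

    def test_equal_variances_give_infinite_prior_df(self):
        fits = self.fits_frame(np.full(50, 0.7))
        prior, out = ebayes_moderate(fits)
        assert np.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(0.7)
        assert out["s2_moderated"].to_numpy() == pytest.approx(0.7)

    def test_zero_prior_df_reduces_to_ordinary_t(self):
        rng = np.random.default_rng(2)
        fits = self.fits_frame(rng.chisquare(10, 40) / 10, beta=rng.normal(size=40))
        out = apply_moderation(fits, ModerationPrior(d0=0.0, s0_sq=1.0))
        t_ols = fits["logFC"] / np.sqrt(fits["s2"] * fits["v"])
        np.testing.assert_allclose(out["t"], t_ols)
        p_ols = 2 * stats.t.sf(np.abs(t_ols), 10)
        np.testing.assert_allclose(out["p"], p_ols)

    def test_infinite_prior_limit_uses_prior_variance_only(self):
        fits = self.fits_frame(np.linspace(0.5, 1.5, 20), beta=np.ones(20))
        out = apply_moderation(fits, ModerationPrior(d0=np.inf, s0_sq=2.0))
        np.testing.assert_allclose(out["t"], 1 / np.sqrt(2.0 * 0.1))

    def test_prior_recovery_on_simulated_variances(self):
        """Known d0=4, s0^2=1: moment estimator recovers d0 within 15% and
        moderated t follows Student t with d0+d df."""
        rng = np.random.default_rng(3)
        m, d, d0, s0 = 5000, 10, 4.0, 1.0
        sigma2 = s0 * d0 / rng.chisquare(d0, m)
        s2 = sigma2 * rng.chisquare(d, m) / d
        v = 0.1
        beta = rng.normal(0, np.sqrt(sigma2 * v))
        fits = self.fits_frame(s2, df=float(d), beta=beta, v=v)
        prior, out = ebayes_moderate(fits)
        assert prior.d0 == pytest.approx(d0, rel=0.15)
        ks = stats.kstest(out["t"], stats.t(d0 + d).cdf)
        assert ks.pvalue > 0.01

    def test_all_zero_variances_rejected(self):
        fits = self.fits_frame(np.zeros(20))
        with pytest.raises(ValueError, match="zero"):
            ebayes_moderate(fits)

    def test_matches_limma_reference_implementation(self, tmp_path):
        """Cross-check moderation against the reference R implementation on a
        small simulated dataset."""
        rng = np.random.default_rng(4)
        n, m = 20, 60
        meta = make_meta(n)
        y = rng.normal(size=(n, m)) * rng.uniform(0.5, 2, size=m)
        mat = tiny_matrix(y, scale="log-pareto")
        fits = fit_linear_models(mat, meta)
        prior, out = ebayes_moderate(fits)

        np.savetxt(tmp_path / "y.csv", y.T, delimiter=",")
        design = np.column_stack(
            [
                np.ones(n),
                (meta.table["group"] == "fabry").astype(float),
                (meta.table["sex"] == "M").astype(float),
                meta.table["age"] - meta.table["age"].mean(),
            ]
        )
        np.savetxt(tmp_path / "design.csv", design, delimiter=",")
        rscript = textwrap.dedent(
            """
            suppressMessages(library(limma))
            y <- as.matrix(read.csv("y.csv", header=FALSE))
            design <- as.matrix(read.csv("design.csv", header=FALSE))
            fit <- lmFit(y, design)
            fit <- eBayes(fit)
            res <- data.frame(d0=fit$df.prior, s02=fit$s2.prior,
                              t=fit$t[,2], p=fit$p.value[,2])
            write.csv(res, "limma_out.csv", row.names=FALSE)
            """
        )
        (tmp_path / "run.R").write_text(rscript)
        subprocess.run(
            ["Rscript", "run.R"], cwd=tmp_path, check=True, capture_output=True
        )
        ref = pd.read_csv(tmp_path / "limma_out.csv")
        assert prior.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-4)
        assert prior.s0_sq == pytest.approx(ref["s02"].iloc[0], rel=1e-4)
        np.testing.assert_allclose(out["t"].to_numpy(), ref["t"].to_numpy(), rtol=1e-6)
        np.testing.assert_allclose(out["p"].to_numpy(), ref["p"].to_numpy(), rtol=1e-6)


class TestBenjaminiYekutieli:
    def test_hand_computed_step_up_example(self):
        adj = adjust_benjamini_yekutieli(np.array([0.01, 0.02, 0.03]))
        np.testing.assert_allclose(adj, [0.055, 0.055, 0.055])

    def test_single_p_value_unchanged(self):
        assert adjust_benjamini_yekutieli(np.array([0.04]))[0] == pytest.approx(0.04)

    def test_adjusted_ge_raw_and_monotone(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=100)
        adj = adjust_benjamini_yekutieli(p)
        assert (adj >= p - 1e-12).all()
        assert (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=50)
        perm = rng.permutation(50)
        adj = adjust_benjamini_yekutieli(p)
        adj_perm = adjust_benjamini_yekutieli(p[perm])
        np.testing.assert_allclose(adj[perm], adj_perm)

    def test_bh_option_is_less_conservative(self):
        p = np.array([0.01, 0.02, 0.03])
        by = adjust_benjamini_yekutieli(p, method="by")
        bh = adjust_benjamini_yekutieli(p, method="bh")
        assert (bh <= by + 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_benjamini_yekutieli(np.array([0.5, 1.2]))


class TestPipeline:
    def test_recovers_planted_shifts_single_seed(self, processed_cohort):
        processed, meta, anno, truth = processed_cohort
        table, summary = differential_pipeline(processed, meta, anno)
        truth_ids = truth.differential_ids()
        sig = set(table.index[table["significant"]])
        sensitivity = len(sig & truth_ids) / len(truth_ids)
        fdr = len(sig - truth_ids) / max(1, len(sig))
        assert sensitivity >= 0.9
        assert fdr <= 0.1

    def test_logfc_signs_match_planted_shifts(self, processed_cohort):
        processed, meta, anno, truth = processed_cohort
        table, _ = differential_pipeline(processed, meta, anno)
        signs = {m: np.sign(s) for m, s in truth.differential}
        agree = [np.sign(table.loc[m, "logFC"]) == signs[m] for m in signs]
        assert np.mean(agree) >= 0.99

    def test_alpha_one_flags_everything(self, processed_cohort):
        processed, meta, anno, _ = processed_cohort
        table, summary = differential_pipeline(processed, meta, anno, alpha=1.0)
        assert summary["n_significant"] == processed.shape[1]

    def test_composition_counts_use_classes(self, processed_cohort):
        processed, meta, anno, _ = processed_cohort
        _, summary = differential_pipeline(processed, meta, anno)
        assert sum(summary["composition"].values()) == summary["n_significant"]
        assert set(summary["composition"]) <= {
            "glycerophospholipid",
            "acylcarnitine",
            "amino_acid",
            "biogenic_amine",
            "sphingomyelin",
            "hexoses",
        }
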