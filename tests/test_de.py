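import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from lncperturb.counts import DesignError, SampleDesign
from lncperturb.de import (
    ModeratedLinearModel,
    build_design,
    moderate_variances,
    trigamma_inverse,
)


def design_sheet(lines=("control", "pertA"), doses=("mock", "low", "high"), reps=3, exp="OE"):
    rows = [
        {
            "sample_id": f"{line}_{dose}_{r}",
            "experiment": exp,
            "perturbation": line,
            "dose": dose,
            "replicate": r,
        }
        for line in lines
        for dose in doses
        for r in range(1, reps + 1)
    ]
    return SampleDesign(pd.DataFrame(rows))


class TestBuildDesign:
    def test_cell_means_construction(self):
        dm = build_design(design_sheet())
        assert dm.matrix.shape == (18, 6)
        assert (dm.matrix.sum(axis=1) == 1).all()  # each sample in exactly one cell
        assert dm.coef_names == [
            "control:mock", "control:low", "control:high",
            "pertA:mock", "pertA:low", "pertA:high",
        ]

    def test_missing_cell_is_error(self):
        d = design_sheet()
        t = d.table[~((d.table.perturbation == "pertA") & (d.table.dose == "high"))]
        with pytest.raises(DesignError, match="empty design cell"):
            build_design(SampleDesign(t.reset_index(drop=True)))

    def test_sample_permutation_gives_same_fits(self):
        d = design_sheet()
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(
            rng.normal(5, 1, size=(30, 18)),
            index=[f"g{i}" for i in range(30)],
            columns=list(d.table["sample_id"]),
        )
        perm = d.table.sample(frac=1, random_state=0).reset_index(drop=True)
        f1 = ModeratedLinearModel.from_design_sheet(expr, d).fit()
        f2 = ModeratedLinearModel.from_design_sheet(expr, SampleDesign(perm)).fit()
        assert np.allclose(f1.coefficients.to_numpy(), f2.coefficients.to_numpy())
        assert np.allclose(f1.residual_var.to_numpy(), f2.residual_var.to_numpy())


class TestFitGenes:
    def test_constant_gene_has_zero_residual_variance(self):
        d = design_sheet()
        expr = pd.DataFrame(
            np.full((12, 18), 3.0), index=[f"g{i}" for i in range(12)],
            columns=list(d.table["sample_id"]),
        )
        fit = ModeratedLinearModel.from_design_sheet(expr, d).fit()
        assert np.allclose(fit.coefficients.to_numpy(), 3.0)
        assert np.allclose(fit.residual_var.to_numpy(), 0.0)

    def test_two_group_closed_form(self):
        """Cell means equal group means; s2 equals the pooled variance."""
        d = design_sheet(lines=("control",), doses=("mock", "low"), reps=3)
        vals = np.array([1.0, 2.0, 6.0, 3.0, 5.0, 10.0])  # mock reps, then low reps
        expr = pd.DataFrame(
            np.tile(vals, (12, 1)), index=[f"g{i}" for i in range(12)],
            columns=list(d.table["sample_id"]),
        )
        fit = ModeratedLinearModel.from_design_sheet(expr, d).fit()
        g = fit.coefficients.iloc[0]
        assert g["control:mock"] == pytest.approx(np.mean(vals[:3]))
        assert g["control:low"] == pytest.approx(np.mean(vals[3:]))
        pooled = (np.var(vals[:3], ddof=1) + np.var(vals[3:], ddof=1)) / 2
        assert fit.residual_var.iloc[0] == pytest.approx(pooled)
        assert fit.df_residual == 4

    def test_insufficient_replication_is_error(self):
        d = design_sheet(reps=1)
        expr = pd.DataFrame(
            np.zeros((5, 6)), index=[f"g{i}" for i in range(5)],
            columns=list(d.table["sample_id"]),
        )
        with pytest.raises(DesignError, match="residual degrees"):
            ModeratedLinearModel.from_design_sheet(expr, d)


class TestModeration:
    def test_trigamma_inverse_roundtrip(self):
        for x in (0.1, 0.5, 2.0, 10.0, 200.0):
            assert trigamma_inverse(float(special.polygamma(1, x))) == pytest.approx(x, rel=1e-6)

    def test_flat_variances_full_shrinkage(self):
        """Equal s2 everywhere: no excess dispersion, so d0 = inf and the
        posterior is the (bias-corrected) trend constant."""
        s2 = np.full(300, 0.37)
        d = 24
        rng = np.random.default_rng(0)
        s20, d0, post = moderate_variances(s2, d, rng.uniform(0, 10, 300))
        assert d0 == np.inf
        correction = np.exp(np.log(d / 2) - special.digamma(d / 2))
        assert np.allclose(post, 0.37 * correction, rtol=1e-6)

    def test_prior_df_recovery(self):
        """s2 drawn as scaled chi-square about a flat trend with d0 = 4:
        trigamma moment matching recovers d0 within 25% at 5,000 genes."""
        rng = np.random.default_rng(3)
        n, d, d0_true = 5000, 10, 4.0
        sigma2 = 0.2 * d0_true / rng.chisquare(d0_true, n)
        s2 = sigma2 * rng.chisquare(d, n) / d
        _, d0, _ = moderate_variances(s2, d, rng.uniform(2, 10, n))
        assert abs(d0 - d0_true) / d0_true < 0.25

    def test_posterior_between_observed_and_trend(self):
        rng = np.random.default_rng(4)
        s2 = 0.1 * rng.chisquare(8, 2000) / 8
        s20, d0, post = moderate_variances(s2, 8, rng.uniform(0, 10, 2000))
        lo = np.minimum(s2, s20)
        hi = np.maximum(s2, s20)
        assert ((post >= lo - 1e-12) & (post <= hi + 1e-12)).all()

    def test_few_genes_falls_back_to_ordinary_t(self):
        d = design_sheet()
        rng = np.random.default_rng(5)
        expr = pd.DataFrame(
            rng.normal(size=(4, 18)), index=list("abcd"),
            columns=list(d.table["sample_id"]),
        )
        with pytest.warns(UserWarning, match="moderation refused"):
            fit = ModeratedLinearModel.from_design_sheet(expr, d).fit()
        assert fit.df_prior == 0.0
        assert np.allclose(fit.s2_post.to_numpy(), fit.residual_var.to_numpy())


class TestContrasts:
    @pytest.fixture()
    def fitted(self):
        d = design_sheet()
        rng = np.random.default_rng(6)
        expr = pd.DataFrame(
            rng.normal(5, 0.5, size=(200, 18)),
            index=[f"g{i}" for i in range(200)],
            columns=list(d.table["sample_id"]),
        )
        return ModeratedLinearModel.from_design_sheet(expr, d).fit()

    def test_zero_contrast_rejected(self, fitted):
        with pytest.raises(DesignError, match="zero contrast"):
            fitted.contrast(np.zeros(6), "null")

    def test_negating_contrast_flips_sign_keeps_p(self, fitted):
        c = fitted.model.design.effect_contrast("pertA", "control", "low")
        a = fitted.contrast(c, "fwd").table
        b = fitted.contrast(-c, "rev").table
        assert np.allclose(a["log2fc"], -b["log2fc"])
        assert np.allclose(a["t"], -b["t"])
        assert np.allclose(a["p_raw"], b["p_raw"])

    def test_effect_vector_sums_to_zero(self, fitted):
        c = fitted.model.design.effect_contrast("pertA", "control", "high")
        assert c.sum() == 0
        assert sorted(c) == [-1, -1, 0, 0, 1, 1]

    def test_effect_antisymmetric_under_line_swap(self, fitted):
        dm = fitted.model.design
        c1 = dm.effect_contrast("pertA", "control", "low")
        c2 = dm.effect_contrast("control", "pertA", "low")
        assert np.allclose(c1, -c2)

    def test_bh_is_monotone_in_raw_p(self, fitted):
        res = fitted.response("control", "high").table.sort_values("p_raw")
        assert (np.diff(res["p_adj"].to_numpy()) >= -1e-15).all()
        assert (res["p_adj"] >= res["p_raw"] - 1e-15).all()

    def test_log2fc_is_contrast_dot_coefficients(self, fitted):
        c = fitted.model.design.response_contrast("pertA", "low")
        res = fitted.contrast(c, "x")
        manual = fitted.coefficients.to_numpy() @ c
        assert np.allclose(res.table["log2fc"].to_numpy(), manual)

    def test_unknown_cell_is_lookup_error(self, fitted):
        with pytest.raises(DesignError, match="no design cell"):
            fitted.response("nosuchline", "low")


class TestNullCalibration:
    def test_effect_pvalues_uniform_under_global_null(self):
        """With no perturbation modulation the contrast-of-contrasts p-values
        are approximately uniform: pooled fraction below 0.05 in [0.03, 0.07]
        and Kolmogorov-Smirnov p > 0.01."""
        from lncperturb.pipeline import run_perturbation_analysis
        from lncperturb.simulate import RnaSeqSimSpec, simulate_counts

        m, d, _ = simulate_counts(RnaSeqSimSpec(perturbation_delta=0.0, seed=11))
        an = run_perturbation_analysis(m, d)
        ps = np.concatenate([r.p_raw.to_numpy() for r in an.effects.values()])
        frac = (ps < 0.05).mean()
        assert 0.03 <= frac <= 0.07
        one = an.effects[("KD", "KDg1", "high")].p_raw.to_numpy()
        assert stats.kstest(one, "uniform").pvalue > 0.01


class TestRecovery:
    def test_planted_isgs_detected_in_control_response(self):
        """>= 95% of planted ISGs (true response log2FC in [1.5, 6], n = 3)
        reach raw p < 0.05 in the control-line response contrast."""
        from lncperturb.pipeline import run_perturbation_analysis
        from lncperturb.simulate import RnaSeqSimSpec, simulate_counts

        m, d, truth = simulate_counts(RnaSeqSimSpec(seed=7))
        an = run_perturbation_analysis(m, d)
        isgs = truth.genes.index[truth.genes.is_isg]
        res = an.responses[("KD", "control", "high")]
        tested = res.table.index.intersection(isgs)
        assert len(tested) >= 90  # ISGs survive the expression filter
        assert (res.p_raw.loc[tested] < 0.05).mean() >= 0.95

    def test_planted_effect_size_recovered(self):
        """Core genes planted with delta = -1 in the KD lines show an effect
        log2FC near -1."""
        from lncperturb.pipeline import run_perturbation_analysis
        from lncperturb.simulate import RnaSeqSimSpec, simulate_counts

        m, d, truth = simulate_counts(RnaSeqSimSpec(seed=7))
        an = run_perturbation_analysis(m, d)
        core = truth.genes.index[truth.genes.is_core]
        eff = an.effects[("KD", "KDg1", "high")].log2fc
        got = eff.loc[eff.index.intersection(core)]
        assert got.mean() == pytest.approx(-1.0, abs=0.25)

    def test_planted_baseline_shift_recovered(self):
        """Genes with a true mock-vs-mock shift rank top by |log2FC| and are
        detected at raw p < 0.05."""
        from lncperturb.counts import normalize
        from lncperturb.simulate import RnaSeqSimSpec, simulate_counts

        spec = RnaSeqSimSpec(n_isg=0, n_core=0, n_kd_only=0, n_oe_only=0, seed=13)
        m, d, _ = simulate_counts(spec)
        # plant a +2 log2 baseline shift in 10 genes of the OE line's samples
        oe = d.table[(d.table.experiment == "OE")]
        pert_cols = oe.loc[oe.perturbation != "control", "sample_id"]
        counts = m.counts.copy()
        shifted = counts.index[:10]
        counts.loc[shifted, pert_cols] = (counts.loc[shifted, pert_cols] * 4).astype(int)
        from lncperturb.counts import CountMatrix

        expr = normalize(CountMatrix(counts), d)
        fit = ModeratedLinearModel.from_design_sheet(expr, d, experiment="OE").fit()
        res = fit.baseline("OE", "control")
        kept = res.table.index.intersection(shifted)
        top = res.table["log2fc"].abs().nlargest(len(kept)).index
        assert set(kept) <= set(top)
        assert (res.p_raw.loc[kept] < 0.05).all()
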