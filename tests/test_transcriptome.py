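"""Moderated t, BH FDR, fold-change conventions, quantile normalization."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from epiconcord import synth, transcriptome
from epiconcord.transcriptome import (
    ModeratedVariancePrior,
    bh_fdr,
    call_degs,
    fit_intensity_prior,
    moderated_t,
    ordinary_t,
    quantile_normalize,
    round_half_away,
    signed_fc_from_log2,
    signed_fold_change,
)


def brute_force_bh(p):
    """Step-up definition evaluated literally: q_i = min_{j>=rank(i)} p_(j)*m/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for pos, idx in enumerate(order):
        candidates = [
            min(p[order[j]] * m / (j + 1), 1.0) for j in range(pos, m)
        ]
        q[idx] = min(candidates)
    return q


def make_groups(n1, n2):
    return pd.Series(
        ["case"] * n1 + ["control"] * n2,
        index=[f"case_{i}" for i in range(n1)]
        + [f"control_{i}" for i in range(n2)],
    )


def random_matrix(n_genes, n1, n2, seed, sd=0.5, trend_slope=0.0, mean=8.0):
    rng = np.random.default_rng(seed)
    base = rng.normal(mean, 1.5, size=n_genes)
    sds = sd * np.exp(0.5 * trend_slope * (base - mean))
    vals = rng.normal(base[:, None], sds[:, None], size=(n_genes, n1 + n2))
    return pd.DataFrame(
        vals,
        index=[f"G{i:05d}" for i in range(n_genes)],
        columns=make_groups(n1, n2).index,
    )


class TestQuantileNormalize:
    def test_identical_columns_fixed_point(self):
        df = pd.DataFrame({"a": [1.0, 3.0, 2.0], "b": [1.0, 3.0, 2.0]})
        pd.testing.assert_frame_equal(quantile_normalize(df), df)

    def test_single_column_unchanged(self):
        df = pd.DataFrame({"a": [5.0, 1.0, 3.0]})
        pd.testing.assert_frame_equal(quantile_normalize(df), df)

    def test_columns_share_sorted_values(self):
        df = random_matrix(200, 3, 3, seed=0)
        out = quantile_normalize(df)
        ref = np.sort(out.iloc[:, 0].to_numpy())
        for col in out.columns:
            np.testing.assert_allclose(np.sort(out[col].to_numpy()), ref, atol=1e-9)

    def test_ranks_preserved_within_columns(self):
        df = random_matrix(50, 2, 2, seed=1)
        out = quantile_normalize(df)
        for col in df.columns:
            assert (
                df[col].rank(method="first") == out[col].rank(method="first")
            ).all()

    def test_missing_values_rejected(self):
        df = pd.DataFrame({"a": [1.0, np.nan], "b": [1.0, 2.0]})
        with pytest.raises(ValueError, match="complete"):
            quantile_normalize(df)


class TestIntensityPrior:
    def test_homoscedastic_prior_recovers_variance(self):
        sd = 0.5
        matrix = random_matrix(2000, 8, 8, seed=2, sd=sd)
        prior = fit_intensity_prior(matrix, make_groups(8, 8))
        assert prior.prior_df > 0
        # flat trend: prior variance close to the true residual variance
        ratio = prior.s0_squared.median() / sd**2
        assert 0.8 < ratio < 1.25

    def test_decreasing_variance_trend_recovered(self):
        matrix = random_matrix(2000, 8, 8, seed=3, sd=0.5, trend_slope=-0.3)
        prior = fit_intensity_prior(matrix, make_groups(8, 8))
        a = prior.mean_intensity
        bulk = (a > a.quantile(0.1)) & (a < a.quantile(0.9))
        corr = np.corrcoef(a[bulk], np.log(prior.s0_squared[bulk]))[0, 1]
        assert corr < -0.9

    def test_too_few_genes_rejected(self):
        matrix = random_matrix(10, 4, 4, seed=4)
        with pytest.raises(ValueError, match="30 genes"):
            fit_intensity_prior(matrix, make_groups(4, 4))

    def test_too_few_samples_rejected(self):
        matrix = random_matrix(100, 2, 3, seed=5)
        with pytest.raises(ValueError, match="3 samples"):
            fit_intensity_prior(matrix, make_groups(2, 3))


class TestModeratedT:
    def test_d0_zero_limit_equals_student_t(self):
        matrix = random_matrix(100, 5, 5, seed=6)
        groups = make_groups(5, 5)
        prior = ModeratedVariancePrior(
            prior_df=0.0,
            s0_squared=pd.Series(1.0, index=matrix.index),
            residual_df=8,
        )
        mod = moderated_t(matrix, groups, prior)
        ols = ordinary_t(matrix, groups)
        np.testing.assert_allclose(
            mod["t_moderated"].to_numpy(), ols["t"].to_numpy(), atol=1e-10
        )
        np.testing.assert_allclose(
            mod["p_value"].to_numpy(), ols["p_value"].to_numpy(), atol=1e-10
        )

    def test_large_d0_limit_uses_prior_only(self):
        matrix = random_matrix(100, 5, 5, seed=7)
        groups = make_groups(5, 5)
        s0 = pd.Series(0.25, index=matrix.index)
        prior = ModeratedVariancePrior(
            prior_df=1e9, s0_squared=s0, residual_df=8
        )
        mod = moderated_t(matrix, groups, prior)
        delta = matrix.filter(like="case_").mean(axis=1) - matrix.filter(
            like="control_"
        ).mean(axis=1)
        expected = delta / np.sqrt(0.25 * (1 / 5 + 1 / 5))
        np.testing.assert_allclose(
            mod["t_moderated"].to_numpy(), expected.to_numpy(), atol=1e-10
        )

    def test_mismatched_design_rejected(self):
        matrix = random_matrix(100, 5, 5, seed=8)
        prior = ModeratedVariancePrior(
            prior_df=2.0, s0_squared=pd.Series(1.0, index=matrix.index),
            residual_df=10,
        )
        with pytest.raises(ValueError, match="residual df"):
            moderated_t(matrix, make_groups(5, 5), prior)

    def test_agrees_with_limma_ranking(self, tmp_path):
        """Independent cross-check against limma's empirical-Bayes t."""
        cfg = synth.SimulationConfig(
            n_probes=600, n_genes=300, n_case=6, n_ctrl=6, seed=11
        )
        ann = synth.simulate_annotation(cfg)
        _, truth = synth.simulate_methylation(cfg, ann)
        matrix = synth.simulate_expression(cfg, truth)
        sheet = cfg.sample_sheet()
        groups = pd.Series(
            sheet["group"].to_numpy(), index=sheet["sample_id"].to_numpy()
        )
        prior = fit_intensity_prior(matrix, groups)
        ours = moderated_t(matrix, groups, prior)

        expr_path = tmp_path / "expr.tsv"
        matrix.to_csv(expr_path, sep="\t")
        script = textwrap.dedent(
            f"""
            suppressMessages(library(limma))
            x <- as.matrix(read.delim("{expr_path}", row.names=1))
            design <- cbind(Intercept=1, Case=rep(c(1,0), c(6,6)))
            fit <- eBayes(lmFit(x, design), trend=TRUE)
            out <- data.frame(gene=rownames(x), t=fit$t[,"Case"])
            write.table(out, "{tmp_path / 'limma.tsv'}", sep="\\t",
                        row.names=FALSE, quote=FALSE)
            """
        )
        r_file = tmp_path / "limma.R"
        r_file.write_text(script)
        proc = subprocess.run(
            ["Rscript", str(r_file)], capture_output=True, text=True
        )
        assert proc.returncode == 0, proc.stderr
        limma = pd.read_csv(tmp_path / "limma.tsv", sep="\t").set_index("gene")
        joint = ours.join(limma, how="inner")
        corr = np.corrcoef(joint["t_moderated"], joint["t"])[0, 1]
        assert corr > 0.99
        top_ours = set(joint["t_moderated"].abs().nlargest(20).index)
        top_limma = set(joint["t"].abs().nlargest(20).index)
        assert len(top_ours & top_limma) >= 15


class TestBhFdr:
    def test_worked_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.04]), [0.02, 0.04])

    def test_single_and_tied_values(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=20
        )
    )
    def test_matches_brute_force_step_up(self, p):
        np.testing.assert_allclose(bh_fdr(p), brute_force_bh(p), atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestFoldChange:
    def test_published_rtpcr_examples(self):
        assert round_half_away(signed_fold_change(2.06, 1.10)) == pytest.approx(1.9)
        assert round_half_away(signed_fold_change(0.35, 1.38)) == pytest.approx(-3.9)
        assert signed_fold_change(2.0, 2.0) == 1.0

    @given(
        st.floats(min_value=0.01, max_value=100.0),
        st.floats(min_value=0.01, max_value=100.0),
    )
    def test_antisymmetry(self, a, b):
        fab = signed_fold_change(a, b)
        fba = signed_fold_change(b, a)
        if a != b:
            assert fab == pytest.approx(-fba, rel=1e-9)
        assert abs(fab) >= 1.0

    def test_log2_consistency(self):
        lfc = np.array([-2.0, 0.0, 1.0])
        np.testing.assert_allclose(signed_fc_from_log2(lfc), [-4.0, 1.0, 2.0])

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            signed_fold_change(0.0, 1.0)


class TestDegCalling:
    def test_all_null_empty(self):
        res = pd.DataFrame(
            {"p_value": [1.0, 1.0], "q_value": [1.0, 1.0], "log2fc": [0.1, -0.1]},
            index=["a", "b"],
        )
        assert len(call_degs(res)) == 0

    def test_threshold_monotone(self, pipeline_run):
        strict = call_degs(pipeline_run["de_results"], fdr=0.05)
        loose = call_degs(pipeline_run["de_results"], fdr=0.10)
        assert set(strict.index) <= set(loose.index)

    def test_sensitivity_on_planted_truth(self, pipeline_run):
        truth = pipeline_run["truth"]
        planted = set(
            truth.gene_de_direction[truth.gene_de_direction != "none"].index
        )
        called = set(pipeline_run["degs"].index)
        assert len(called & planted) / len(planted) >= 0.8

    def test_fdr_control_over_replicates(self):
        """Observed false-discovery proportion at q<=0.10, averaged over
        50 seeded replicates with 20% planted effects, stays below 0.15."""
        fdps = []
        for seed in range(50):
            matrix = random_matrix(300, 6, 6, seed=seed, sd=0.5)
            planted = matrix.index[:60]
            matrix.loc[planted, matrix.columns[:6]] += 1.0
            groups = make_groups(6, 6)
            prior = fit_intensity_prior(matrix, groups)
            degs = call_degs(moderated_t(matrix, groups, prior), fdr=0.10)
            if len(degs):
                fdps.append(
                    len(set(degs.index) - set(planted)) / len(degs)
                )
        assert np.mean(fdps) <= 0.15
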