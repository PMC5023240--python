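import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from evomex import contrasts
from tests.conftest import build_matrix


def _two_group_matrix(n=60, delta_scale=1.0, noise=0.3, seed=0, probes_per_gene=1):
    rng = np.random.default_rng(seed)
    base = rng.normal(8, 1.5, n)
    delta = rng.normal(0, delta_scale, n)
    return build_matrix(
        {"WT": np.zeros(n), "EM": delta},
        base,
        noise_sd=noise,
        seed=seed + 1,
        probes_per_gene=probes_per_gene,
    )


class TestModeratedT:
    def test_no_moderation_equals_ordinary_t(self):
        m = _two_group_matrix(seed=3)
        out = contrasts.moderated_contrast(m, "WT", "EM", prior_df=0)
        a = m.group_values("WT").to_numpy()
        b = m.group_values("EM").to_numpy()
        t_ref, p_ref = stats.ttest_ind(b, a, axis=1, equal_var=True)
        np.testing.assert_allclose(out["t"], t_ref, rtol=1e-10)
        np.testing.assert_allclose(out["p"], p_ref, rtol=1e-10)

    def test_infinite_prior_shares_one_variance(self):
        m = _two_group_matrix(seed=4)
        out = contrasts.moderated_contrast(m, "WT", "EM", prior_df=np.inf)
        assert out["s2_post"].nunique() == 1
        s0 = out["s2_post"].iloc[0]
        expected_t = out["effect"] / np.sqrt(s0 * (2 / 3))
        np.testing.assert_allclose(out["t"], expected_t, rtol=1e-10)

    def test_group_swap_negates_effect_keeps_p(self):
        m = _two_group_matrix(seed=5)
        fwd = contrasts.moderated_contrast(m, "WT", "EM")
        rev = contrasts.moderated_contrast(m, "EM", "WT")
        np.testing.assert_allclose(fwd["effect"], -rev["effect"], rtol=1e-12)
        np.testing.assert_allclose(fwd["t"], -rev["t"], rtol=1e-12)
        np.testing.assert_allclose(fwd["p"], rev["p"], rtol=1e-12)

    def test_all_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            contrasts.squeeze_variances(np.zeros(10), 4.0)

    def test_null_type_i_error_nominal(self):
        m = _two_group_matrix(n=4000, delta_scale=0.0, noise=0.25, seed=6)
        out = contrasts.moderated_contrast(m, "WT", "EM")
        rate = (out["p"] < 0.05).mean()
        half_width = 2.576 * np.sqrt(0.05 * 0.95 / len(out))
        assert abs(rate - 0.05) <= half_width

    def test_matches_limma_ebayes(self, tmp_path):
        """Dual-route check against the reference empirical-Bayes
        implementation on a heteroscedastic fixture."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable; limma cross-check cannot run")
        rng = np.random.default_rng(11)
        n = 150
        sd = np.sqrt(0.04 * rng.chisquare(6, n) / 6)
        base = rng.normal(8, 1.5, n)
        delta = rng.normal(0, 1.0, n)
        cols = {}
        for g, offset in (("WT", 0.0), ("EM", delta)):
            for r in range(3):
                cols[f"{g}_{r+1}"] = base + offset + rng.normal(0, sd)
        values = pd.DataFrame(cols, index=[f"g{i}" for i in range(n)])
        matrix_path = tmp_path / "m.tsv"
        values.to_csv(matrix_path, sep="\t")
        script = tmp_path / "check.R"
        script.write_text(
            "suppressMessages(library(limma))\n"
            f"x <- as.matrix(read.delim('{matrix_path}', row.names=1))\n"
            "groups <- factor(rep(c('WT','EM'), each=3), levels=c('WT','EM'))\n"
            "fit <- eBayes(lmFit(x, model.matrix(~groups)))\n"
            "out <- data.frame(t=fit$t[,2], p=fit$p.value[,2])\n"
            f"write.table(out, '{tmp_path / 'limma.tsv'}', sep='\\t', quote=FALSE)\n"
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "limma.tsv", sep="\t", index_col=0)

        samples = pd.DataFrame(
            {"group": ["WT"] * 3 + ["EM"] * 3, "lineage": ""}, index=values.columns
        )
        from evomex.io import ExpressionMatrix

        m = ExpressionMatrix(
            values=values,
            samples=samples,
            probe_map=pd.Series(values.index, index=values.index),
        )
        mine = contrasts.moderated_contrast(m, "WT", "EM")
        np.testing.assert_allclose(mine["t"], ref["t"], rtol=1e-6)
        np.testing.assert_allclose(mine["p"], ref["p"], rtol=1e-6)


class TestAssimilation:
    def test_single_probe_identity(self):
        m = _two_group_matrix(n=20, seed=7)
        probe = contrasts.moderated_contrast(m, "WT", "EM")
        locus = contrasts.assimilate_probes(probe, m.probe_map)
        assert (locus["n_probes"] == 1).all()
        np.testing.assert_allclose(
            locus["effect"].sort_index(),
            probe["effect"].rename(m.probe_map).sort_index(),
        )
        np.testing.assert_allclose(
            locus["p"].sort_index(), probe["p"].rename(m.probe_map).sort_index()
        )

    def test_median_effect(self):
        probe_stats = pd.DataFrame(
            {"effect": [2.0, 2.0, 2.0], "t": [3.0, 3.1, 2.9], "p": [0.01, 0.01, 0.02],
             "df_total": [4.0, 4.0, 4.0]},
            index=["a", "b", "c"],
        )
        pm = pd.Series(["L", "L", "L"], index=["a", "b", "c"])
        out = contrasts.assimilate_probes(probe_stats, pm)
        assert out.loc["L", "effect"] == 2.0
        assert out.loc["L", "n_probes"] == 3

    def test_replicated_probe_stouffer_scaling(self):
        # k identical probes: combined z must equal sqrt(k) * single-probe z
        z1 = stats.norm.isf(0.02 / 2)
        probe_stats = pd.DataFrame(
            {"effect": [1.0] * 4, "t": [2.5] * 4, "p": [0.02] * 4, "df_total": [4.0] * 4},
            index=list("abcd"),
        )
        pm = pd.Series(["L"] * 4, index=list("abcd"))
        out = contrasts.assimilate_probes(probe_stats, pm)
        assert out.loc["L", "z"] == pytest.approx(2 * z1)

    def test_conflicting_probes_agree_with_mean_intensity_oracle(self):
        # probes of one locus disagreeing in sign: the assimilated call must
        # agree in direction with a direct test on per-sample mean intensity
        m = _two_group_matrix(n=12, delta_scale=1.5, noise=0.2, seed=8, probes_per_gene=3)
        probe = contrasts.moderated_contrast(m, "WT", "EM", prior_df=0)
        locus = contrasts.assimilate_probes(probe, m.probe_map)
        mean_by_locus = m.values.groupby(m.probe_map).mean()
        wt = mean_by_locus[m.group_columns("WT")].to_numpy()
        em = mean_by_locus[m.group_columns("EM")].to_numpy()
        t_oracle, _ = stats.ttest_ind(em, wt, axis=1)
        oracle = pd.Series(t_oracle, index=mean_by_locus.index)
        strong = oracle.abs() > 3
        assert strong.any()
        assert (
            np.sign(locus.loc[strong[strong].index, "z"]) == np.sign(oracle[strong])
        ).all()


class TestAdjustPvalues:
    def test_bh_step_up_hand_example(self):
        p = [0.005, 0.009, 0.05, 0.1, 0.2]
        expected = [0.0225, 0.0225, 0.05 * 5 / 3, 0.125, 0.2]
        np.testing.assert_allclose(contrasts.adjust_pvalues(p), expected)

    def test_equal_and_single(self):
        np.testing.assert_allclose(
            contrasts.adjust_pvalues([0.03, 0.03, 0.03]), [0.03, 0.03, 0.03]
        )
        np.testing.assert_allclose(contrasts.adjust_pvalues([0.07]), [0.07])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            contrasts.adjust_pvalues([0.1, 1.7])

    def test_q_never_below_p(self):
        rng = np.random.default_rng(12)
        p = rng.random(200)
        q = contrasts.adjust_pvalues(p)
        assert (q >= p - 1e-12).all()


class TestContrastTable:
    def test_tidy_output_structure(self, expression_2000):
        matrix, _ = expression_2000
        table = contrasts.contrast_table(matrix)
        assert set(table["contrast"]) == {contrasts.ACCLIMATION, contrasts.ADAPTATION}
        n_loci = matrix.probe_map.nunique()
        assert len(table) == 2 * n_loci  # one acclimation + one lineage
        assert (table["q"] >= table["p"] - 1e-12).all()
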