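import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spongenet.diffexpr import (benjamini_hochberg, moderated_t, results_table,
                                select_top)
from spongenet.io_core import SpongenetError

from conftest import make_expr


class TestModeratedT:
    def test_identical_groups_give_zero_logfc_and_p_one(self):
        mat = np.vstack([np.tile([1.0, 2.0, 3.0], 2) for _ in range(5)])
        mat += np.random.default_rng(0).normal(size=mat.shape) * 0  # constant
        mat[0] = [4, 5, 6, 4, 5, 6]
        em = make_expr(mat, groups=["case"] * 3 + ["control"] * 3)
        res = {r.gene_id: r for r in moderated_t(em)}
        assert res["g000"].log_fc == pytest.approx(0.0)
        assert res["g000"].p_value == pytest.approx(1.0)

    def test_equal_variance_genes_reduce_to_ordinary_t(self):
        """With homogeneous residual variance the moment estimate of the
        prior df fails and the ordinary pooled two-sample t is returned."""
        rng = np.random.default_rng(5)
        n1 = n2 = 10
        base = rng.normal(size=n1 + n2)
        mat = np.vstack([base[rng.permutation(n1 + n2)] for _ in range(50)])
        em = make_expr(mat, groups=["case"] * n1 + ["control"] * n2)
        res = moderated_t(em)
        for r in res:
            x = em.data.loc[r.gene_id, em.samples_in_group("case")]
            y = em.data.loc[r.gene_id, em.samples_in_group("control")]
            t_ref, p_ref = stats.ttest_ind(x, y)
            assert r.t_stat == pytest.approx(t_ref, abs=1e-10)
            assert r.p_value == pytest.approx(p_ref, abs=1e-10)

    def test_matches_limma_ebayes_on_heterogeneous_variances(self, tmp_path):
        """Independent oracle: Bioconductor limma on the same matrix."""
        rng = np.random.default_rng(42)
        G, n1, n2 = 60, 8, 7
        sds = rng.uniform(0.5, 3.0, G)
        X = rng.normal(0, 1, (G, n1 + n2)) * sds[:, None]
        X[:10, :n1] += 1.5
        em = make_expr(X, groups=["case"] * n1 + ["control"] * n2)
        res = {r.gene_id: r for r in moderated_t(em)}
        expr_path = tmp_path / "expr.tsv"
        em.data.to_csv(expr_path, sep="\t")
        script = tmp_path / "limma.R"
        script.write_text(f"""
suppressMessages(library(limma))
x <- as.matrix(read.delim("{expr_path}", row.names=1))
design <- cbind(Intercept=1, case=c(rep(1,{n1}), rep(0,{n2})))
fit <- eBayes(lmFit(x, design))
out <- data.frame(id=rownames(x), t=fit$t[,"case"], p=fit$p.value[,"case"])
write.table(out, "{tmp_path}/limma_out.tsv", sep="\\t", row.names=FALSE, quote=FALSE)
""")
        subprocess.run(["Rscript", str(script)], check=True,
                       capture_output=True)
        ref = pd.read_csv(tmp_path / "limma_out.tsv", sep="\t", index_col=0)
        for gid in em.gene_ids:
            assert res[gid].t_stat == pytest.approx(ref.loc[gid, "t"], abs=1e-8)
            assert res[gid].p_value == pytest.approx(ref.loc[gid, "p"], abs=1e-8)

    def test_group_with_one_sample_is_hard_error(self):
        em = make_expr(np.ones((3, 3)), groups=["case", "control", "control"])
        with pytest.raises(SpongenetError):
            moderated_t(em)

    def test_zero_variance_gene_flagged_not_infinite(self):
        rng = np.random.default_rng(1)
        mat = rng.normal(size=(10, 8))
        mat[0] = 1.0
        em = make_expr(mat, groups=["case"] * 4 + ["control"] * 4)
        res = {r.gene_id: r for r in moderated_t(em)}
        assert res["g000"].zero_variance
        assert np.isfinite(res["g000"].t_stat)

    def test_null_calibration_of_raw_p_values(self):
        """Global null: ~5% of genes at p < 0.05 (within +-0.02)."""
        rng = np.random.default_rng(11)
        mat = rng.normal(size=(1000, 60))
        em = make_expr(mat, groups=["case"] * 30 + ["control"] * 30)
        frac = np.mean([r.p_value < 0.05 for r in moderated_t(em)])
        assert 0.03 <= frac <= 0.07

    def test_ranks_are_a_permutation(self):
        rng = np.random.default_rng(2)
        em = make_expr(rng.normal(size=(30, 12)),
                       groups=["case"] * 6 + ["control"] * 6)
        res = moderated_t(em)
        assert sorted(r.rank for r in res) == list(range(1, 31))
        assert results_table(res)["rank"].tolist() == list(range(1, 31))


class TestBenjaminiHochberg:
    def test_hand_worked_step_up(self):
        adj = benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_monotone_and_order_invariant(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=200)
        adj = benjamini_hochberg(p)
        assert np.all(adj >= p)
        assert np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)
        perm = rng.permutation(200)
        np.testing.assert_allclose(benjamini_hochberg(p[perm]), adj[perm])


class TestSelectTop:
    def _results(self, adj_ps, log_fcs=None):
        from spongenet.diffexpr import DifferentialResult
        log_fcs = log_fcs or [1.0] * len(adj_ps)
        return [DifferentialResult(f"g{i}", log_fcs[i], 0.0, adj_ps[i],
                                   adj_ps[i], i + 1)
                for i in range(len(adj_ps))]

    def test_smallest_adj_p_selected(self):
        res = self._results([0.5, 0.1, 0.3, 0.2, 0.9, 0.05, 0.6, 0.7, 0.8, 0.4])
        assert select_top(res, 3) == ["g5", "g1", "g3"]

    def test_tie_broken_by_absolute_logfc(self):
        res = self._results([0.1, 0.1], log_fcs=[1.0, -2.0])
        assert select_top(res, 1) == ["g1"]

    def test_select_all_returns_rank_order(self):
        res = self._results([0.3, 0.1, 0.2])
        assert select_top(res, 3) == ["g1", "g2", "g0"]

    def test_requesting_more_than_available_errors(self):
        with pytest.raises(SpongenetError, match="3"):
            select_top(self._results([0.1, 0.2, 0.3]), 4)
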