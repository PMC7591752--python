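import numpy as np
import pytest

from spongenet.io_core import SpongenetError
from spongenet.sponge_network import sensitivity_correlation
from spongenet.synthetic_data import (PRESETS, SyntheticConfig,
                                      cutoff_scan_dataset, generate,
                                      write_dataset)


class TestDeterminism:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = SyntheticConfig(n_mirna=40, n_lncrna=10, n_mrna=20,
                              m_case=15, m_control=15, n_sponge_pairs=2,
                              shared_mirnas_per_pair=4)
        p1 = write_dataset(generate(cfg, 7), tmp_path / "a")
        p2 = write_dataset(generate(cfg, 7), tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_different_seed_differs(self):
        cfg = SyntheticConfig(n_mirna=30, n_lncrna=5, n_mrna=10,
                              m_case=12, m_control=12, n_sponge_pairs=1,
                              shared_mirnas_per_pair=3)
        a = generate(cfg, 1).mirna.values
        b = generate(cfg, 2).mirna.values
        assert not np.array_equal(a, b)


class TestPlantedStructure:
    def test_all_planted_ids_exist_in_matrices(self, small_dataset):
        ds = small_dataset
        genes = set(ds.mirna.gene_ids) | set(ds.lncrna.gene_ids) \
            | set(ds.mrna.gene_ids)
        for m, t, _ in ds.truth.regulation.pairs:
            assert m in genes and t in genes
        for a, b, _ in ds.truth.sponge_pairs:
            assert a in genes and b in genes
        for g in ds.truth.differential:
            assert g in genes

    def test_beta_zero_leaves_null_correlations(self):
        cfg = SyntheticConfig(n_mirna=30, n_lncrna=10, n_mrna=30,
                              m_case=100, m_control=100, beta=0.0,
                              n_sponge_pairs=0, n_diff_per_class=0)
        ds = generate(cfg, 3)
        m = ds.mirna.n_samples
        Z = ds.mirna.values
        T = ds.mrna.values
        Zc = (Z - Z.mean(1, keepdims=True)) / Z.std(1, keepdims=True)
        Tc = (T - T.mean(1, keepdims=True)) / T.std(1, keepdims=True)
        corr = Zc @ Tc.T / m
        # null-correlation bound: |r| <= 3/sqrt(m) for virtually all pairs
        assert np.quantile(np.abs(corr), 0.999) <= 3 / np.sqrt(m)

    def test_planted_pair_population_sc_recovered(self):
        cfg = SyntheticConfig(n_mirna=10, n_lncrna=4, n_mrna=4,
                              m_case=1000, m_control=1000, n_sponge_pairs=1,
                              shared_mirnas_per_pair=1, sponge_sc=0.5,
                              n_diff_per_class=0, decoy_ratio=0.0)
        ds = generate(cfg, 11)
        (a, b, sc_pop) = ds.truth.sponge_pairs[0]
        rows = {g: ds.lncrna.values[i] for i, g in enumerate(ds.lncrna.gene_ids)}
        rows |= {g: ds.mrna.values[i] for i, g in enumerate(ds.mrna.gene_ids)}
        regs = ds.truth.regulation.regulators_of()
        shared = sorted(regs[a] & regs[b])
        Z = np.vstack([ds.mirna.values[ds.mirna.gene_ids.index(r)]
                       for r in shared])
        rho, part, sc, _ = sensitivity_correlation(rows[a], rows[b], Z)
        assert sc == pytest.approx(sc_pop, abs=0.05)

    def test_planted_regulation_correlation_matches_loading(self):
        cfg = SyntheticConfig(n_mirna=20, n_lncrna=5, n_mrna=20,
                              m_case=1000, m_control=1000, beta=-0.4,
                              n_sponge_pairs=0, n_diff_per_class=0)
        ds = generate(cfg, 13)
        errs = []
        for m, t, c in ds.truth.regulation.pairs:
            z = ds.mirna.values[ds.mirna.gene_ids.index(m)]
            em = ds.lncrna if c == "lncRNA" else ds.mrna
            x = em.values[em.gene_ids.index(t)]
            errs.append(abs(np.corrcoef(z, x)[0, 1] - cfg.beta))
        assert max(errs) < 0.05

    def test_infeasible_sponge_sc_raises_with_bound(self):
        cfg = SyntheticConfig(n_mirna=30, n_lncrna=6, n_mrna=6,
                              m_case=15, m_control=15, n_sponge_pairs=1,
                              sponge_sc=0.99, shared_mirnas_per_pair=3)
        with pytest.raises(SpongenetError, match="attainable"):
            generate(cfg, 0)

    def test_decoy_ratio_respected(self, small_dataset):
        ds = small_dataset
        truth = len(ds.truth.regulation)
        total = len(ds.putative_union())
        assert total == pytest.approx(11 * truth, rel=0.01)

    def test_differential_genes_shifted_in_cases(self, small_dataset):
        ds = small_dataset
        for g, delta in list(ds.truth.differential.items())[:5]:
            for em in (ds.mirna, ds.lncrna, ds.mrna):
                if g in em.data.index:
                    case = em.data.loc[g, em.samples_in_group("case")].mean()
                    ctrl = em.data.loc[g, em.samples_in_group("control")].mean()
                    assert case - ctrl == pytest.approx(delta, abs=0.35)


class TestScanFixture:
    def test_backbone_histogram_is_collinear(self):
        ds = cutoff_scan_dataset(seed=2, m_samples=500)
        strong = [(a, b) for a, b, sc in ds.truth.sponge_pairs if sc >= 0.2]
        from spongenet.graph_topology import degree_histogram
        assert degree_histogram(strong) == {1: 16, 2: 4, 4: 1}
        assert ds.truth.optimal_sc_cutoff == 0.25
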