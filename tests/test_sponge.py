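import numpy as np
import pytest

from spongenet.io_core import InteractionSet, SpongenetError
from spongenet.sponge_network import (infer_sponge_network, partial_correlation,
                                      sensitivity_correlation,
                                      shared_mirna_test)

import oracles
from conftest import make_expr


class TestSharedMirnaTest:
    def test_full_overlap_exact_value(self):
        n, p = shared_mirna_test(set("abcde"), set("abcde"), 10)
        assert n == 5
        assert p == pytest.approx(1 / 252, rel=1e-12)

    def test_single_overlap_small_universe(self):
        n, p = shared_mirna_test({"a", "b"}, {"a", "c"}, 4)
        assert n == 1
        assert p == pytest.approx(5 / 6, rel=1e-12)

    def test_zero_overlap_gives_p_one(self):
        _, p = shared_mirna_test({"a"}, {"b"}, 10)
        assert p == pytest.approx(1.0)

    def test_empty_regulator_set(self):
        assert shared_mirna_test(set(), {"a"}, 5) == (0, 1.0)

    def test_matches_exhaustive_enumeration_small_universes(self):
        rng = np.random.default_rng(17)
        universe = [f"u{i}" for i in range(20)]
        for _ in range(40):
            m = int(rng.integers(4, 21))
            k1 = int(rng.integers(1, m + 1))
            k2 = int(rng.integers(1, m + 1))
            r1 = set(rng.choice(universe[:m], size=k1, replace=False))
            r2 = set(rng.choice(universe[:m], size=k2, replace=False))
            n, p = shared_mirna_test(r1, r2, m)
            assert p == pytest.approx(
                oracles.hypergeom_tail_brute(n, m, k1, k2), rel=1e-10)


class TestSensitivityCorrelation:
    def test_first_order_closed_form_exact(self):
        """Sample correlations forced to (0.8, 0.6, 0.6): the partial is
        (0.8 - 0.36) / (1 - 0.36) = 0.6875, so SC = 0.1125."""
        R = np.array([[1.0, 0.8, 0.6], [0.8, 1.0, 0.6], [0.6, 0.6, 1.0]])
        D = oracles.exact_sample_correlation_data(R, m=200, seed=0)
        rho, part, sc, _ = sensitivity_correlation(D[:, 0], D[:, 1],
                                                   D[:, 2][None, :])
        assert rho == pytest.approx(0.8, abs=1e-12)
        assert part == pytest.approx(0.6875, abs=1e-12)
        assert sc == pytest.approx(0.1125, abs=1e-12)

    def test_empty_conditioning_set_gives_sc_zero(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=(2, 50))
        rho, part, sc, _ = sensitivity_correlation(x, y, None)
        assert sc == 0.0
        assert rho == part

    def test_shared_factor_model_population_sc(self):
        """x = z + e1, y = z + e2: rho ~ 0.5, partial ~ 0, SC ~ 0.5."""
        rng = np.random.default_rng(42)
        m = 2000
        z = rng.normal(size=m)
        x = z + rng.normal(size=m)
        y = z + rng.normal(size=m)
        rho, part, sc, _ = sensitivity_correlation(x, y, z[None, :])
        assert rho == pytest.approx(0.5, abs=0.05)
        assert part == pytest.approx(0.0, abs=0.05)
        assert sc == pytest.approx(0.5, abs=0.05)

    def test_precision_matrix_agrees_with_residual_regression(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            data = rng.normal(size=(5, 80))
            x, y, Z = data[0], data[1], data[2:]
            got = partial_correlation(x, y, Z)
            # residual-regression definition
            Q = np.column_stack([np.ones(80), Z.T])
            rx = x - Q @ np.linalg.lstsq(Q, x, rcond=None)[0]
            ry = y - Q @ np.linalg.lstsq(Q, y, rcond=None)[0]
            ref = np.corrcoef(rx, ry)[0, 1]
            assert got == pytest.approx(ref, abs=1e-10)

    def test_constant_vector_is_hard_error(self):
        with pytest.raises(SpongenetError):
            sensitivity_correlation(np.ones(10), np.arange(10.0), None)

    def test_oversized_conditioning_truncated_and_flagged(self):
        rng = np.random.default_rng(3)
        m = 12
        x, y = rng.normal(size=(2, m))
        Z = rng.normal(size=(m + 5, m))
        *_, truncated = sensitivity_correlation(x, y, Z)
        assert truncated


class TestInferSpongeNetwork:
    def _tiny(self, rho_sign=1.0, seed=0):
        rng = np.random.default_rng(seed)
        m = 300
        z = rng.normal(size=(3, m))
        shared = z.mean(axis=0) * np.sqrt(3)
        x = -0.7 * shared / 1.0 + 0.7 * rng.normal(size=m)
        y = rho_sign * (-0.7) * shared + 0.7 * rng.normal(size=m)
        lnc = make_expr(np.vstack([x, y]), "lncRNA", ["L1", "L2"])
        mirna = make_expr(np.vstack([z, rng.normal(size=(7, m))]), "miRNA",
                          [f"mi{i}" for i in range(10)])
        targets = InteractionSet({(f"mi{i}", g, "lncRNA")
                                  for i in range(3) for g in ("L1", "L2")})
        return lnc, mirna, targets

    def test_no_shared_regulators_gives_empty_network(self):
        lnc, mirna, _ = self._tiny()
        targets = InteractionSet({("mi0", "L1", "lncRNA"),
                                  ("mi1", "L2", "lncRNA")})
        edges = infer_sponge_network({"lncRNA": lnc}, mirna, targets)
        assert edges == []

    def test_planted_pair_detected_with_sc_identity(self):
        lnc, mirna, targets = self._tiny()
        edges = infer_sponge_network({"lncRNA": lnc}, mirna, targets,
                                     sc_min=0.25)
        assert len(edges) == 1
        e = edges[0]
        assert (e.rna_i, e.rna_j) == ("L1", "L2")
        assert e.pair_class == "lncRNA-lncRNA"
        assert e.sc == pytest.approx(e.rho_ij - e.rho_ij_given_n, abs=1e-12)

    def test_negative_correlation_excluded(self):
        lnc, mirna, targets = self._tiny(rho_sign=-1.0)
        edges = infer_sponge_network({"lncRNA": lnc}, mirna, targets,
                                     sc_min=-10, p_corr_max=0.05)
        assert edges == []

    def test_edge_count_monotone_in_thresholds(self, small_dataset):
        ds = small_dataset
        counts = []
        for sc_min in (0.0, 0.15, 0.3, 0.45):
            edges = infer_sponge_network(ds.expr_by_class(), ds.mirna,
                                         ds.putative_union(), sc_min=sc_min)
            counts.append(len(edges))
        assert counts == sorted(counts, reverse=True)
        tight = infer_sponge_network(ds.expr_by_class(), ds.mirna,
                                     ds.putative_union(), p_share_max=0.001,
                                     sc_min=0.0)
        assert len(tight) <= counts[0]

    def test_planted_recovery_on_small_preset(self, small_dataset):
        ds = small_dataset
        edges = infer_sponge_network(ds.expr_by_class(), ds.mirna,
                                     ds.putative_union(), sc_min=0.25)
        truth = {(a, b) for a, b, _ in ds.truth.sponge_pairs}
        found = {(e.rna_i, e.rna_j) for e in edges}
        tp = len(truth & found)
        assert tp / len(truth) >= 0.8                 # recall
        assert tp / max(len(found), 1) >= 0.8         # precision
        for e in edges:
            assert -1 <= e.rho_ij_given_n <= 1
            assert e.n_shared >= 1
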