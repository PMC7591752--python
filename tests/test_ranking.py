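import numpy as np
import pytest

from spongenet import target_inference as ti
from spongenet.io_core import InteractionSet


def _sm(scores, mirnas=None, targets=None, method="pearson", signed=True):
    scores = np.asarray(scores, dtype=float)
    mirnas = mirnas or [f"m{i}" for i in range(scores.shape[0])]
    targets = targets or [f"t{j}" for j in range(scores.shape[1])]
    return ti.ScoreMatrix(method, mirnas, targets, scores,
                          np.zeros(scores.shape, bool), signed)


class TestRankAndValidate:
    def test_truth_superset_validates_everything(self):
        sm = _sm([[0.9, 0.8], [0.7, 0.6]])
        truth = InteractionSet({(m, t, "mRNA") for m in ("m0", "m1")
                                for t in ("t0", "t1")})
        rep = ti.rank_and_validate({"mRNA": sm}, truth, k=2)
        assert rep.n_validated == rep.n_predicted == 4

    def test_empty_truth_validates_nothing(self):
        sm = _sm([[0.9, 0.8]])
        rep = ti.rank_and_validate({"mRNA": sm}, InteractionSet(set()), k=2)
        assert rep.n_validated == 0

    def test_hand_set_scores_against_exhaustive_check(self):
        scores = [[0.9, 0.1, 0.8, 0.2],
                  [0.3, 0.7, 0.2, 0.6]]
        truth = InteractionSet({("m0", "t0", "mRNA"), ("m0", "t1", "mRNA"),
                                ("m1", "t3", "mRNA")})
        k = 2
        sm = _sm(scores)
        rep = ti.rank_and_validate({"mRNA": sm}, truth, k)
        # brute force: per miRNA, the k largest |score| targets
        expected = 0
        for i, m in enumerate(sm.mirna_ids):
            top = sorted(range(4), key=lambda j: (-abs(scores[i][j]),
                                                  sm.target_ids[j]))[:k]
            expected += sum((m, sm.target_ids[j], "mRNA") in truth.pairs
                            for j in top)
        assert rep.n_validated == expected == 2

    def test_k_clamped_to_universe(self):
        sm = _sm([[0.5, 0.4]])
        rep = ti.rank_and_validate({"mRNA": sm}, InteractionSet(set()), k=10)
        assert rep.n_predicted == 2

    def test_score_ties_broken_by_target_id(self):
        sm = _sm([[0.5, 0.5, 0.5]])
        ranked = ti.rank_targets(sm, 2)
        assert ranked[0].target_ids == ["t0", "t1"]

    def test_signed_ranking_convention(self):
        sm = _sm([[-0.9, 0.8]])
        by_abs = ti.rank_targets(sm, 1, rank_signed=False)
        by_neg = ti.rank_targets(sm, 1, rank_signed=True)
        assert by_abs[0].target_ids == ["t0"]
        assert by_neg[0].target_ids == ["t0"]
        sm2 = _sm([[0.9, -0.8]])
        assert ti.rank_targets(sm2, 1, rank_signed=True)[0].target_ids == ["t1"]


class TestBuildNetwork:
    def test_edge_count_two_classes(self):
        rng = np.random.default_rng(0)
        by_class = {
            "lncRNA": _sm(rng.uniform(0.1, 1, (2, 10))),
            "mRNA": _sm(rng.uniform(0.1, 1, (2, 10))),
        }
        net = ti.build_target_network(by_class, k=3)
        assert len(net) == 2 * 3 * 2

    def test_k_equal_universe_gives_complete_bipartite(self):
        rng = np.random.default_rng(1)
        by_class = {"mRNA": _sm(rng.uniform(0.1, 1, (3, 4)))}
        net = ti.build_target_network(by_class, k=4)
        assert len(net) == 12

    def test_planted_pairs_recovered_at_twice_outdegree(self, small_dataset):
        ds = small_dataset
        sm = ti.score_correlation("pearson", ds.mirna, ds.mrna)
        out_deg = max(
            sum(1 for m, t, c in ds.truth.regulation.pairs
                if m == mi and c == "mRNA")
            for mi in ds.mirna.gene_ids)
        net = ti.build_target_network({"mRNA": sm}, k=2 * out_deg)
        truth_mrna = {(m, t) for m, t, c in ds.truth.regulation.pairs
                      if c == "mRNA"}
        recovered = truth_mrna & net.pairs_no_class()
        assert len(recovered) >= 0.8 * len(truth_mrna)


class TestBestMethod:
    def _rep(self, name, validated, predicted, k=50):
        return ti.ValidationReport(name, k, predicted, validated)

    def test_highest_summed_validated_wins(self):
        reports = [self._rep("a", 5, 100), self._rep("b", 9, 100),
                   self._rep("a", 6, 100, k=100), self._rep("b", 1, 100, k=100)]
        assert ti.best_method(reports) == "a"

    def test_tie_broken_by_fewer_predictions_then_name(self):
        reports = [self._rep("a", 5, 100), self._rep("b", 5, 60)]
        assert ti.best_method(reports) == "b"
        reports = [self._rep("b", 5, 100), self._rep("a", 5, 100)]
        assert ti.best_method(reports) == "a"

    def test_masked_competition_scorer_wins_on_weak_signal_fixture(self):
        """When regulation is too weak for correlation methods but the
        candidate mask is exactly the truth, the two-view competition
        scorer validates every prediction and is selected."""
        from spongenet.synthetic_data import promise_favoured_dataset
        ds = promise_favoured_dataset(3)
        reports = []
        for method in ("pearson", "spearman", "lasso", "zscore", "promise"):
            if method in ti.CORRELATION_METHODS:
                sm = ti.score_correlation(method, ds.mirna, ds.mrna)
            elif method == "lasso":
                sm = ti.score_regression("lasso", ds.mirna, ds.mrna)
            elif method == "zscore":
                sm = ti.score_zscore(ds.mirna, ds.mrna)
            else:
                sm, _ = ti.score_promise(ds.mirna, ds.mrna,
                                         ds.putative["mRNA"])
            reports.append(ti.rank_and_validate({"mRNA": sm},
                                                ds.truth.regulation, 5))
        assert ti.best_method(reports) == "promise"
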