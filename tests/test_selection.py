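"""Information gain, MRMD ranking, and incremental selection."""

import itertools
import math

import numpy as np
import pytest

from snopred import (
    InformationGainSelector,
    MRMDSelector,
    RankedFeatures,
    binarize_presence,
    incremental_selection,
    information_gain,
    mrmd_distance,
    mrmd_rank,
    mrmd_relevance,
    rank_dipeptide_ig,
    rank_residue_ig,
    rank_residue_mrmd,
)
from snopred.metrics import EvalMetrics


def brute_force_ig(feature, labels):
    """Independent oracle: plug-in mutual information from the 2x2 table."""
    f = np.asarray(feature)
    x = np.asarray(labels)
    n = len(x)
    mi = 0.0
    for fv in (0, 1):
        for xv in (0, 1):
            p_joint = ((f == fv) & (x == xv)).sum() / n
            p_f = (f == fv).sum() / n
            p_x = (x == xv).sum() / n
            if p_joint > 0:
                mi += p_joint * math.log2(p_joint / (p_f * p_x))
    return mi


class TestBinarize:
    def test_examples_and_idempotence(self):
        assert list(binarize_presence(np.array([0.0, 0.3, 0.0]))) == [0, 1, 0]
        M = np.array([[0.0, 0.2], [0.0, 0.0]])
        B = binarize_presence(M)
        assert (B[:, 0] == 0).all()
        assert (binarize_presence(B) == B).all()


class TestInformationGain:
    def test_feature_equals_labels(self):
        assert information_gain([1, 1, 0, 0], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_independent_feature(self):
        assert information_gain([1, 0, 1, 0], [1, 1, 0, 0]) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        assert information_gain([1, 1, 1, 0], [1, 1, 0, 0]) == pytest.approx(0.3113, abs=1e-4)

    def test_errors(self):
        with pytest.raises(ValueError):
            information_gain([1, 0], [1, 0, 1])
        with pytest.raises(ValueError):
            information_gain([1, 0, 1], [1, 1, 1])

    def test_exhaustive_oracle_small_n(self):
        """IG equals brute-force plug-in MI on every 2x2 pattern, n <= 12."""
        checked = 0
        for n in range(2, 13):
            for a, b, c in itertools.product(range(n + 1), repeat=3):
                d = n - a - b - c
                if d < 0:
                    continue
                # a: f=1,x=1; b: f=1,x=0; c: f=0,x=1; d: f=0,x=0
                if a + c == 0 or b + d == 0:
                    continue  # single-class labels are rejected
                f = np.array([1] * a + [1] * b + [0] * c + [0] * d)
                x = np.array([1] * a + [0] * b + [1] * c + [0] * d)
                assert information_gain(f, x) == pytest.approx(brute_force_ig(f, x), abs=1e-12)
                checked += 1
        assert checked > 1000

    def test_invariant_to_bit_swaps(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            f = rng.integers(0, 2, 30)
            x = np.concatenate([[0, 1], rng.integers(0, 2, 28)])
            base = information_gain(f, x)
            assert information_gain(1 - f, x) == pytest.approx(base)
            assert information_gain(f, 1 - x) == pytest.approx(base)


class TestResidueRankings:
    def test_planted_residue_ranks_first(self, default_sim):
        assert rank_residue_ig(default_sim).order[0] == "K"

    def test_shuffled_labels_kill_ig(self, default_sim):
        from snopred import LabeledDataset, PeptideWindow

        rng = np.random.default_rng(3)
        labels = rng.permutation(default_sim.labels)
        shuffled = LabeledDataset(
            [PeptideWindow(w.residues, label=int(l))
             for w, l in zip(default_sim, labels)]
        )
        assert rank_residue_ig(shuffled).scores[0] < 0.01

    def test_dipeptide_ranking_shape_and_signal(self, default_sim):
        ranked = rank_dipeptide_ig(default_sim)
        assert len(ranked.order) == 400
        assert (np.diff(ranked.scores) <= 1e-15).all()
        # the planted K gradient makes KK pairs the strongest dipeptide signal
        assert "K" in ranked.order[0]

    def test_mrmd_residue_ranking_recovers_plant(self, default_sim):
        for variant in ("ed", "cos", "tc", "mean"):
            assert rank_residue_mrmd(default_sim, variant=variant).order[0] == "K"


class TestMRMDComponents:
    def test_relevance_examples(self):
        y = np.array([1, 1, 0, 0, 1, 0])
        assert mrmd_relevance(y, y) == pytest.approx(1.0)
        assert mrmd_relevance(-y, y) == pytest.approx(1.0)
        with pytest.warns(UserWarning):
            assert mrmd_relevance(np.ones(6), y) == 0.0

    def test_orthogonal_feature_zero_relevance(self):
        y = np.array([1, 1, 0, 0])
        f = np.array([1.0, -1.0, 1.0, -1.0])
        assert mrmd_relevance(f, y) == pytest.approx(0.0, abs=1e-12)

    def test_identical_columns_zero_ed(self):
        X = np.tile(np.arange(5.0)[:, None], (1, 2))
        assert np.allclose(mrmd_distance(X, "ed"), 0.0)

    def test_orthogonal_unit_columns_cosine_one(self):
        X = np.eye(3)[:, :2]
        assert np.allclose(mrmd_distance(X, "cos"), 1.0)
        assert np.allclose(mrmd_distance(X, "tc"), 1.0)

    def test_mean_is_average_of_three(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(size=(30, 6))
        expected = (mrmd_distance(X, "ed") + mrmd_distance(X, "cos") + mrmd_distance(X, "tc")) / 3
        assert np.allclose(mrmd_distance(X, "mean"), expected)

    def test_single_feature_rejected(self):
        with pytest.raises(ValueError):
            mrmd_distance(np.ones((4, 1)), "ed")


class TestMRMDRank:
    def test_weight_limits(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(100, 8))
        y = (X[:, 3] + 0.5 * rng.normal(size=100) > 0).astype(int)
        rel_order = np.argsort(-np.array([mrmd_relevance(X[:, j], y) for j in range(8)]),
                               kind="stable")
        got = mrmd_rank(X, y, variant="ed", w_d=0.0)
        assert list(got.indices) == list(rel_order)
        dist_order = np.argsort(-mrmd_distance(X, "ed"), kind="stable")
        got = mrmd_rank(X, y, variant="ed", w_r=0.0)
        assert list(got.indices) == list(dist_order)

    def test_duplicate_never_outranks_original(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(size=(60, 5))
        X[:, 4] = X[:, 1]  # duplicate column 1 at index 4
        y = (X[:, 0] > 0.5).astype(int)
        for variant in ("ed", "cos", "tc", "mean"):
            ranked = mrmd_rank(X, y, variant=variant)
            assert list(ranked.indices).index(1) < list(ranked.indices).index(4)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(size=(50, 6))
        y = rng.integers(0, 2, 50)
        perm = rng.permutation(6)
        base = mrmd_rank(X, y, variant="mean")
        permuted = mrmd_rank(X[:, perm], y, variant="mean")
        assert [perm[i] for i in permuted.indices] == list(base.indices)

    def test_planted_feature_recovery_many_noise(self):
        """One informative feature among 50 noise columns: IG and every
        MRMD variant put it first at n = 500."""
        rng = np.random.default_rng(8)
        n = 500
        y = rng.integers(0, 2, n)
        X = rng.uniform(size=(n, 51))
        X[:, 17] = y + 0.3 * rng.normal(size=n)
        for variant in ("ed", "cos", "tc", "mean"):
            assert mrmd_rank(X, y, variant=variant).indices[0] == 17
        ig = InformationGainSelector(k=1).fit(X, y)
        assert ig.ranking_.indices[0] == 17


class TestSelectors:
    def test_ig_selector_keeps_original_order(self):
        X = np.array([[1, 0, 1], [1, 0, 1], [0, 0, 1], [0, 0, 0]], dtype=float)
        y = np.array([1, 1, 0, 0])
        # col 0: IG = 1 bit; col 1: constant, IG = 0; col 2: IG ~ 0.31
        sel = InformationGainSelector(k=2).fit(X, y)
        assert list(sel.get_support(indices=True)) == [0, 2]
        assert sel.transform(X).shape == (4, 2)

    def test_mrmd_selector_transform(self):
        rng = np.random.default_rng(9)
        X = rng.uniform(size=(40, 6))
        y = rng.integers(0, 2, 40)
        sel = MRMDSelector(k=3, variant="mean").fit(X, y)
        assert sel.transform(X).shape == (40, 3)


class TestIncrementalSelection:
    @staticmethod
    def _metric(acc):
        n_right = int(round(acc * 100))
        return EvalMetrics(tp=n_right, fp=100 - n_right, tn=0, fn=0)

    def test_unimodal_evaluator(self):
        ranked = RankedFeatures.from_scores([f"f{i}" for i in range(20)], np.arange(20)[::-1], "ig")
        trace = incremental_selection(
            ranked, lambda d: self._metric(1 - abs(d - 7) / 100), dims=range(1, 21))
        assert trace.best_dim == 7

    def test_singleton_dims(self):
        ranked = RankedFeatures.from_scores(["a", "b", "c"], [3, 2, 1], "ig")
        trace = incremental_selection(ranked, lambda d: self._metric(0.5), dims=[2])
        assert trace.best_dim == 2

    def test_tie_prefers_smaller_dimension(self):
        ranked = RankedFeatures.from_scores(["a", "b", "c"], [3, 2, 1], "ig")
        trace = incremental_selection(ranked, lambda d: self._metric(0.8), dims=[1, 2, 3])
        assert trace.best_dim == 1

    def test_empty_dims_rejected(self):
        ranked = RankedFeatures.from_scores(["a"], [1.0], "ig")
        with pytest.raises(ValueError):
            incremental_selection(ranked, lambda d: self._metric(1.0), dims=[])
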