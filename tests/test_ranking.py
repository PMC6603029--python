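"""Ranker oracles, consensus averaging, and signature selection."""

import numpy as np
import pytest

from radiolik import (
    RankerOutput,
    consensus_rank,
    fisher_score,
    laplacian_score,
    mutual_information_ranker,
    redundancy_score,
    relieff,
    select_signature,
    spec_score,
    variance_score,
)
from radiolik.core_tables import FeatureMeta


# ---------------------------------------------------------------- oracles

def fisher_oracle(X, labels):
    """Direct recomputation: sum_c n_c (mu_c - mu)^2 / sum_c n_c var_c."""
    out = []
    for j in range(X.shape[1]):
        col = X[:, j]
        grand = col.mean()
        num = den = 0.0
        for c in np.unique(labels):
            grp = col[labels == c]
            num += len(grp) * (grp.mean() - grand) ** 2
            den += len(grp) * grp.var()
        out.append(num / den if den > 0 else 0.0)
    return np.array(out)


def relieff_oracle(X, labels, k):
    """Brute-force ReliefF: explicit neighbor enumeration, Manhattan
    distance on [0, 1]-scaled features, all samples as anchors."""
    span = X.max(axis=0) - X.min(axis=0)
    span = np.where(span > 0, span, 1.0)
    Xs = (X - X.min(axis=0)) / span
    Xs[:, (X.max(axis=0) - X.min(axis=0)) == 0] = 0.0
    n, p = Xs.shape
    W = np.zeros(p)
    for i in range(n):
        dists = [
            (abs(Xs[i] - Xs[j]).sum(), j) for j in range(n) if j != i
        ]
        hits = sorted(
            (d, j) for d, j in dists if labels[j] == labels[i]
        )[: k]
        misses = sorted(
            (d, j) for d, j in dists if labels[j] != labels[i]
        )[: k]
        dh = np.mean([abs(Xs[j] - Xs[i]) for _, j in hits], axis=0)
        dm = np.mean([abs(Xs[j] - Xs[i]) for _, j in misses], axis=0)
        W += dm - dh
    return W / n


def heat_graph_oracle(X, k):
    """Independent kNN heat-kernel graph: loops and sorted distances."""
    n = X.shape[0]
    D = np.array(
        [[np.linalg.norm(X[i] - X[j]) for j in range(n)] for i in range(n)]
    )
    knn = {}
    dists = []
    for i in range(n):
        order = sorted((D[i, j], j) for j in range(n) if j != i)[:k]
        knn[i] = [j for _, j in order]
        dists.extend(d for d, _ in order)
    sigma = np.mean(dists)
    W = np.zeros((n, n))
    for i in range(n):
        for j in knn[i]:
            w = np.exp(-D[i, j] ** 2 / sigma**2)
            W[i, j] = max(W[i, j], w)
            W[j, i] = max(W[j, i], w)
    return W


def laplacian_oracle(X, k):
    W = heat_graph_oracle(X, k)
    d = W.sum(axis=1)
    L = np.diag(d) - W
    out = []
    for j in range(X.shape[1]):
        f = X[:, j]
        ft = f - (f @ d) / d.sum()
        out.append((ft @ L @ ft) / (ft @ (d * ft)))
    return np.array(out)


def spec_oracle(X, k):
    W = heat_graph_oracle(X, k)
    d = W.sum(axis=1)
    Lsym = np.eye(len(d)) - W / np.sqrt(np.outer(d, d))
    out = []
    for j in range(X.shape[1]):
        fh = np.sqrt(d) * X[:, j]
        fh = fh / np.linalg.norm(fh)
        out.append(fh @ Lsym @ fh)
    return np.array(out)


# ---------------------------------------------------------------- rankers

class TestFisher:
    def test_brute_force_small_case(self, rng):
        X = rng.standard_normal((6, 2))
        labels = np.array([0, 0, 0, 1, 1, 1])
        np.testing.assert_allclose(
            fisher_score(X, labels).raw_scores,
            fisher_oracle(X, labels),
            atol=1e-12,
        )

    def test_unit_variance_separated_means(self):
        # class means 0 and 1, population class variances 1, equal n
        col = np.array([-1.0, 1.0, 0.0, 2.0])
        labels = np.array([0, 0, 1, 1])
        score = fisher_score(col[:, None], labels).raw_scores[0]
        # sum_c n_c (mu_c - 0.5)^2 = 1; sum_c n_c var_c = 4
        assert score == pytest.approx(0.25, abs=1e-12)

    def test_no_separation_scores_zero(self, rng):
        col = np.tile(rng.standard_normal(5), 2)
        labels = np.repeat([0, 1], 5)
        assert fisher_score(col[:, None], labels).raw_scores[0] == pytest.approx(0.0, abs=1e-12)

    def test_zero_within_class_variance_sentinel(self):
        X = np.column_stack(
            [[0, 0, 1, 1], [0.1, 0.2, 0.3, 0.6]]
        ).astype(float)
        labels = np.array([0, 0, 1, 1])
        with pytest.warns(UserWarning, match="zero within-class variance"):
            scores = fisher_score(X, labels).raw_scores
        assert scores[0] == scores[1] + 1.0  # max finite + 1

    def test_single_class_errors(self, rng):
        with pytest.raises(ValueError, match="2 classes"):
            fisher_score(rng.standard_normal((4, 2)), [1, 1, 1, 1])


class TestRelieff:
    def test_brute_force_enumeration_n20(self, rng):
        X = rng.standard_normal((20, 5))
        labels = rng.integers(0, 2, 20)
        labels[:4] = [0, 0, 1, 1]
        out = relieff(X, labels, k_neighbors=3)
        np.testing.assert_allclose(
            out.raw_scores, relieff_oracle(X, labels, 3), atol=1e-12
        )

    def test_separating_feature_attains_max_weight(self, rng):
        labels = np.repeat([0, 1], 10)
        X = rng.standard_normal((20, 6))
        X[:, 2] = labels  # perfect separator
        w = relieff(X, labels, k_neighbors=3).raw_scores
        assert np.argmax(w) == 2
        assert -1 <= w.min() and w.max() <= 1

    def test_constant_feature_weight_zero(self, rng):
        X = rng.standard_normal((16, 3))
        X[:, 1] = 4.2
        labels = np.repeat([0, 1], 8)
        assert relieff(X, labels).raw_scores[1] == 0.0

    def test_duplicated_columns_equal_weights(self, rng):
        X = rng.standard_normal((18, 2))
        X = np.column_stack([X, X[:, 0]])
        labels = np.repeat([0, 1], 9)
        w = relieff(X, labels).raw_scores
        assert w[0] == pytest.approx(w[2], abs=1e-12)


class TestMutualInformation:
    def test_feature_equal_to_label_gives_label_entropy(self):
        labels = np.repeat([0, 1], 8)
        X = labels[:, None].astype(float)
        mi = mutual_information_ranker(X, labels).raw_scores[0]
        assert mi == pytest.approx(np.log(2), abs=1e-12)

    def test_brute_force_contingency_on_8_samples(self):
        X = np.array([0.1, 0.9, 0.15, 0.85, 0.2, 0.8, 0.12, 0.88])[:, None]
        labels = np.array([0, 1, 0, 1, 0, 1, 1, 0])
        mi = mutual_information_ranker(X, labels, n_bins=2).raw_scores[0]
        # hand contingency: bin 0 = {0,0,0,1}, bin 1 = {1,1,1,0}
        oracle = 0.0
        joint = {(0, 0): 3, (0, 1): 1, (1, 0): 1, (1, 1): 3}
        for (b, l), c in joint.items():
            pxy = c / 8
            px = 4 / 8
            py = 4 / 8
            oracle += pxy * np.log(pxy / (px * py))
        assert mi == pytest.approx(oracle, abs=1e-12)

    def test_independent_feature_mi_near_zero(self, rng):
        labels = rng.integers(0, 2, 1000)
        X = rng.standard_normal((1000, 1))
        mi = mutual_information_ranker(X, labels).raw_scores[0]
        assert mi < 0.02


class TestGraphScores:
    def test_laplacian_hand_graph_n4(self, rng):
        X = rng.standard_normal((4, 3)) * [1, 5, 0.3]
        out = laplacian_score(X, k_neighbors=2)
        np.testing.assert_allclose(
            out.raw_scores, laplacian_oracle(X, 2), atol=1e-12
        )
        assert out.orientation == "lower_better"

    def test_spec_hand_graph_n4(self, rng):
        X = rng.standard_normal((4, 3)) + 2.0
        np.testing.assert_allclose(
            spec_score(X, k_neighbors=2).raw_scores,
            spec_oracle(X, 2),
            atol=1e-12,
        )

    def test_smooth_feature_beats_noise_on_two_blobs(self, rng):
        blob = np.repeat([0.0, 5.0], 15)
        noise = rng.standard_normal(30)
        X = np.column_stack([blob, noise])
        lap = laplacian_score(X, k_neighbors=4).raw_scores
        spc = spec_score(X, k_neighbors=4).raw_scores
        assert lap[0] < lap[1]  # lower = smoother = better
        assert spc[0] < spc[1]

    def test_sample_permutation_invariance(self, rng):
        X = rng.standard_normal((25, 4))
        perm = rng.permutation(25)
        np.testing.assert_allclose(
            laplacian_score(X).raw_scores,
            laplacian_score(X[perm]).raw_scores,
            atol=1e-10,
        )

    def test_spec_scale_invariance(self, rng):
        """The spectral score of c*f equals that of f on a fixed graph."""
        X = rng.standard_normal((20, 3)) + 1.0
        from radiolik.ranking import _knn_heat_graph

        W = _knn_heat_graph(X, 5, None)
        d = W.sum(axis=1)
        Lsym = np.eye(len(d)) - W / np.sqrt(np.outer(d, d))

        def score(f):
            fh = np.sqrt(d) * f
            fh /= np.linalg.norm(fh)
            return fh @ Lsym @ fh

        f = X[:, 1]
        assert score(3.7 * f) == pytest.approx(score(f), rel=1e-12)

    def test_constant_feature_assigned_worst(self, rng):
        X = rng.standard_normal((12, 2))
        X[:, 0] = 3.0
        with pytest.warns(UserWarning, match="constant"):
            scores = laplacian_score(X).raw_scores
        assert scores[0] > scores[1]


class TestSimpleFilters:
    def test_redundancy_hand_case(self, rng):
        X = rng.standard_normal((50, 3))
        scores = redundancy_score(X).raw_scores
        R = np.corrcoef(X, rowvar=False)
        for j in range(3):
            hand = -np.mean([abs(R[j, k]) for k in range(3) if k != j])
            assert scores[j] == pytest.approx(hand, abs=1e-12)

    def test_identical_features_score_lowest(self, rng):
        X = rng.standard_normal((40, 5))
        X[:, 3] = X[:, 1]
        scores = redundancy_score(X).raw_scores
        assert set(np.argsort(scores)[:2]) == {1, 3}

    def test_independent_features_near_zero(self, rng):
        scores = redundancy_score(rng.standard_normal((2000, 6))).raw_scores
        assert np.abs(scores).max() < 0.05

    def test_variance_score_cases(self, rng):
        X = np.column_stack(
            [np.full(8, 3.0), np.tile([0.0, 1.0], 4), rng.uniform(2, 4, 8)]
        )
        s = variance_score(X).raw_scores
        assert s[0] == 0.0
        assert s[1] == pytest.approx(0.25, abs=1e-12)  # balanced binary
        # min-max scaling makes the score invariant to affine rescaling
        s2 = variance_score(X * 100 - 7).raw_scores
        np.testing.assert_allclose(s, s2, atol=1e-12)


# ------------------------------------------------------------- consensus

class TestConsensus:
    def test_single_ranker_preserves_ordering(self, rng):
        raw = rng.standard_normal(8)
        names = [f"f{i}" for i in range(8)]
        cons = consensus_rank(
            [RankerOutput("r", raw, "higher_better")], names
        )
        assert cons.top(8) == [names[i] for i in np.argsort(-raw)]

    def test_reversed_rankers_tie_broken_by_name(self):
        names = ["c", "a", "b"]
        out1 = RankerOutput("r1", np.array([1.0, 2, 3]), "higher_better")
        out2 = RankerOutput("r2", np.array([3.0, 2, 1]), "higher_better")
        cons = consensus_rank([out1, out2], names)
        np.testing.assert_allclose(cons.consensus, 0.5)
        assert cons.top(3) == ["a", "b", "c"]

    def test_hand_oracle_5x3(self):
        names = list("abcde")
        outs = [
            RankerOutput("r1", np.array([10.0, 20, 30, 40, 50]),
                         "higher_better"),
            RankerOutput("r2", np.array([1.0, 3, 2, 5, 4]), "lower_better"),
            RankerOutput("r3", np.array([0.0, 0, 0, 0, 8]), "higher_better"),
        ]
        cons = consensus_rank(outs, names)
        np.testing.assert_allclose(
            cons.consensus,
            [1 / 3, 0.25, (0.5 + 0.75) / 3, 0.25, (1 + 0.25 + 1) / 3],
            atol=1e-12,
        )
        assert cons.top(5) == ["e", "c", "a", "b", "d"]

    def test_duplicated_rankers_idempotent(self, rng):
        names = [f"f{i}" for i in range(6)]
        out = RankerOutput("r", rng.standard_normal(6), "higher_better")
        once = consensus_rank([out], names)
        thrice = consensus_rank([out, out, out], names)
        np.testing.assert_allclose(once.consensus, thrice.consensus)
        assert once.rank.tolist() == thrice.rank.tolist()

    def test_constant_ranker_normalized_to_half(self):
        out = RankerOutput("r", np.zeros(4), "higher_better")
        with pytest.warns(UserWarning, match="constant scores"):
            cons = consensus_rank([out], list("abcd"))
        np.testing.assert_allclose(cons.consensus, 0.5)

    def test_rank_average_mode(self, rng):
        names = [f"f{i}" for i in range(5)]
        out = RankerOutput("r", rng.standard_normal(5), "higher_better")
        cons = consensus_rank([out], names, mode="rank")
        assert cons.top(5) == consensus_rank([out], names).top(5)
        assert sorted(cons.consensus) == pytest.approx(
            [1 / 5, 2 / 5, 3 / 5, 4 / 5, 1.0]
        )

    def test_feature_count_mismatch(self):
        out = RankerOutput("r", np.ones(3), "higher_better")
        with pytest.raises(ValueError, match="expected 4"):
            consensus_rank([out], list("abcd"))


class TestSelectSignature:
    @staticmethod
    def ranking_for(names):
        scores = np.arange(len(names), 0, -1, dtype=float)
        return consensus_rank(
            [RankerOutput("r", scores, "higher_better")], names
        )

    def test_shape_first_then_texture(self):
        names = [
            "shape_SurfaceVolumeRatio", "glcm_SumEntropy",
            "firstorder_Mean", "shape_Volume",
        ]
        sig = select_signature(
            self.ranking_for(names),
            [FeatureMeta.from_name(n) for n in names],
        )
        assert sig.shape_feature == "shape_SurfaceVolumeRatio"
        assert sig.texture_feature == "glcm_SumEntropy"

    def test_texture_top_block_shape_fifth(self):
        names = [
            "glszm_LargeAreaLowGrayLevelEmphasis", "glcm_SumEntropy",
            "firstorder_Mean", "ngtdm_Contrast", "shape_Volume",
            "shape_Sphericity",
        ]
        sig = select_signature(
            self.ranking_for(names),
            [FeatureMeta.from_name(n) for n in names],
        )
        assert sig.shape_feature == "shape_Volume"
        assert sig.texture_feature == "glszm_LargeAreaLowGrayLevelEmphasis"

    def test_all_texture_top_k_errors(self):
        names = ["glcm_A", "glcm_B", "glrlm_C", "shape_D"]
        with pytest.raises(ValueError, match="no shape feature"):
            select_signature(
                self.ranking_for(names),
                [FeatureMeta.from_name(n) for n in names],
                top_k=3,
            )


# ----------------------------------------------------- group invariances

class TestInvariances:
    def test_sample_permutation_supervised(self, rng):
        X = rng.standard_normal((30, 4))
        labels = rng.integers(0, 2, 30)
        labels[:4] = [0, 0, 1, 1]
        perm = rng.permutation(30)
        for fn in (fisher_score, mutual_information_ranker):
            np.testing.assert_allclose(
                fn(X, labels).raw_scores,
                fn(X[perm], labels[perm]).raw_scores,
                atol=1e-12,
            )
        np.testing.assert_allclose(
            relieff(X, labels).raw_scores,
            relieff(X[perm], labels[perm]).raw_scores,
            atol=1e-12,
        )

    def test_label_swap_invariance(self, rng):
        X = rng.standard_normal((24, 5))
        labels = np.repeat([0, 1], 12)
        for fn in (fisher_score, mutual_information_ranker, relieff):
            np.testing.assert_allclose(
                fn(X, labels).raw_scores,
                fn(X, 1 - labels).raw_scores,
                atol=1e-12,
            )

    def test_planted_signature_recovered(self, cohort):
        """At effect size 3, both ranker groups place the planted
        features on top and recover a planted shape+texture pair."""
        from radiolik.ranking import run_ranker_group
        from radiolik.synthetic import INFORMATIVE_FEATURES

        planted = set(INFORMATIVE_FEATURES)
        for group in ("supervised", "unsupervised"):
            outs = run_ranker_group(
                cohort.values, group, labels=cohort.labels
            )
            cons = consensus_rank(outs, cohort.feature_names, group=group)
            assert len(planted & set(cons.top(5))) >= 3
            sig = select_signature(cons, cohort.features)
            assert sig.shape_feature in planted
            assert sig.texture_feature in planted
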