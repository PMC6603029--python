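"""Feature-ranking algorithms, consensus averaging, signature selection.

Two groups of rankers are provided behind one uniform interface:

* **supervised** (wrapper-style, label-aware): Fisher score, ReliefF,
  and a binned mutual-information ranker;
* **unsupervised** (filter-style, label-free): Laplacian score,
  spectral (normalized-Laplacian) score, minimum-redundancy score, and
  a min-max-scaled variance score.

Each ranker returns a :class:`RankerOutput` carrying raw per-feature
scores and an orientation flag.  :func:`consensus_rank` orients every
output to higher-is-better, min-max normalizes it to [0, 1], and
averages with equal weights, so that heterogeneous score scales each
contribute equally to the final ranking.  A rank-average mode (mean of
rank positions instead of normalized scores) is available as an
alternative commensuration scheme.

:func:`select_signature` then builds a two-feature diagnostic signature
from the consensus list: the best-ranked shape feature plus the
best-ranked texture feature within the top-k (default 25).  Shape and
texture carry complementary information about a nodule — geometry
versus gray-level patterns — which motivates the one-of-each rule.

Additional rankers can be registered in ``SUPERVISED_RANKERS`` /
``UNSUPERVISED_RANKERS`` without touching the consensus logic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import mutual_info_score
from sklearn.neighbors import NearestNeighbors

from radiolik.core_tables import FeatureMeta

__all__ = [
    "RankerOutput",
    "ConsensusRanking",
    "RadiomicSignature",
    "fisher_score",
    "relieff",
    "mutual_information_ranker",
    "laplacian_score",
    "spec_score",
    "redundancy_score",
    "variance_score",
    "consensus_rank",
    "select_signature",
    "SUPERVISED_RANKERS",
    "UNSUPERVISED_RANKERS",
    "run_ranker_group",
]


@dataclass
class RankerOutput:
    """Raw per-feature scores from one ranking algorithm."""

    ranker_name: str
    raw_scores: np.ndarray
    orientation: str  # "higher_better" | "lower_better"

    def __post_init__(self) -> None:
        self.raw_scores = np.asarray(self.raw_scores, dtype=float)
        if self.orientation not in ("higher_better", "lower_better"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if not np.isfinite(self.raw_scores).all():
            raise ValueError(f"{self.ranker_name}: non-finite scores")

    @property
    def oriented(self) -> np.ndarray:
        """Scores flipped so that higher always means better."""
        if self.orientation == "higher_better":
            return self.raw_scores
        return -self.raw_scores


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(
            f"need exactly 2 classes, got {classes.size}"
        )
    return classes


def fisher_score(values: np.ndarray, labels: Sequence[int]) -> RankerOutput:
    """Fisher score: between-class separation over within-class variance.

    For feature j with grand mean mu_j, class means mu_cj, population
    class variances sigma2_cj and class sizes n_c:

        F_j = sum_c n_c (mu_cj - mu_j)^2 / sum_c n_c sigma2_cj

    A feature with zero pooled within-class variance but separated means
    would score infinity; it is assigned (max finite score + 1) with a
    warning so downstream normalization stays finite.
    """
    X = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = _check_binary(labels)
    for c in classes:
        if (labels == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
    grand = X.mean(axis=0)
    num = np.zeros(X.shape[1])
    den = np.zeros(X.shape[1])
    for c in classes:
        Xc = X[labels == c]
        nc = Xc.shape[0]
        num += nc * (Xc.mean(axis=0) - grand) ** 2
        den += nc * Xc.var(axis=0)  # population variance
    scores = np.zeros(X.shape[1])
    ok = den > 0
    scores[ok] = num[ok] / den[ok]
    degenerate = (~ok) & (num > 0)
    if degenerate.any():
        warnings.warn(
            f"{degenerate.sum()} feature(s) have zero within-class variance; "
            "assigning max finite score + 1",
            stacklevel=2,
        )
        finite_max = scores[ok].max() if ok.any() else 0.0
        scores[degenerate] = finite_max + 1.0
    return RankerOutput("fisher", scores, "higher_better")


def relieff(
    values: np.ndarray,
    labels: Sequence[int],
    k_neighbors: int = 10,
    n_iterations: int | None = None,
    seed: int | None = None,
) -> RankerOutput:
    """ReliefF feature weights for a binary classification problem.

    Features are min-max scaled to [0, 1]; neighbors are found by
    Manhattan distance on the scaled matrix.  For each anchor sample the
    k nearest same-class hits and k nearest other-class misses update
    each feature's weight: differences to misses reward, differences to
    hits penalize.  Weights lie in [-1, 1]; higher is better.

    By default every sample serves as an anchor (deterministic);
    ``n_iterations`` with a ``seed`` subsamples anchors without
    replacement.
    """
    X = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    _check_binary(labels)
    n, p = X.shape
    rng_span = X.max(axis=0) - X.min(axis=0)
    span = np.where(rng_span > 0, rng_span, 1.0)
    Xs = (X - X.min(axis=0)) / span
    Xs[:, rng_span == 0] = 0.0

    if n_iterations is None or n_iterations >= n:
        anchors = np.arange(n)
    else:
        if seed is None:
            raise ValueError("subsampled ReliefF requires a seed")
        anchors = np.random.default_rng(seed).choice(
            n, size=n_iterations, replace=False
        )

    # pairwise Manhattan distances; fine at cohort scale (n <= few 1000)
    D = np.abs(Xs[:, None, :] - Xs[None, :, :]).sum(axis=2)
    np.fill_diagonal(D, np.inf)

    W = np.zeros(p)
    for i in anchors:
        same = np.flatnonzero(labels == labels[i])
        other = np.flatnonzero(labels != labels[i])
        same = same[same != i]
        k_hit = min(k_neighbors, same.size)
        k_miss = min(k_neighbors, other.size)
        if k_hit == 0 or k_miss == 0:
            continue
        hits = same[np.argsort(D[i, same], kind="stable")[:k_hit]]
        misses = other[np.argsort(D[i, other], kind="stable")[:k_miss]]
        diff_hit = np.abs(Xs[hits] - Xs[i]).mean(axis=0)
        diff_miss = np.abs(Xs[misses] - Xs[i]).mean(axis=0)
        W += diff_miss - diff_hit
    W /= len(anchors)
    return RankerOutput("relieff", W, "higher_better")


def mutual_information_ranker(
    values: np.ndarray, labels: Sequence[int], n_bins: int = 10
) -> RankerOutput:
    """Mutual information (nats) between each binned feature and the label.

    Each feature is discretized into ``n_bins`` equal-width bins over
    its observed range; MI is computed from the resulting contingency
    table with the class label.
    """
    X = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    _check_binary(labels)
    scores = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        col = X[:, j]
        lo, hi = col.min(), col.max()
        if hi == lo:
            scores[j] = 0.0
            continue
        edges = np.linspace(lo, hi, n_bins + 1)
        binned = np.clip(np.digitize(col, edges[1:-1]), 0, n_bins - 1)
        scores[j] = mutual_info_score(binned, labels)
    return RankerOutput("mutual_information", scores, "higher_better")


def _knn_heat_graph(
    X: np.ndarray, k_neighbors: int, heat_sigma: float | None
) -> np.ndarray:
    """Symmetrized kNN graph with heat-kernel edge weights.

    Euclidean kNN on samples; an edge exists when either endpoint lists
    the other among its k nearest; weight exp(-d^2 / sigma^2) with
    sigma defaulting to the mean kNN distance.
    """
    n = X.shape[0]
    if n < k_neighbors + 1:
        raise ValueError(
            f"need at least k_neighbors + 1 = {k_neighbors + 1} samples"
        )
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X)
    dist, idx = nn.kneighbors(X)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self
    if heat_sigma is None:
        heat_sigma = float(dist.mean())
        if heat_sigma == 0.0:
            heat_sigma = 1.0
    W = np.zeros((n, n))
    rows = np.repeat(np.arange(n), k_neighbors)
    cols = idx.ravel()
    w = np.exp(-(dist.ravel() ** 2) / heat_sigma**2)
    W[rows, cols] = w
    W = np.maximum(W, W.T)  # symmetrize (union of neighborhoods)
    return W


def laplacian_score(
    values: np.ndarray,
    k_neighbors: int = 5,
    heat_sigma: float | None = None,
) -> RankerOutput:
    """Laplacian score: locality preservation of each feature.

    With graph Laplacian L = D - W and degree matrix D on the sample
    kNN graph, the score of the D-weighted-mean-centered feature f~ is

        L_j = (f~' L f~) / (f~' D f~)

    Smaller scores indicate features that vary smoothly across the
    neighborhood graph, i.e. respect local structure.  Constant
    features have a zero denominator and are assigned the worst finite
    score + 1 with a warning.
    """
    X = np.asarray(values, dtype=float)
    W = _knn_heat_graph(X, k_neighbors, heat_sigma)
    d = W.sum(axis=1)
    L = np.diag(d) - W
    scores = np.empty(X.shape[1])
    degenerate = np.zeros(X.shape[1], dtype=bool)
    for j in range(X.shape[1]):
        f = X[:, j]
        f_t = f - (f @ d) / d.sum()
        denom = f_t @ (d * f_t)
        if denom <= 0:
            degenerate[j] = True
            scores[j] = np.nan
            continue
        scores[j] = (f_t @ L @ f_t) / denom
    if degenerate.any():
        warnings.warn(
            f"{degenerate.sum()} constant feature(s); assigned worst score",
            stacklevel=2,
        )
        worst = np.nanmax(scores) if (~degenerate).any() else 1.0
        scores[degenerate] = worst + 1.0
    return RankerOutput("laplacian", scores, "lower_better")


def spec_score(values: np.ndarray, k_neighbors: int = 5) -> RankerOutput:
    """Spectral feature score on the normalized graph Laplacian.

    Uses the same kNN heat-kernel graph as :func:`laplacian_score`.
    Each feature is degree-weighted (f^ = D^{1/2} f, unit-normalized)
    and scored as f^' Lsym f^ with Lsym = I - D^{-1/2} W D^{-1/2}.
    Smaller means smoother on the graph, hence better.
    """
    X = np.asarray(values, dtype=float)
    W = _knn_heat_graph(X, k_neighbors, None)
    d = W.sum(axis=1)
    d_isqrt = 1.0 / np.sqrt(np.where(d > 0, d, 1.0))
    Lsym = np.eye(len(d)) - (d_isqrt[:, None] * W * d_isqrt[None, :])
    scores = np.empty(X.shape[1])
    degenerate = np.zeros(X.shape[1], dtype=bool)
    for j in range(X.shape[1]):
        f_hat = np.sqrt(d) * X[:, j]
        norm = np.linalg.norm(f_hat)
        if norm == 0:
            degenerate[j] = True
            scores[j] = np.nan
            continue
        f_hat = f_hat / norm
        scores[j] = f_hat @ Lsym @ f_hat
    if degenerate.any():
        warnings.warn(
            f"{degenerate.sum()} zero feature(s); assigned worst score",
            stacklevel=2,
        )
        worst = np.nanmax(scores) if (~degenerate).any() else 1.0
        scores[degenerate] = worst + 1.0
    return RankerOutput("spec", scores, "lower_better")


def redundancy_score(values: np.ndarray) -> RankerOutput:
    """Minimum-redundancy score: negated mean absolute Pearson correlation.

    score_j = -mean_{k != j} |r(f_j, f_k)|.  Features least correlated
    with the rest score highest.  Constant features have undefined
    correlations, treated as 0 with a warning.
    """
    X = np.asarray(values, dtype=float)
    p = X.shape[1]
    if p < 2:
        raise ValueError("need at least 2 features")
    sd = X.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{constant.sum()} constant feature(s); correlations set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X, rowvar=False)
    R = np.nan_to_num(R, nan=0.0)
    np.fill_diagonal(R, 0.0)
    scores = -np.abs(R).sum(axis=0) / (p - 1)
    return RankerOutput("redundancy", scores, "higher_better")


def variance_score(values: np.ndarray) -> RankerOutput:
    """Population variance of each min-max-scaled feature.

    Scaling to [0, 1] makes variances comparable across features with
    different units; a constant feature scores 0.
    """
    X = np.asarray(values, dtype=float)
    span = X.max(axis=0) - X.min(axis=0)
    safe = np.where(span > 0, span, 1.0)
    Xs = (X - X.min(axis=0)) / safe
    scores = Xs.var(axis=0)
    scores[span == 0] = 0.0
    return RankerOutput("variance", scores, "higher_better")


#: Label-aware (wrapper-group) rankers.
SUPERVISED_RANKERS: dict[str, Callable] = {
    "fisher": fisher_score,
    "relieff": relieff,
    "mutual_information": mutual_information_ranker,
}

#: Label-free (filter-group) rankers.
UNSUPERVISED_RANKERS: dict[str, Callable] = {
    "laplacian": laplacian_score,
    "spec": spec_score,
    "redundancy": redundancy_score,
    "variance": variance_score,
}


def run_ranker_group(
    values: np.ndarray,
    group: str,
    labels: Sequence[int] | None = None,
    members: Sequence[str] | None = None,
) -> list[RankerOutput]:
    """Run every ranker of a group ("supervised" | "unsupervised")."""
    if group == "supervised":
        bank = SUPERVISED_RANKERS
        if labels is None:
            raise ValueError("supervised ranking requires labels")
    elif group == "unsupervised":
        bank = UNSUPERVISED_RANKERS
    else:
        raise ValueError(f"unknown ranker group {group!r}")
    names = list(members) if members is not None else list(bank)
    outputs = []
    for name in names:
        if name not in bank:
            raise ValueError(f"unknown {group} ranker {name!r}")
        fn = bank[name]
        if group == "supervised":
            outputs.append(fn(values, labels))
        else:
            outputs.append(fn(values))
    return outputs


@dataclass
class ConsensusRanking:
    """Averaged, oriented, normalized scores over a bank of rankers."""

    feature_names: list[str]
    normalized_scores: pd.DataFrame  # features x rankers, each in [0, 1]
    consensus: np.ndarray
    rank: np.ndarray  # 1 = best
    group: str | None = None

    def top(self, k: int) -> list[str]:
        """Feature names of the best k ranks, in rank order."""
        order = np.argsort(self.rank, kind="stable")
        return [self.feature_names[i] for i in order[:k]]

    def to_dataframe(self) -> pd.DataFrame:
        df = self.normalized_scores.copy()
        df.insert(0, "feature", self.feature_names)
        df["consensus"] = self.consensus
        df["rank"] = self.rank
        return df.sort_values("rank").reset_index(drop=True)


def consensus_rank(
    outputs: Sequence[RankerOutput],
    feature_names: Sequence[str],
    *,
    mode: str = "score",
    group: str | None = None,
) -> ConsensusRanking:
    """Average oriented, normalized ranker scores into a final ranking.

    Parameters
    ----------
    outputs
        Ranker outputs covering the same features in the same order.
    feature_names
        Names for the score vectors' entries.
    mode
        ``"score"`` (default): min-max normalize each oriented score
        vector to [0, 1] and average.  ``"rank"``: average normalized
        rank positions instead (best = 1.0), which is insensitive to
        score scale entirely.

    Ranks are assigned by descending consensus; ties break by ascending
    feature name so the result is deterministic.
    """
    if not outputs:
        raise ValueError("need at least one ranker output")
    n = len(feature_names)
    for out in outputs:
        if out.raw_scores.shape != (n,):
            raise ValueError(
                f"ranker {out.ranker_name!r} scored "
                f"{out.raw_scores.size} features, expected {n}"
            )
    cols = {}
    for out in outputs:
        s = out.oriented.astype(float)
        if mode == "score":
            span = s.max() - s.min()
            if span == 0:
                warnings.warn(
                    f"ranker {out.ranker_name!r} gave constant scores; "
                    "normalized to 0.5",
                    stacklevel=2,
                )
                norm = np.full(n, 0.5)
            else:
                norm = (s - s.min()) / span
        elif mode == "rank":
            # best (highest oriented score) -> 1.0, worst -> 1/n
            order = np.lexsort((list(feature_names), -s))
            pos = np.empty(n)
            pos[order] = np.arange(1, n + 1)
            norm = (n + 1 - pos) / n
        else:
            raise ValueError(f"unknown consensus mode {mode!r}")
        name = out.ranker_name
        while name in cols:  # duplicated ranker names stay distinct columns
            name += "_"
        cols[name] = norm
    scores_df = pd.DataFrame(cols)
    consensus = scores_df.to_numpy().mean(axis=1)
    order = np.lexsort((list(feature_names), -consensus))
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(1, n + 1)
    return ConsensusRanking(
        feature_names=list(feature_names),
        normalized_scores=scores_df,
        consensus=consensus,
        rank=rank,
        group=group,
    )


@dataclass(frozen=True)
class RadiomicSignature:
    """A two-feature diagnostic signature: one shape + one texture."""

    shape_feature: str
    texture_feature: str
    source_group: str | None = None


def select_signature(
    ranking: ConsensusRanking,
    metas: Sequence[FeatureMeta],
    top_k: int = 25,
) -> RadiomicSignature:
    """Pick the best-ranked shape and texture features within the top-k.

    The signature pairs complementary information: the highest-ranked
    feature of kind shape with the highest-ranked feature of kind
    texture, both restricted to the top ``top_k`` consensus ranks.

    Raises
    ------
    ValueError
        If the top-k list lacks a shape or a texture feature.
    """
    kind_of = {m.name: m.kind for m in metas}
    missing = [n for n in ranking.feature_names if n not in kind_of]
    if missing:
        raise ValueError(f"no metadata for features: {missing[:3]}")
    shape = texture = None
    for name in ranking.top(top_k):
        k = kind_of[name]
        if k == "shape" and shape is None:
            shape = name
        elif k == "texture" and texture is None:
            texture = name
        if shape and texture:
            break
    if shape is None:
        raise ValueError(f"no shape feature in the top {top_k} ranks")
    if texture is None:
        raise ValueError(f"no texture feature in the top {top_k} ranks")
    return RadiomicSignature(
        shape_feature=shape, texture_feature=texture,
        source_group=ranking.group,
    )
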