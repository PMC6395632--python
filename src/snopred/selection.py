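"""Feature ranking and selection: information gain and MRMD.

**Information gain (IG)** scores a binary feature Y against the binary
class X as ``IG(X|Y) = H(X) - H(X|Y)`` in bits, with probabilities
estimated by plug-in counts from the 2x2 contingency table and the
convention ``0 * log 0 = 0``.  Continuous features are first binarized
to presence (> 0).

**MRMD** (max-relevance max-distance) scores each feature as a weighted
sum of its relevance — the absolute Pearson correlation with the class —
and its mean distance to the other feature columns (Euclidean, cosine
dissimilarity, Tanimoto dissimilarity, or the mean of the three).
Distances are min-max scaled to [0, 1] before combining so the two
terms are commensurate; default weights are ``w_r = w_d = 1``.

Both rankings are stable: ties keep original column order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .alphabet import AMINO_ACIDS


# --------------------------------------------------------------------
# information gain
# --------------------------------------------------------------------

def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def binarize_presence(matrix: np.ndarray, threshold: float = 0.0) -> np.ndarray:
    """Presence indicator: 1 where value > threshold, else 0."""
    return (np.asarray(matrix) > threshold).astype(int)


def information_gain(feature, labels) -> float:
    """IG of the binary class given a binary feature, in bits.

    ``H(class) - H(class | feature)`` with plug-in probabilities from
    the 2x2 contingency counts; result lies in [0, H(class)] <= 1 bit.
    """
    f = np.asarray(feature, dtype=int)
    x = np.asarray(labels, dtype=int)
    if f.shape != x.shape:
        raise ValueError(f"feature and labels lengths differ: {f.shape} vs {x.shape}")
    n = len(x)
    if n == 0 or len(np.unique(x)) < 2:
        raise ValueError("labels must contain both classes")
    h_x = _entropy_bits(np.bincount(x, minlength=2) / n)
    h_cond = 0.0
    for y_val in (0, 1):
        mask = f == y_val
        n_y = int(mask.sum())
        if n_y == 0:
            continue
        h_cond += (n_y / n) * _entropy_bits(np.bincount(x[mask], minlength=2) / n_y)
    return h_x - h_cond


@dataclass
class RankedFeatures:
    """A stable descending ranking of named features.

    ``order`` lists feature names best-first; ``scores`` is aligned with
    ``order``; ``indices`` maps rank -> original column index.
    """

    order: list[str]
    scores: np.ndarray
    indices: np.ndarray
    method: str

    @classmethod
    def from_scores(cls, names, scores, method: str) -> "RankedFeatures":
        scores = np.asarray(scores, dtype=float)
        idx = np.argsort(-scores, kind="stable")
        return cls(order=[names[i] for i in idx], scores=scores[idx], indices=idx, method=method)

    def top(self, d: int) -> np.ndarray:
        """Original column indices of the best *d* features."""
        return self.indices[:d]


def _presence_matrix_residues(dataset) -> np.ndarray:
    """(n, 20) presence of each residue anywhere off-center in the window."""
    t = dataset.t
    out = np.zeros((len(dataset), 20), dtype=int)
    for i, w in enumerate(dataset):
        seq = w.residues[:t] + w.residues[t + 1 :]
        for j, aa in enumerate(AMINO_ACIDS):
            if aa in seq:
                out[i, j] = 1
    return out


def _presence_matrix_dipeptides(dataset) -> np.ndarray:
    """(n, 400) presence of each X-free dipeptide among window-adjacent
    pairs that do not involve the center position."""
    t = dataset.t
    vocab = {a + b: k for k, (a, b) in enumerate(product(AMINO_ACIDS, repeat=2))}
    out = np.zeros((len(dataset), 400), dtype=int)
    for i, w in enumerate(dataset):
        s = w.residues
        for p in range(len(s) - 1):
            if p == t or p + 1 == t:
                continue
            k = vocab.get(s[p : p + 2])
            if k is not None:
                out[i, k] = 1
    return out


def rank_residue_ig(dataset) -> RankedFeatures:
    """Rank the 20 residues by IG of off-center presence vs. the label."""
    X = _presence_matrix_residues(dataset)
    y = dataset.labels
    scores = [information_gain(X[:, j], y) for j in range(20)]
    return RankedFeatures.from_scores(list(AMINO_ACIDS), scores, method="ig")


def rank_dipeptide_ig(dataset) -> RankedFeatures:
    """Rank the 400 dipeptides by IG of off-center presence vs. the label."""
    X = _presence_matrix_dipeptides(dataset)
    y = dataset.labels
    names = [a + b for a, b in product(AMINO_ACIDS, repeat=2)]
    scores = [information_gain(X[:, j], y) for j in range(400)]
    return RankedFeatures.from_scores(names, scores, method="ig")


def rank_position_ig(dataset) -> RankedFeatures:
    """Rank the 2t off-center positions by IG of the class given the
    (21-category) residue identity at that position."""
    y = dataset.labels
    n = len(dataset)
    h_x = _entropy_bits(np.bincount(y, minlength=2) / n)
    t = dataset.t
    names, scores = [], []
    for p in range(2 * t + 1):
        if p == t:
            continue
        residues = np.array([w.residues[p] for w in dataset])
        h_cond = 0.0
        for r in np.unique(residues):
            mask = residues == r
            h_cond += (mask.sum() / n) * _entropy_bits(np.bincount(y[mask], minlength=2) / mask.sum())
        names.append(f"{p - t:+d}")
        scores.append(h_x - h_cond)
    return RankedFeatures.from_scores(names, scores, method="ig")


# --------------------------------------------------------------------
# MRMD
# --------------------------------------------------------------------

MRMD_VARIANTS = ("ed", "cos", "tc", "mean")


def mrmd_relevance(feature, labels) -> float:
    """Absolute Pearson correlation between a feature and the labels;
    a zero-variance feature gets relevance 0 with a warning."""
    f = np.asarray(feature, dtype=float)
    y = np.asarray(labels, dtype=float)
    if f.std() == 0.0 or y.std() == 0.0:
        warnings.warn("zero-variance input: relevance defined as 0")
        return 0.0
    return float(abs(np.corrcoef(f, y)[0, 1]))


def _safe_similarity(gram: np.ndarray, sq_norms: np.ndarray, kind: str) -> np.ndarray:
    """Pairwise cosine or Tanimoto similarity with zero-vector guards:
    two zero columns are identical (similarity 1); a zero against a
    non-zero column has similarity 0."""
    if kind == "cos":
        denom = np.sqrt(np.outer(sq_norms, sq_norms))
    else:  # tanimoto
        denom = sq_norms[:, None] + sq_norms[None, :] - gram
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(denom > 0, gram / np.where(denom > 0, denom, 1.0), 0.0)
    both_zero = (sq_norms[:, None] == 0) & (sq_norms[None, :] == 0)
    sim[both_zero] = 1.0
    return sim


def mrmd_distance(matrix: np.ndarray, variant: str = "ed", center: bool = False) -> np.ndarray:
    """Per-feature mean distance to every other feature column.

    Variants: ``ed`` Euclidean, ``cos`` 1 - cosine similarity, ``tc``
    1 - Tanimoto coefficient, ``mean`` the arithmetic mean of the three.

    With ``center=True`` columns are mean-centered first; cosine
    similarity of centered columns is the inter-feature Pearson
    correlation, which makes the angular variants informative on
    all-positive compositional data whose raw columns are nearly
    collinear.
    """
    X = np.asarray(matrix, dtype=float)
    if center:
        X = X - X.mean(axis=0, keepdims=True)
    m = X.shape[1]
    if m < 2:
        raise ValueError("MRMD distance needs at least 2 features")
    if variant not in MRMD_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {MRMD_VARIANTS}")
    gram = X.T @ X
    sq_norms = np.diag(gram).copy()
    off = ~np.eye(m, dtype=bool)

    def mean_off(d: np.ndarray) -> np.ndarray:
        return (d * off).sum(axis=1) / (m - 1)

    out = {}
    if variant in ("ed", "mean"):
        sq = np.maximum(sq_norms[:, None] + sq_norms[None, :] - 2 * gram, 0.0)
        out["ed"] = mean_off(np.sqrt(sq))
    if variant in ("cos", "mean"):
        out["cos"] = mean_off(1.0 - _safe_similarity(gram, sq_norms, "cos"))
    if variant in ("tc", "mean"):
        out["tc"] = mean_off(1.0 - _safe_similarity(gram, sq_norms, "tc"))
    if variant == "mean":
        return (out["ed"] + out["cos"] + out["tc"]) / 3.0
    return out[variant]


def mrmd_rank(matrix: np.ndarray, labels, variant: str = "ed",
              w_r: float = 1.0, w_d: float = 1.0,
              feature_names: list[str] | None = None,
              center: bool = False) -> RankedFeatures:
    """Stable descending ranking by ``w_r * relevance + w_d * distance``,
    the distances min-max scaled to [0, 1]."""
    X = np.asarray(matrix, dtype=float)
    names = feature_names if feature_names is not None else [f"f{i}" for i in range(X.shape[1])]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rel = np.array([mrmd_relevance(X[:, j], labels) for j in range(X.shape[1])])
    if (X.std(axis=0) == 0.0).any():
        warnings.warn("zero-variance feature(s): relevance set to 0")
    dist = mrmd_distance(X, variant=variant, center=center)
    span = dist.max() - dist.min()
    scaled = (dist - dist.min()) / span if span > 0 else np.zeros_like(dist)
    return RankedFeatures.from_scores(names, w_r * rel + w_d * scaled, method=f"mrmd-{variant}")


def residue_count_matrix(dataset) -> np.ndarray:
    """(n, 20) off-center occurrence counts of each residue per window."""
    t = dataset.t
    out = np.zeros((len(dataset), 20))
    for i, w in enumerate(dataset):
        seq = w.residues[:t] + w.residues[t + 1 :]
        for j, aa in enumerate(AMINO_ACIDS):
            out[i, j] = seq.count(aa)
    return out


def rank_residue_mrmd(dataset, variant: str = "ed",
                      w_r: float = 1.0, w_d: float = 1.0) -> RankedFeatures:
    """Rank the 20 residues by MRMD on their off-center occurrence
    counts, with columns centered so the angular distance variants see
    class structure rather than the shared compositional baseline."""
    X = residue_count_matrix(dataset)
    return mrmd_rank(X, dataset.labels, variant=variant, w_r=w_r, w_d=w_d,
                     feature_names=list(AMINO_ACIDS), center=True)


# --------------------------------------------------------------------
# incremental selection
# --------------------------------------------------------------------

@dataclass
class SelectionTrace:
    """Cross-validation performance as a function of feature dimension."""

    dims: list[int]
    metrics_at_dim: dict[int, "object"]  # dim -> EvalMetrics
    best_dim: int = field(init=False)

    def __post_init__(self):
        if not self.dims:
            raise ValueError("dims must be non-empty")
        if any(b <= a for a, b in zip(self.dims, self.dims[1:])):
            raise ValueError("dims must be strictly increasing")
        best = max(self.dims, key=lambda d: (self.metrics_at_dim[d].acc, -d))
        self.best_dim = best

    def to_rows(self) -> list[dict]:
        return [
            {"dim": d, "sn": m.sn, "sp": m.sp, "acc": m.acc, "mcc": m.mcc}
            for d, m in ((d, self.metrics_at_dim[d]) for d in self.dims)
        ]


def incremental_selection(ranked: RankedFeatures, evaluator, dims=None, max_dim: int | None = None) -> SelectionTrace:
    """Evaluate the top-``d`` ranked features for each ``d`` and pick the
    dimension maximizing accuracy (ties -> smallest).

    *evaluator* maps a dimension to an EvalMetrics-like object with an
    ``acc`` attribute and must be deterministic given its own seed.
    """
    if dims is None:
        dims = list(range(1, (max_dim or len(ranked.order)) + 1))
    dims = sorted(set(int(d) for d in dims))
    if not dims:
        raise ValueError("dims must be non-empty")
    metrics = {d: evaluator(d) for d in dims}
    return SelectionTrace(dims=dims, metrics_at_dim=metrics)


# --------------------------------------------------------------------
# sklearn-style selectors
# --------------------------------------------------------------------

class _RankingSelector(BaseEstimator, TransformerMixin):
    """Select the top-``k`` features of a fitted ranking, preserving the
    original column order among the selected (like ``SelectKBest``)."""

    def __init__(self, k: int | None = None):
        self.k = k

    def _rank(self, X, y) -> RankedFeatures:  # pragma: no cover - abstract
        raise NotImplementedError

    def fit(self, X, y):
        X = np.asarray(X)
        self.ranking_ = self._rank(X, y)
        k = X.shape[1] if self.k is None else min(self.k, X.shape[1])
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[self.ranking_.top(k)] = True
        return self

    def transform(self, X):
        return np.asarray(X)[:, self.support_]

    def get_support(self, indices: bool = False):
        return np.flatnonzero(self.support_) if indices else self.support_


class InformationGainSelector(_RankingSelector):
    """Top-``k`` features by information gain of presence (> threshold)
    against the binary label."""

    def __init__(self, k: int | None = None, threshold: float = 0.0):
        super().__init__(k=k)
        self.threshold = threshold

    def _rank(self, X, y) -> RankedFeatures:
        B = binarize_presence(X, self.threshold)
        scores = [information_gain(B[:, j], y) for j in range(X.shape[1])]
        return RankedFeatures.from_scores([f"f{i}" for i in range(X.shape[1])], scores, "ig")


class MRMDSelector(_RankingSelector):
    """Top-``k`` features by the MRMD combined relevance + distance score."""

    def __init__(self, k: int | None = None, variant: str = "ed",
                 w_r: float = 1.0, w_d: float = 1.0):
        super().__init__(k=k)
        self.variant = variant
        self.w_r = w_r
        self.w_d = w_d

    def _rank(self, X, y) -> RankedFeatures:
        return mrmd_rank(X, y, variant=self.variant, w_r=self.w_r, w_d=self.w_d)
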