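"""The end-to-end SNO-site classifier and its evaluation schemes.

:class:`SNOPredictor` is a scikit-learn classifier over raw window
strings: it featurizes (any subset of the nine encoders), optionally
reduces one feature block by IG or MRMD ranking, and fits a classifier
(default: standardized RBF-kernel SVM; published SNO predictors rarely
document their classifier configuration, so the slot is pluggable).

Evaluation covers the jackknife (leave-one-out), repeated stratified
k-fold, and independent-test protocols, reporting pooled confusion
counts per repeat plus mean and maximum summaries.  Supervised stages
(positional profiles, feature ranking, classifier) are refit on each
training fold by default; ``prefit_profiles=True`` instead fits the profile
encoders and ranking once on the full dataset before splitting, which
leaks label information but mirrors how profile-encoded predictors are
often evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.model_selection import GridSearchCV, LeaveOneOut, StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .encoders import ENCODER_ORDER, WindowFeaturizer
from .metrics import EvalMetrics, compute_metrics
from .selection import InformationGainSelector, MRMDSelector
from .windows import LabeledDataset

SELECTION_METHODS = ("none", "ig", "mrmd-ed", "mrmd-cos", "mrmd-tc", "mrmd-mean")


def default_classifier(param_grid: dict | None = None, random_state: int | None = None,
                       cv: int = 3):
    """Standardized RBF-SVM, optionally wrapped in a small grid search."""
    pipe = make_pipeline(StandardScaler(), SVC(C=10.0, gamma="scale", random_state=random_state))
    if param_grid:
        return GridSearchCV(pipe, param_grid, cv=cv, scoring="accuracy", n_jobs=1)
    return pipe


def small_svc_grid(n_features: int) -> dict:
    """The documented C / gamma grid for the default SVM."""
    return {"svc__C": [1.0, 10.0, 100.0],
            "svc__gamma": [1.0 / n_features, 0.01, 0.001]}


class SNOPredictor(BaseEstimator, ClassifierMixin):
    """Window-string classifier: featurize, (optionally) select, classify.

    Parameters
    ----------
    encoders : sequence of str
        Encoder blocks to concatenate (canonical order enforced).
    lam, w : PC-PseAAC parameters.
    selection : one of SELECTION_METHODS
        Ranking used to reduce ``selection_block``; ``"none"`` keeps the
        full matrix.
    selection_dim : int or None
        Number of top-ranked features kept inside the selected block
        (e.g. the published optimum keeps kmer2's top 180 of 400).
    selection_block : str or None
        Block to reduce; ``None`` ranks and reduces the whole matrix.
    classifier : estimator or None
        Any binary classifier with fit/predict; default is the
        standardized RBF-SVM.
    smoothing : float
        Laplace pseudocount for positional profiles.
    random_state : int or None
        Seed forwarded to the default classifier.
    """

    def __init__(self, encoders=ENCODER_ORDER, lam: int = 5, w: float = 0.5,
                 selection: str = "none", selection_dim: int | None = None,
                 selection_block: str | None = "kmer2", classifier=None,
                 smoothing: float = 0.0, random_state: int | None = None):
        self.encoders = tuple(encoders)
        self.lam = lam
        self.w = w
        self.selection = selection
        self.selection_dim = selection_dim
        self.selection_block = selection_block
        self.classifier = classifier
        self.smoothing = smoothing
        self.random_state = random_state

    # -- internals ----------------------------------------------------

    def _make_selector(self, k: int):
        if self.selection == "ig":
            return InformationGainSelector(k=k)
        variant = self.selection.split("-", 1)[1]
        return MRMDSelector(k=k, variant=variant)

    def _fit_columns(self, F: np.ndarray, y) -> np.ndarray:
        """Column indices kept after (optional) block-wise selection."""
        n_cols = F.shape[1]
        if self.selection == "none" or self.selection_dim is None:
            return np.arange(n_cols)
        if self.selection not in SELECTION_METHODS:
            raise ValueError(f"unknown selection {self.selection!r}; choose from {SELECTION_METHODS}")
        if self.selection_block is None:
            block = slice(0, n_cols)
        else:
            if self.selection_block not in self.featurizer_.blocks_:
                raise ValueError(f"selection_block {self.selection_block!r} not among fitted "
                                 f"blocks {list(self.featurizer_.blocks_)}")
            block = self.featurizer_.blocks_[self.selection_block]
        sel = self._make_selector(k=self.selection_dim).fit(F[:, block], y)
        keep_in_block = np.flatnonzero(sel.get_support()) + block.start
        self.block_ranking_ = sel.ranking_
        before = np.arange(block.start)
        after = np.arange(block.stop, n_cols)
        return np.concatenate([before, keep_in_block, after])

    # -- sklearn api --------------------------------------------------

    def fit(self, X, y):
        X = list(X)
        y = np.asarray(y, dtype=int)
        self.featurizer_ = WindowFeaturizer(
            encoders=self.encoders, lam=self.lam, w=self.w, smoothing=self.smoothing
        ).fit(X, y)
        F = self.featurizer_.transform(X)
        self.columns_ = self._fit_columns(F, y)
        self.n_features_in_ = F.shape[1]
        self.n_features_used_ = len(self.columns_)
        clf = self.classifier if self.classifier is not None else default_classifier(
            random_state=self.random_state
        )
        self.classifier_ = clone(clf).fit(F[:, self.columns_], y)
        self.classes_ = np.unique(y)
        return self

    def _matrix(self, X) -> np.ndarray:
        return self.featurizer_.transform(list(X))[:, self.columns_]

    def predict(self, X) -> np.ndarray:
        return self.classifier_.predict(self._matrix(X))

    def decision_function(self, X) -> np.ndarray:
        clf = self.classifier_
        if hasattr(clf, "decision_function"):
            return clf.decision_function(self._matrix(X))
        return clf.predict_proba(self._matrix(X))[:, 1]


# --------------------------------------------------------------------
# evaluation protocols
# --------------------------------------------------------------------

@dataclass
class CVResult:
    """Per-repeat pooled confusion counts plus mean / max summaries."""

    per_repeat: list[EvalMetrics]

    @property
    def mean(self) -> dict:
        keys = ("sn", "sp", "acc", "mcc")
        return {k: float(np.mean([getattr(m, k) for m in self.per_repeat])) for k in keys}

    @property
    def max(self) -> EvalMetrics:
        """The best repeat, by accuracy."""
        return max(self.per_repeat, key=lambda m: m.acc)

    def as_dict(self) -> dict:
        return {"per_repeat": [m.as_dict() for m in self.per_repeat],
                "mean": self.mean, "max": self.max.as_dict()}


def train_predict(train: LabeledDataset, test: LabeledDataset, estimator=None,
                  config: dict | None = None):
    """Fit on *train* only, apply to *test*; returns (scores, predictions,
    EvalMetrics).  Fully deterministic given the estimator's seed."""
    if train.t != test.t:
        raise ValueError(f"train t={train.t} differs from test t={test.t}")
    if estimator is None:
        estimator = predictor_from_config(config or {})
    est = clone(estimator).fit(train.sequences, train.labels)
    pred = est.predict(test.sequences)
    scores = est.decision_function(test.sequences)
    return scores, pred, compute_metrics(test.labels, pred)


def cross_validate(dataset: LabeledDataset, estimator=None, scheme: str = "kfold",
                   k: int = 10, repeats: int = 1, seed: int = 0,
                   prefit_profiles: bool = False, config: dict | None = None) -> CVResult:
    """Jackknife or repeated stratified k-fold evaluation.

    Confusion counts are pooled over the folds of each repeat.  By
    default every supervised stage is refit inside each training fold;
    ``prefit_profiles=True`` fits the featurizer and feature ranking once on
    the full dataset (label leakage — provided for comparability only).
    """
    if estimator is None:
        estimator = predictor_from_config(config or {})
    y = dataset.labels
    n = len(dataset)
    if scheme == "jackknife":
        splitters = [LeaveOneOut()]
    elif scheme == "kfold":
        if k > n:
            raise ValueError(f"k={k} exceeds dataset size {n}")
        splitters = [StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + r)
                     for r in range(repeats)]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    frozen = None
    if prefit_profiles:
        frozen = clone(estimator).fit(dataset.sequences, y)

    per_repeat = []
    for splitter in splitters:
        counts = EvalMetrics(0, 0, 0, 0)
        for train_idx, test_idx in splitter.split(np.zeros(n), y):
            if prefit_profiles:
                est = clone(estimator)
                est.featurizer_ = frozen.featurizer_
                est.columns_ = frozen.columns_
                F = frozen.featurizer_.transform([dataset.windows[i].residues for i in train_idx])
                clf = est.classifier if est.classifier is not None else default_classifier(
                    random_state=est.random_state)
                est.classifier_ = clone(clf).fit(F[:, frozen.columns_], y[train_idx])
                est.classes_ = np.unique(y[train_idx])
                pred = est.predict([dataset.windows[i].residues for i in test_idx])
            else:
                est = clone(estimator).fit(
                    [dataset.windows[i].residues for i in train_idx], y[train_idx])
                pred = est.predict([dataset.windows[i].residues for i in test_idx])
            counts = counts + compute_metrics(y[test_idx], pred)
        per_repeat.append(counts)
    return CVResult(per_repeat=per_repeat)


# --------------------------------------------------------------------
# strict config -> estimator
# --------------------------------------------------------------------

_CONFIG_KEYS = {"encoders", "lam", "w", "selection", "selection_dim", "selection_block",
                "classifier", "grid", "smoothing", "seed"}


def predictor_from_config(config: dict) -> SNOPredictor:
    """Build an :class:`SNOPredictor` from a flat config dict; unknown
    keys raise (strict schema)."""
    unknown = set(config) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
    seed = int(config.get("seed", 0))
    clf = None
    kind = config.get("classifier", "svc")
    if kind != "svc":
        raise ValueError(f"unknown classifier {kind!r} (built-in: 'svc'; pass an estimator "
                         "object to SNOPredictor for anything else)")
    if config.get("grid"):
        n_feat = 645  # scale gamma grid to the full feature dimension
        clf = default_classifier(param_grid=small_svc_grid(n_feat), random_state=seed)
    return SNOPredictor(
        encoders=tuple(config.get("encoders", ENCODER_ORDER)),
        lam=int(config.get("lam", 5)),
        w=float(config.get("w", 0.5)),
        selection=config.get("selection", "none"),
        selection_dim=config.get("selection_dim"),
        selection_block=config.get("selection_block", "kmer2"),
        classifier=clf,
        smoothing=float(config.get("smoothing", 0.0)),
        random_state=seed,
    )
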