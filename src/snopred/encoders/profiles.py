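"""Training-set-dependent positional profile encoders.

All five encoders here score a window against empirical per-position
residue (or residue-pair / residue-triplet) frequencies estimated
separately from the positive (SNO) and negative (non-SNO) training
windows:

* **BPB** — bi-profile Bayes: positive-class then negative-class
  posterior probability of the observed residue at each non-center
  position (length ``2 * 2t``).
* **ANBPB** — BPB with each positional frequency mapped through the
  standard normal CDF of its within-position z-score (length ``2 * 2t``).
* **DBPB** — adjacent-pair posteriors over the de-centered window
  (length ``2 * (2t - 1)``).
* **IAAPair** — adjacent and next-nearest pair posteriors over the
  *full* window (the center cysteine is kept), each entry the positive
  minus the negative posterior (length ``2t + (2t - 1)``).
* **PSTAAP** — adjacent-triplet positive-minus-negative posteriors over
  the de-centered window (length ``2t - 2``).

Pairs and triplets are indexed over the full 21-letter alphabet
(including the dummy ``X``), so padded flanks are first-class events.
Frequencies are raw empirical proportions; optional Laplace (+1)
smoothing is available for downstream classifiers that dislike zeros.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy.stats import norm
from sklearn.base import BaseEstimator, TransformerMixin

from ..alphabet import WINDOW_ALPHABET, WINDOW_INDEX

A = len(WINDOW_ALPHABET)  # 21


def _codes(sequences: list[str]) -> np.ndarray:
    """(n, length) int array of alphabet codes."""
    try:
        return np.array([[WINDOW_INDEX[ch] for ch in s] for s in sequences], dtype=np.int32)
    except KeyError as e:
        raise ValueError(f"illegal residue {e.args[0]!r} in window") from None


def _position_tables(codes: np.ndarray, order: int, smoothing: float) -> np.ndarray:
    """Empirical k-tuple frequencies: (n_positions, A**order) table.

    Position ``p`` tabulates the tuple starting at column ``p``.
    """
    n, length = codes.shape
    n_pos = length - order + 1
    table = np.zeros((n_pos, A**order))
    for p in range(n_pos):
        idx = np.zeros(n, dtype=np.int64)
        for o in range(order):
            idx = idx * A + codes[:, p + o]
        np.add.at(table[p], idx, 1.0)
    table += smoothing
    table /= table.sum(axis=1, keepdims=True)
    return table


def _gapped_pair_tables(codes: np.ndarray, gap: int, smoothing: float) -> np.ndarray:
    """Pair frequencies for residues ``gap + 1`` apart: (n_pos, A**2)."""
    n, length = codes.shape
    n_pos = length - gap - 1
    table = np.zeros((n_pos, A * A))
    for p in range(n_pos):
        idx = codes[:, p].astype(np.int64) * A + codes[:, p + gap + 1]
        np.add.at(table[p], idx, 1.0)
    table += smoothing
    table /= table.sum(axis=1, keepdims=True)
    return table


class PositionalProfile:
    """Per-position residue / pair / triplet probability tables for the
    positive and negative classes of a labeled window dataset.

    Attributes (each a dict ``{1: table, 0: table}``):

    - ``singles`` — (2t, 21): de-centered single-residue frequencies;
    - ``pairs_dec`` — (2t-1, 441): de-centered adjacent pairs;
    - ``pairs0`` — (2t, 441): full-window adjacent pairs;
    - ``pairs1`` — (2t-1, 441): full-window next-nearest pairs;
    - ``triples`` — (2t-2, 9261): de-centered adjacent triplets.
    """

    def __init__(self, t: int, singles, pairs_dec, pairs0, pairs1, triples, counts):
        self.t = t
        self.singles = singles
        self.pairs_dec = pairs_dec
        self.pairs0 = pairs0
        self.pairs1 = pairs1
        self.triples = triples
        self.counts = counts  # {1: n_pos, 0: n_neg}

    @classmethod
    def from_data(cls, sequences: list[str], labels, smoothing: float = 0.0) -> "PositionalProfile":
        """Fit empirical profiles; requires both classes present."""
        labels = np.asarray(labels, dtype=int)
        if len(sequences) != len(labels):
            raise ValueError("sequences and labels must have equal length")
        lengths = {len(s) for s in sequences}
        if len(lengths) != 1:
            raise ValueError(f"all windows must share one length, got {sorted(lengths)}")
        (length,) = lengths
        if length % 2 == 0:
            raise ValueError(f"window length must be odd, got {length}")
        t = (length - 1) // 2
        counts = {c: int((labels == c).sum()) for c in (0, 1)}
        if counts[0] == 0 or counts[1] == 0:
            raise ValueError("profiles need at least one window of each class")

        full = _codes(list(sequences))
        dec = np.concatenate([full[:, :t], full[:, t + 1 :]], axis=1)
        singles, pairs_dec, pairs0, pairs1, triples = {}, {}, {}, {}, {}
        for c in (0, 1):
            m = labels == c
            singles[c] = _position_tables(dec[m], 1, smoothing)
            pairs_dec[c] = _position_tables(dec[m], 2, smoothing)
            pairs0[c] = _position_tables(full[m], 2, smoothing)
            pairs1[c] = _gapped_pair_tables(full[m], 1, smoothing)
            triples[c] = _position_tables(dec[m], 3, smoothing)
        return cls(t, singles, pairs_dec, pairs0, pairs1, triples, counts)

    # -- serialization (sparse: empirical tables are mostly zeros) -----

    _TABLES = ("singles", "pairs_dec", "pairs0", "pairs1", "triples")

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {"alphabet": WINDOW_ALPHABET, "t": self.t,
               "counts": {str(k): v for k, v in self.counts.items()}}
        for name in self._TABLES:
            tabs = getattr(self, name)
            doc[name] = {
                str(c): [
                    {str(j): tabs[c][p, j] for j in np.nonzero(tabs[c][p])[0]}
                    for p in range(tabs[c].shape[0])
                ]
                for c in (0, 1)
            }
        text = json.dumps(doc)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PositionalProfile":
        text = Path(source).read_text() if Path(str(source)[:200]).exists() else str(source)
        doc = json.loads(text)
        if doc["alphabet"] != WINDOW_ALPHABET:
            raise ValueError("profile alphabet mismatch")
        t = doc["t"]
        widths = {"singles": A, "pairs_dec": A * A, "pairs0": A * A,
                  "pairs1": A * A, "triples": A**3}
        kwargs = {}
        for name in cls._TABLES:
            tabs = {}
            for c in (0, 1):
                rows = doc[name][str(c)]
                arr = np.zeros((len(rows), widths[name]))
                for p, row in enumerate(rows):
                    for j, v in row.items():
                        arr[p, int(j)] = v
                tabs[c] = arr
            kwargs[name] = tabs
        counts = {int(k): v for k, v in doc["counts"].items()}
        return cls(t, counts=counts, **kwargs)


def fit_positional_profiles(train, smoothing: float = 0.0) -> PositionalProfile:
    """Fit a :class:`PositionalProfile` from a LabeledDataset."""
    return PositionalProfile.from_data(train.sequences, train.labels, smoothing=smoothing)


class _ProfileEncoderBase(BaseEstimator, TransformerMixin):
    """Shared fit/validation for the five profile encoders.

    A pre-fitted profile may be injected (``profile=``) so several
    encoders can share one estimation pass; otherwise ``fit`` computes
    it from the training windows and labels.
    """

    def __init__(self, profile: PositionalProfile | None = None, smoothing: float = 0.0):
        self.profile = profile
        self.smoothing = smoothing

    def fit(self, X, y=None):
        if self.profile is not None:
            self.profile_ = self.profile
        else:
            if y is None:
                raise ValueError(f"{type(self).__name__} requires labels to fit")
            self.profile_ = PositionalProfile.from_data(list(X), y, smoothing=self.smoothing)
        self._post_fit()
        return self

    def _post_fit(self):
        pass

    def _check(self, X) -> np.ndarray:
        codes = _codes(list(X))
        expected = 2 * self.profile_.t + 1
        if codes.shape[1] != expected:
            raise ValueError(
                f"window length {codes.shape[1]} does not match profile t={self.profile_.t} "
                f"(expected {expected})"
            )
        return codes

    @staticmethod
    def _decenter(codes: np.ndarray, t: int) -> np.ndarray:
        return np.concatenate([codes[:, :t], codes[:, t + 1 :]], axis=1)


def _gather(table: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """table: (n_pos, vocab); idx: (n, n_pos) -> (n, n_pos)."""
    return table[np.arange(idx.shape[1])[None, :], idx]


def _pair_idx(codes: np.ndarray, gap: int) -> np.ndarray:
    return codes[:, : codes.shape[1] - gap - 1].astype(np.int64) * A + codes[:, gap + 1 :]


def _triple_idx(codes: np.ndarray) -> np.ndarray:
    return (codes[:, :-2].astype(np.int64) * A + codes[:, 1:-1]) * A + codes[:, 2:]


class BPBEncoder(_ProfileEncoderBase):
    """Bi-profile Bayes: per-position residue posteriors, positive block
    then negative block; length ``4t`` (t=10 -> 40)."""

    def transform(self, X) -> np.ndarray:
        codes = self._decenter(self._check(X), self.profile_.t)
        pos = _gather(self.profile_.singles[1], codes)
        neg = _gather(self.profile_.singles[0], codes)
        return np.hstack([pos, neg])

    def get_feature_names_out(self, input_features=None):
        offs = _offset_names(self.profile_.t)
        return np.array([f"bpb_pos_{o}" for o in offs] + [f"bpb_neg_{o}" for o in offs])


class ANBPBEncoder(_ProfileEncoderBase):
    """Adapted-normal-distribution BPB: each positional frequency f is
    replaced by Φ((f - mean) / sd), mean and sd taken over the 21
    letter-frequencies at that position within the class (sd = 0 maps
    to Φ(0) = 0.5); length ``4t``."""

    def _post_fit(self):
        self.tables_ = {}
        for c in (0, 1):
            tab = self.profile_.singles[c]
            mean = tab.mean(axis=1, keepdims=True)
            sd = tab.std(axis=1, keepdims=True)
            ok = sd > 1e-12  # exactly-uniform positions: z := 0 -> Phi(0) = 0.5
            z = np.where(ok, (tab - mean) / np.where(ok, sd, 1.0), 0.0)
            self.tables_[c] = norm.cdf(z)

    def transform(self, X) -> np.ndarray:
        codes = self._decenter(self._check(X), self.profile_.t)
        return np.hstack([_gather(self.tables_[1], codes), _gather(self.tables_[0], codes)])

    def get_feature_names_out(self, input_features=None):
        offs = _offset_names(self.profile_.t)
        return np.array([f"anbpb_pos_{o}" for o in offs] + [f"anbpb_neg_{o}" for o in offs])


class DBPBEncoder(_ProfileEncoderBase):
    """Double BPB: adjacent-pair posteriors over the de-centered window,
    positive block then negative block; length ``2(2t - 1)`` (t=10 -> 38)."""

    def transform(self, X) -> np.ndarray:
        codes = self._decenter(self._check(X), self.profile_.t)
        idx = _pair_idx(codes, gap=0)
        return np.hstack([_gather(self.profile_.pairs_dec[1], idx),
                          _gather(self.profile_.pairs_dec[0], idx)])

    def get_feature_names_out(self, input_features=None):
        n = 2 * self.profile_.t - 1
        return np.array([f"dbpb_pos_p{i}" for i in range(n)] + [f"dbpb_neg_p{i}" for i in range(n)])


class IAAPairEncoder(_ProfileEncoderBase):
    """Pairwise propensity over the *full* window (center cysteine
    retained): adjacent pairs (2t positions) then next-nearest pairs
    (2t - 1 positions), each entry positive minus negative posterior;
    length ``4t - 1`` (t=10 -> 39), values in [-1, 1]."""

    def transform(self, X) -> np.ndarray:
        codes = self._check(X)
        i0 = _pair_idx(codes, gap=0)
        i1 = _pair_idx(codes, gap=1)
        adj = _gather(self.profile_.pairs0[1], i0) - _gather(self.profile_.pairs0[0], i0)
        nxt = _gather(self.profile_.pairs1[1], i1) - _gather(self.profile_.pairs1[0], i1)
        return np.hstack([adj, nxt])

    def get_feature_names_out(self, input_features=None):
        t = self.profile_.t
        return np.array([f"iaapair_adj_p{i}" for i in range(2 * t)]
                        + [f"iaapair_gap1_p{i}" for i in range(2 * t - 1)])


class PSTAAPEncoder(_ProfileEncoderBase):
    """Position-specific tri-amino-acid propensity: adjacent-triplet
    positive-minus-negative posteriors over the de-centered window;
    length ``2t - 2`` (t=10 -> 18), values in [-1, 1]."""

    def transform(self, X) -> np.ndarray:
        codes = self._decenter(self._check(X), self.profile_.t)
        idx = _triple_idx(codes)
        return _gather(self.profile_.triples[1], idx) - _gather(self.profile_.triples[0], idx)

    def get_feature_names_out(self, input_features=None):
        return np.array([f"pstaap_p{i}" for i in range(2 * self.profile_.t - 2)])


def _offset_names(t: int) -> list[str]:
    return [f"{o:+d}" for o in range(-t, t + 1) if o != 0]
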