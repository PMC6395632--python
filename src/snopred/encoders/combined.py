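"""Combined window featurizer with named, contiguous feature blocks.

``WindowFeaturizer`` concatenates any subset of the nine encoders in
the canonical order

    pcpseaac, kmer1, kmer2, pcpseaac-g, anbpb, dbpb, bpb, iaapair, pstaap

which at ``t = 10`` and ``lam = 5`` yields a 645-dimensional vector with
block sizes 25 / 20 / 400 / 25 / 40 / 38 / 40 / 39 / 18.  Profile
encoders share a single :class:`PositionalProfile` estimated once per
``fit``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ..indices import PhysicochemicalIndexSet
from .composition import KmerEncoder, PseAACEncoder
from .profiles import (
    ANBPBEncoder,
    BPBEncoder,
    DBPBEncoder,
    IAAPairEncoder,
    PositionalProfile,
    PSTAAPEncoder,
)

ENCODER_ORDER: tuple[str, ...] = (
    "pcpseaac", "kmer1", "kmer2", "pcpseaac-g",
    "anbpb", "dbpb", "bpb", "iaapair", "pstaap",
)
PROFILE_ENCODERS = frozenset({"anbpb", "dbpb", "bpb", "iaapair", "pstaap"})


class WindowFeaturizer(BaseEstimator, TransformerMixin):
    """Transform window strings into the concatenated feature matrix.

    Parameters
    ----------
    encoders : sequence of str
        Encoder names to include; always applied in canonical order.
    lam, w : PC-PseAAC correlation depth and weight.
    indices : PhysicochemicalIndexSet, optional
        Index set for the general-mode PC-PseAAC (default: packaged
        three-table set, which makes the two modes coincide).
    smoothing : float
        Optional Laplace pseudocount for the positional profiles.

    Attributes
    ----------
    blocks_ : dict[str, slice]
        Encoder name -> contiguous column range in the output matrix.
    profile_ : PositionalProfile or None
        Shared positional profile (present iff a profile encoder is used).
    """

    def __init__(self, encoders=ENCODER_ORDER, lam: int = 5, w: float = 0.5,
                 indices: PhysicochemicalIndexSet | None = None, smoothing: float = 0.0):
        self.encoders = tuple(encoders)
        self.lam = lam
        self.w = w
        self.indices = indices
        self.smoothing = smoothing

    def _make(self, name: str, profile: PositionalProfile | None):
        if name == "pcpseaac":
            return PseAACEncoder(lam=self.lam, w=self.w, mode="pcpseaac3")
        if name == "pcpseaac-g":
            return PseAACEncoder(lam=self.lam, w=self.w, mode="general", indices=self.indices)
        if name == "kmer1":
            return KmerEncoder(k=1)
        if name == "kmer2":
            return KmerEncoder(k=2)
        cls = {"bpb": BPBEncoder, "anbpb": ANBPBEncoder, "dbpb": DBPBEncoder,
               "iaapair": IAAPairEncoder, "pstaap": PSTAAPEncoder}.get(name)
        if cls is None:
            raise ValueError(f"unknown encoder {name!r}; choose from {ENCODER_ORDER}")
        return cls(profile=profile, smoothing=self.smoothing)

    def fit(self, X, y=None):
        unknown = set(self.encoders) - set(ENCODER_ORDER)
        if unknown:
            raise ValueError(f"unknown encoder(s) {sorted(unknown)}; choose from {ENCODER_ORDER}")
        X = list(X)
        names = [n for n in ENCODER_ORDER if n in self.encoders]
        self.profile_ = None
        if PROFILE_ENCODERS & set(names):
            if y is None:
                raise ValueError("profile encoders require labels to fit")
            self.profile_ = PositionalProfile.from_data(X, y, smoothing=self.smoothing)
        self.encoders_: dict[str, BaseEstimator] = {}
        self.blocks_: dict[str, slice] = {}
        self.feature_names_: list[str] = []
        start = 0
        for name in names:
            enc = self._make(name, self.profile_).fit(X, y)
            width = len(enc.get_feature_names_out())
            self.encoders_[name] = enc
            self.blocks_[name] = slice(start, start + width)
            self.feature_names_.extend(f"{name}:{f}" for f in enc.get_feature_names_out())
            start += width
        self.n_features_out_ = start
        return self

    def transform(self, X) -> np.ndarray:
        X = list(X)
        return np.hstack([self.encoders_[n].transform(X) for n in self.encoders_])

    def get_feature_names_out(self, input_features=None):
        return np.array(self.feature_names_)

    def block_sizes(self) -> dict[str, int]:
        return {n: s.stop - s.start for n, s in self.blocks_.items()}
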