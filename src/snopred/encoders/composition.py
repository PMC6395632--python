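"""Composition and sequence-order encoders.

Two families live here:

* **PC-PseAAC** — parallel-correlation pseudo amino acid composition:
  20 normalized amino-acid frequencies plus ``lam`` tier-correlation
  terms, each tier averaging the squared physicochemical difference
  between residues that many positions apart, weighted by ``w``.  The
  three-index mode uses hydrophobicity, hydrophilicity and side-chain
  mass; the general mode averages over any user-supplied index set.
* **kmer** — normalized occurrence frequencies of length-``k``
  substrings over the 20-amino-acid alphabet (k=1: 20 features,
  k=2: 400).

The dummy residue ``X`` carries no physicochemical values and is not
part of the composition alphabet: occurrences of ``X`` are excluded
from frequency counts, and residue pairs containing ``X`` are skipped
in the tier correlations (the tier mean is taken over the pairs
actually evaluated).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ..alphabet import AA_INDEX, AMINO_ACIDS
from ..indices import PhysicochemicalIndexSet, default_indices


@dataclass(frozen=True)
class PseAACParams:
    """PC-PseAAC hyperparameters: correlation depth ``lam`` (λ ≥ 0) and
    sequence-order weight ``w`` in [0, 1].  λ must stay below the
    effective (non-X) sequence length."""

    lam: int = 5
    w: float = 0.5

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError(f"lam must be >= 0, got {self.lam}")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError(f"w must lie in [0, 1], got {self.w}")


def theta_correlation(
    r_i: str, r_j: str, indices: PhysicochemicalIndexSet, mode: str = "pcpseaac3"
) -> float:
    """Squared-difference correlation Θ(R_i, R_j) between two residues.

    ``pcpseaac3`` averages the squared differences of standardized
    hydrophobicity, hydrophilicity and side-chain mass; ``general``
    averages over all indices in *indices*.  Symmetric and >= 0.
    """
    if indices.standardized is None:
        raise ValueError("indices must be standardized")
    if mode == "pcpseaac3" and len(indices.names) != 3:
        raise ValueError("pcpseaac3 mode requires exactly 3 indices")
    elif mode not in ("pcpseaac3", "general"):
        raise ValueError(f"unknown mode {mode!r}")
    total = 0.0
    for name in indices.names:
        tab = indices.standardized[name]
        total += (tab[r_i] - tab[r_j]) ** 2
    return total / len(indices.names)


def _tier_factors(sequence: str, lam: int, theta_matrix: np.ndarray) -> np.ndarray:
    """Θ_1..Θ_lam over *sequence*; pairs containing X are skipped and
    each tier is the mean over its evaluated pairs (0 if none)."""
    codes = np.array([AA_INDEX.get(ch, -1) for ch in sequence])
    thetas = np.zeros(lam)
    for j in range(1, lam + 1):
        a, b = codes[:-j], codes[j:]
        mask = (a >= 0) & (b >= 0)
        if mask.any():
            thetas[j - 1] = theta_matrix[a[mask], b[mask]].mean()
    return thetas


def _theta_matrix(indices: PhysicochemicalIndexSet) -> np.ndarray:
    """Pairwise Θ over the 20 amino acids as a (20, 20) array."""
    H = indices.standardized_matrix()  # (mu, 20)
    diff = H[:, :, None] - H[:, None, :]
    return (diff**2).mean(axis=0)


def _aa_frequencies(sequence: str) -> np.ndarray:
    counts = np.zeros(20)
    for ch in sequence:
        i = AA_INDEX.get(ch)
        if i is not None:
            counts[i] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("sequence contains no standard amino acid (all X?)")
    return counts / total


def encode_pc_pseaac(
    sequence: str,
    params: PseAACParams | None = None,
    indices: PhysicochemicalIndexSet | None = None,
    mode: str = "pcpseaac3",
) -> np.ndarray:
    """PC-PseAAC vector of length ``20 + lam`` for one sequence.

    Entries 1–20 are the normalized amino-acid frequencies and entries
    21–20+λ the weighted tier correlations, all divided by the common
    denominator ``Σf + w·ΣΘ`` so the vector sums to 1.
    """
    params = params or PseAACParams()
    if indices is None:
        indices = default_indices()
    if mode == "pcpseaac3" and len(indices.names) != 3:
        raise ValueError("pcpseaac3 mode requires exactly 3 indices")
    L_eff = sum(1 for ch in sequence if ch in AA_INDEX)
    if params.lam >= L_eff:
        raise ValueError(f"lam={params.lam} must be < effective length {L_eff}")
    f = _aa_frequencies(sequence)
    thetas = _tier_factors(sequence, params.lam, _theta_matrix(indices))
    denom = f.sum() + params.w * thetas.sum()
    return np.concatenate([f, params.w * thetas]) / denom


def _kmer_vocab(k: int) -> list[str]:
    return ["".join(p) for p in product(AMINO_ACIDS, repeat=k)]


def encode_kmer(sequence: str, k: int = 1) -> np.ndarray:
    """Frequencies of the ``20**k`` k-mers among the X-free k-mers of
    *sequence*; entries sum to 1."""
    if k not in (1, 2):
        raise ValueError(f"k must be 1 or 2, got {k}")
    counts = np.zeros(20**k)
    n = 0
    for i in range(len(sequence) - k + 1):
        kmer = sequence[i : i + k]
        idx = 0
        for ch in kmer:
            j = AA_INDEX.get(ch)
            if j is None:
                break
            idx = idx * 20 + j
        else:
            counts[idx] += 1
            n += 1
    if n == 0:
        raise ValueError(f"sequence has no X-free {k}-mer")
    return counts / n


class PseAACEncoder(BaseEstimator, TransformerMixin):
    """Stateless transformer: window strings -> PC-PseAAC vectors.

    Parameters
    ----------
    lam, w : see :class:`PseAACParams`.
    mode : {"pcpseaac3", "general"}
        Index handling; both use the packaged three-table set unless
        *indices* overrides it.
    indices : PhysicochemicalIndexSet, optional
        User index set (standardized internally if raw).
    """

    def __init__(self, lam: int = 5, w: float = 0.5, mode: str = "pcpseaac3",
                 indices: PhysicochemicalIndexSet | None = None):
        self.lam = lam
        self.w = w
        self.mode = mode
        self.indices = indices

    def fit(self, X, y=None):
        from ..indices import standardize_indices

        idx = self.indices if self.indices is not None else default_indices()
        if idx.standardized is None:
            idx = standardize_indices(idx)
        self.indices_ = idx
        self.theta_matrix_ = _theta_matrix(idx)
        self.n_features_out_ = 20 + self.lam
        return self

    def transform(self, X) -> np.ndarray:
        params = PseAACParams(lam=self.lam, w=self.w)
        out = np.empty((len(X), self.n_features_out_))
        for i, seq in enumerate(X):
            L_eff = sum(1 for ch in seq if ch in AA_INDEX)
            if params.lam >= L_eff:
                raise ValueError(f"lam={params.lam} must be < effective length {L_eff}")
            f = _aa_frequencies(seq)
            thetas = _tier_factors(seq, params.lam, self.theta_matrix_)
            denom = f.sum() + params.w * thetas.sum()
            out[i] = np.concatenate([f, params.w * thetas]) / denom
        return out

    def get_feature_names_out(self, input_features=None):
        return np.array(
            [f"f_{aa}" for aa in AMINO_ACIDS] + [f"theta_{j}" for j in range(1, self.lam + 1)]
        )


class KmerEncoder(BaseEstimator, TransformerMixin):
    """Stateless transformer: window strings -> k-mer frequency vectors."""

    def __init__(self, k: int = 1):
        self.k = k

    def fit(self, X, y=None):
        if self.k not in (1, 2):
            raise ValueError(f"k must be 1 or 2, got {self.k}")
        self.vocab_ = _kmer_vocab(self.k)
        self.n_features_out_ = 20**self.k
        return self

    def transform(self, X) -> np.ndarray:
        return np.vstack([encode_kmer(seq, self.k) for seq in X])

    def get_feature_names_out(self, input_features=None):
        return np.array(self.vocab_)
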