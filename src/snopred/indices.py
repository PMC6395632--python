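"""Physicochemical amino-acid index tables and their standardization.

Pseudo amino acid composition correlates residues through
physicochemical indices.  Before use, each index is centered on its
20-amino-acid mean and divided by the population (÷20) root-mean-square
deviation, so standardized values have zero mean and unit mean square.

The packaged defaults are the three tables of Chou's original PseAAC:
hydrophobicity, hydrophilicity (Hopp–Woods) and side-chain mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .alphabet import AMINO_ACIDS

DEFAULT_INDEX_NAMES = ("hydrophobicity", "hydrophilicity", "side_chain_mass")


@dataclass
class PhysicochemicalIndexSet:
    """A named collection of per-amino-acid index values.

    Attributes
    ----------
    names : list of str
        Index names, in order.
    raw : dict
        ``name -> {amino acid -> raw value}``; each index covers exactly
        the 20 standard amino acids.
    standardized : dict or None
        Same shape after standardization (zero mean, unit mean square
        over the 20 amino acids), or ``None`` before
        :func:`standardize_indices` has run.
    """

    names: list[str]
    raw: dict[str, dict[str, float]]
    standardized: dict[str, dict[str, float]] | None = field(default=None)

    def __post_init__(self):
        for name in self.names:
            missing = set(AMINO_ACIDS) - set(self.raw[name])
            extra = set(self.raw[name]) - set(AMINO_ACIDS)
            if missing or extra:
                raise ValueError(
                    f"index {name!r} must cover exactly the 20 standard amino acids "
                    f"(missing {sorted(missing)}, extra {sorted(extra)})"
                )

    def standardized_matrix(self) -> np.ndarray:
        """Standardized values as an (n_indices, 20) array, AA order fixed."""
        if self.standardized is None:
            raise RuntimeError("call standardize_indices() first")
        return np.array(
            [[self.standardized[n][aa] for aa in AMINO_ACIDS] for n in self.names]
        )


def standardize_indices(raw: PhysicochemicalIndexSet) -> PhysicochemicalIndexSet:
    """Standardize each index: subtract the 20-AA mean, divide by the
    population RMS deviation.  Raw values are retained alongside.

    Raises on a constant (zero-variance) index.
    """
    std: dict[str, dict[str, float]] = {}
    for name in raw.names:
        values = np.array([raw.raw[name][aa] for aa in AMINO_ACIDS], dtype=float)
        centered = values - values.mean()
        rms = np.sqrt(np.mean(centered**2))
        if rms == 0.0:
            raise ValueError(f"degenerate index {name!r}: zero variance over the 20 amino acids")
        std[name] = dict(zip(AMINO_ACIDS, centered / rms))
    return PhysicochemicalIndexSet(names=list(raw.names), raw=dict(raw.raw), standardized=std)


def load_index_table(path: str | Path) -> PhysicochemicalIndexSet:
    """Load a user index table: TSV with an ``aa`` column plus one
    numeric column per index (or the two-column ``aa<TAB>value`` form).
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] == 2 and df.columns[1] != "aa":
        df.columns = ["aa", Path(path).stem]
    names = [c for c in df.columns if c != "aa"]
    raw = {name: dict(zip(df["aa"], df[name].astype(float))) for name in names}
    return PhysicochemicalIndexSet(names=names, raw=raw)


def default_indices(standardize: bool = True) -> PhysicochemicalIndexSet:
    """The packaged hydrophobicity / hydrophilicity / side-chain-mass set."""
    with resources.as_file(resources.files("snopred.data") / "pse_indices.tsv") as p:
        idx = load_index_table(p)
    return standardize_indices(idx) if standardize else idx
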