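"""Cysteine-centered peptide windows and labeled window datasets.

A window is a ``2t + 1``-residue string centered on a cysteine; flanks
that fall outside the source protein are padded with the dummy residue
``X``.  The default half-width is ``t = 10`` (21-mer windows), the
convention used throughout SNO-site prediction work.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import DUMMY, WINDOW_INDEX, sanitize

log = logging.getLogger(__name__)

DEFAULT_T = 10


@dataclass(frozen=True)
class PeptideWindow:
    """A fixed-length residue window centered on a cysteine.

    Parameters
    ----------
    residues : str
        Window string of odd length ``2t + 1`` over the 21-letter
        alphabet (20 amino acids + dummy ``X``).
    label : int or None
        1 for an S-nitrosylated center, 0 for a non-SNO center, ``None``
        if unlabeled.
    source_id : str or None
        Accession of the source protein, when known.
    site_position : int or None
        1-based position of the center cysteine in the source protein.
    """

    residues: str
    label: int | None = None
    source_id: str | None = None
    site_position: int | None = None

    @property
    def t(self) -> int:
        return (len(self.residues) - 1) // 2

    @property
    def center(self) -> str:
        return self.residues[self.t]

    def decentered(self) -> str:
        """The window with its center residue removed (2t residues)."""
        t = self.t
        return self.residues[:t] + self.residues[t + 1 :]


def validate_window(window: PeptideWindow | str, strict_center: bool = True) -> tuple[bool, list[str]]:
    """Check the window invariants; return ``(ok, diagnostics)``.

    Invariants: odd length, all characters in the 21-letter alphabet,
    and (in strict mode) center residue ``C``.
    """
    residues = window.residues if isinstance(window, PeptideWindow) else window
    diagnostics: list[str] = []
    if len(residues) % 2 == 0 or len(residues) < 3:
        diagnostics.append(f"length {len(residues)} is not an odd number >= 3")
    illegal = sorted({ch for ch in residues if ch not in WINDOW_INDEX})
    if illegal:
        diagnostics.append(f"illegal residue(s): {', '.join(illegal)}")
    if strict_center and len(residues) % 2 == 1 and residues[len(residues) // 2] != "C":
        diagnostics.append(f"center residue is {residues[len(residues) // 2]!r}, not 'C'")
    return (not diagnostics), diagnostics


def extract_windows(protein_sequence: str, t: int = DEFAULT_T, source_id: str | None = None) -> list[PeptideWindow]:
    """Extract one window per cysteine in *protein_sequence*.

    Each window spans positions ``-t .. +t`` around a cysteine;
    positions beyond the protein ends are filled with ``X``.  Windows
    are returned in order of cysteine position (1-based site recorded).
    Non-standard letters (B, Z, U, O, ``*`` ...) are mapped to ``X``
    with a warning.
    """
    if not protein_sequence:
        raise ValueError("protein sequence must be non-empty")
    if t < 1:
        raise ValueError(f"window half-width t must be >= 1, got {t}")
    seq, remapped = sanitize(protein_sequence)
    if remapped:
        log.warning("non-standard letters %s mapped to X in %s", sorted(remapped), source_id or "<sequence>")
    padded = DUMMY * t + seq + DUMMY * t
    out = []
    for i, ch in enumerate(seq):
        if ch == "C":
            out.append(
                PeptideWindow(
                    residues=padded[i : i + 2 * t + 1],
                    source_id=source_id,
                    site_position=i + 1,
                )
            )
    return out


class LabeledDataset:
    """An ordered collection of equal-length labeled peptide windows."""

    def __init__(self, windows: Sequence[PeptideWindow]):
        windows = list(windows)
        if not windows:
            raise ValueError("dataset must contain at least one window")
        length = len(windows[0].residues)
        for i, w in enumerate(windows):
            if len(w.residues) != length:
                raise ValueError(
                    f"row {i}: window length {len(w.residues)} differs from {length}"
                )
            if w.label not in (0, 1):
                raise ValueError(f"row {i}: missing or non-binary label {w.label!r}")
        self.windows: list[PeptideWindow] = windows
        self.t: int = (length - 1) // 2

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    def __eq__(self, other) -> bool:
        return isinstance(other, LabeledDataset) and self.windows == other.windows

    @property
    def sequences(self) -> list[str]:
        return [w.residues for w in self.windows]

    @property
    def labels(self) -> np.ndarray:
        return np.asarray([w.label for w in self.windows], dtype=int)

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_negative(self) -> int:
        return len(self) - self.n_positive

    def subset(self, idx: Iterable[int]) -> "LabeledDataset":
        return LabeledDataset([self.windows[i] for i in idx])


def _parse_label(token: str, row: int) -> int:
    token = token.strip()
    if token in {"0", "1"}:
        return int(token)
    raise ValueError(f"row {row}: unknown label token {token!r} (expected 0 or 1)")


def load_dataset(path: str | Path, format: str = "tsv", strict_center: bool = True) -> LabeledDataset:
    """Load a labeled window dataset from ``tsv`` or ``fasta-pair`` format.

    TSV: two columns ``peptide<TAB>label`` with an optional header line.
    fasta-pair: FASTA records whose headers carry ``|label=0`` or
    ``|label=1``.
    """
    path = Path(path)
    windows: list[PeptideWindow] = []
    if format == "tsv":
        with open(path) as fh:
            for row, line in enumerate(fh):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"row {row}: expected 'peptide<TAB>label', got {line!r}")
                pep, lab = parts[0].strip().upper(), parts[1]
                if row == 0 and lab.strip() not in {"0", "1"}:
                    continue  # header line
                windows.append(PeptideWindow(residues=pep, label=_parse_label(lab, row)))
    elif format == "fasta-pair":
        for rec in SeqIO.parse(str(path), "fasta"):
            desc = rec.description
            if "label=1" in desc:
                label = 1
            elif "label=0" in desc:
                label = 0
            else:
                raise ValueError(f"record {rec.id}: header lacks |label=0/1")
            windows.append(
                PeptideWindow(residues=str(rec.seq).upper(), label=label, source_id=rec.id.split("|")[0])
            )
    else:
        raise ValueError(f"unknown format {format!r}")

    if not windows:
        raise ValueError(f"{path}: no records found")
    length = len(windows[0].residues)
    for i, w in enumerate(windows):
        if len(w.residues) != length:
            raise ValueError(f"row {i}: window length {len(w.residues)} differs from {length}")
        ok, diag = validate_window(w, strict_center=strict_center)
        if not ok:
            raise ValueError(f"row {i} ({w.residues}): " + "; ".join(diag))
    ds = LabeledDataset(windows)
    log.info("loaded %d windows (%d positive / %d negative, t=%d) from %s",
             len(ds), ds.n_positive, ds.n_negative, ds.t, path)
    return ds


def save_dataset(dataset: LabeledDataset, path: str | Path, format: str = "tsv") -> None:
    """Write a dataset in the same dialects :func:`load_dataset` reads."""
    path = Path(path)
    if format == "tsv":
        with open(path, "w") as fh:
            for w in dataset:
                fh.write(f"{w.residues}\t{w.label}\n")
    elif format == "fasta-pair":
        records = []
        for i, w in enumerate(dataset):
            rid = w.source_id or f"win{i}"
            records.append(
                SeqRecord(Seq(w.residues), id=f"{rid}|label={w.label}", description="")
            )
        SeqIO.write(records, str(path), "fasta")
    else:
        raise ValueError(f"unknown format {format!r}")


def write_windows_tsv(windows: Sequence[PeptideWindow], path: str | Path) -> None:
    """Write (possibly unlabeled) windows with provenance columns."""
    with open(Path(path), "w") as fh:
        fh.write("peptide\tsource_id\tsite_position\n")
        for w in windows:
            fh.write(f"{w.residues}\t{w.source_id or ''}\t{w.site_position or ''}\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (multi-record, wrapped) FASTA file as (id, sequence) pairs."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records],
        str(path),
        "fasta",
    )
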