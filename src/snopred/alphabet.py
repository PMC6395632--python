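"""Residue alphabets shared across the package.

Peptide windows live over a 21-letter alphabet: the 20 standard amino
acids plus the dummy residue ``X`` used to pad windows that extend past
either end of the source protein.
"""

from __future__ import annotations

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
DUMMY: str = "X"
WINDOW_ALPHABET: str = AMINO_ACIDS + DUMMY

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
WINDOW_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(WINDOW_ALPHABET)}

#: Ambiguity / non-standard codes silently remapped to the dummy residue.
NONSTANDARD = set("BZJUO*")


def sanitize(sequence: str) -> tuple[str, set[str]]:
    """Uppercase *sequence* and map non-standard letters to ``X``.

    Returns the cleaned sequence and the set of letters that were
    remapped (empty if the sequence was already clean).
    """
    seq = sequence.upper()
    remapped: set[str] = set()
    out = []
    for ch in seq:
        if ch in WINDOW_INDEX:
            out.append(ch)
        else:
            remapped.add(ch)
            out.append(DUMMY)
    return "".join(out), remapped
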