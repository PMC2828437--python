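"""Canonical amino-acid alphabet and sequence validation.

Core positions of a bound peptide are indexed i = 0..8 (pockets P1..P9) and
residue types j = 0..19 in the fixed order below, so a scoring model is a
9 x 20 real matrix.
"""

from __future__ import annotations

import numpy as np

#: The 20 canonical residues, alphabetical one-letter order.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

N_RESIDUES: int = len(AMINO_ACIDS)
CORE_LENGTH: int = 9
N_PARAMETERS: int = CORE_LENGTH * N_RESIDUES

AA_INDEX: dict[str, int] = {aa: j for j, aa in enumerate(AMINO_ACIDS)}


class AlphabetError(ValueError):
    """A sequence contains a symbol outside the canonical 20 residues."""


def validate_sequence(sequence: str, *, min_length: int = CORE_LENGTH) -> str:
    """Validate a peptide sequence and return it unchanged.

    Non-canonical symbols (B, J, O, U, X, Z, lowercase, gaps) raise
    :class:`AlphabetError`; sequences shorter than ``min_length`` raise
    ``ValueError``.
    """
    if not isinstance(sequence, str):
        raise AlphabetError(f"sequence must be a string, got {type(sequence).__name__}")
    bad = sorted({ch for ch in sequence if ch not in AA_INDEX})
    if bad:
        raise AlphabetError(
            f"non-canonical residue(s) {bad!r} in sequence {sequence!r}"
        )
    if len(sequence) < min_length:
        raise ValueError(
            f"sequence {sequence!r} has length {len(sequence)} < {min_length}"
        )
    return sequence


def encode_indices(sequence: str) -> np.ndarray:
    """Map a validated sequence to an integer array of residue indices."""
    validate_sequence(sequence, min_length=0)
    return np.fromiter((AA_INDEX[ch] for ch in sequence), dtype=np.intp, count=len(sequence))
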