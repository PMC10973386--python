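"""Residue alphabet shared across the package.

The 20 canonical amino acids plus ``X`` as an unknown placeholder.  ``X`` in a
subject sequence never satisfies a residue class during pattern matching; it is
accepted on input so that masked or low-confidence positions survive I/O.
Ambiguity codes (B, Z, J) and the non-standard U/O are rejected at load time —
every motif grammar in the registry enumerates canonical residues only.
"""

from __future__ import annotations

CANONICAL = "ACDEFGHIKLMNPQRSTVWY"
CANONICAL_SET = frozenset(CANONICAL)
UNKNOWN = "X"
ALPHABET = CANONICAL + UNKNOWN
ALPHABET_SET = frozenset(ALPHABET)

#: index of each canonical residue in score matrices (stable, alphabetical)
RESIDUE_INDEX = {aa: i for i, aa in enumerate(CANONICAL)}


def validate_residues(residues: str, record_id: str = "<anonymous>") -> str:
    """Uppercase *residues* and verify every character is canonical or X.

    Raises ``ValueError`` naming the record and 1-based offending position.
    """
    up = residues.upper()
    for pos, ch in enumerate(up, start=1):
        if ch not in ALPHABET_SET:
            raise ValueError(
                f"illegal residue {ch!r} at position {pos} in record {record_id!r}; "
                f"allowed: 20 canonical amino acids and X"
            )
    return up
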