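"""Amino-acid alphabet shared across the package.

The 20 standard residues are kept in fixed alphabetical order; every
frequency vector, odds vector and log-odds vector in the package is indexed
in this order.  Ambiguity letters (B, J, O, U, X, Z) are legal in sequence
records but are never counted towards compositions; scoring treats them
according to the scanner's ambiguity policy.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
AMBIGUITY: frozenset[str] = frozenset("BJOUXZ")
ALPHABET: frozenset[str] = frozenset(AMINO_ACIDS) | AMBIGUITY

N_AA = len(AMINO_ACIDS)

# lookup table: byte -> index in AMINO_ACIDS, -1 for ambiguity, -2 for illegal
_CODE = np.full(128, -2, dtype=np.int8)
for _aa, _i in AA_INDEX.items():
    _CODE[ord(_aa)] = _i
for _aa in AMBIGUITY:
    _CODE[ord(_aa)] = -1


def encode(residues: str) -> np.ndarray:
    """Encode an uppercase residue string as indices into ``AMINO_ACIDS``.

    Ambiguity letters map to -1.  Raises ``ValueError`` naming the first
    illegal character and its 1-based position.
    """
    raw = np.frombuffer(residues.encode("ascii", errors="replace"), dtype=np.uint8)
    codes = _CODE[np.minimum(raw, 127)]
    bad = np.flatnonzero(codes == -2)
    if bad.size:
        pos = int(bad[0])
        raise ValueError(
            f"illegal residue character {residues[pos]!r} at position {pos + 1}"
        )
    return codes
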