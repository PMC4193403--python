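"""Amino-acid alphabet handling shared across the package.

Canonical residues get matrix indices 0-19 (alphabetical order); the
non-canonical letters that occur in real proteomes (B, Z, X, U, O, J) are
kept in sequences but share a single "ambiguous" index, 20, which the
scoring scheme prices with a flat score. '*' (stop) and '-' (gap) are
stripped during sanitization.
"""

from __future__ import annotations

import numpy as np

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUOUS_AA = "BZXUOJ"
AMBIGUOUS_INDEX = 20
STRIP_CHARS = "*-"

_CODE = {aa: i for i, aa in enumerate(CANONICAL_AA)}
_CODE.update({aa: AMBIGUOUS_INDEX for aa in AMBIGUOUS_AA})

# fast byte-level lookup: 255 marks an invalid character
_LUT = np.full(128, 255, dtype=np.uint8)
for _aa, _i in _CODE.items():
    _LUT[ord(_aa)] = _i


def sanitize(raw: str) -> str:
    """Uppercase, strip stops/gaps, and validate residue letters.

    Raises ``ValueError`` naming the offending character if a letter
    outside the 20 canonical + {B,Z,X,U,O,J} set remains.
    """
    s = raw.upper()
    for ch in STRIP_CHARS:
        s = s.replace(ch, "")
    for ch in s:
        if ch not in _CODE:
            raise ValueError(f"invalid residue character {ch!r} in sequence")
    return s


def encode(residues: str) -> np.ndarray:
    """Encode a sanitized residue string as int8 matrix indices (0-20)."""
    raw = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    codes = _LUT[raw]
    if (codes == 255).any():
        bad = chr(int(raw[codes == 255][0]))
        raise ValueError(f"invalid residue character {bad!r} in sequence")
    return codes.astype(np.int8)
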