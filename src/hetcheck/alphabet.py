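"""The 20-state amino-acid alphabet shared by every module.

All character matrices in the package are encoded against this single,
fixed alphabet: the 20 canonical residues in the classical PAML/PHYLIP
order (``ARNDCQEGHILKMFPSTWYV``).  Gap characters and ambiguity codes are
both mapped to "unobserved" (integer code ``-1``); they differ only in how
they are classified, which matters for gap-fraction filters.
"""

from __future__ import annotations

import numpy as np

#: Canonical residue order used for every profile, matrix and encoded column.
CANONICAL_STATES: str = "ARNDCQEGHILKMFPSTWYV"

N_STATES: int = 20

#: Characters meaning "gap / missing data".
GAP_CHARS: frozenset[str] = frozenset({"-", "?"})

#: Ambiguity / non-canonical codes, treated as unobserved.
AMBIGUITY_CHARS: frozenset[str] = frozenset({"X", "B", "Z", "J", "*", "."})

#: Integer code for any unobserved cell (gap or ambiguity).
UNOBSERVED: int = -1

_INDEX = {c: i for i, c in enumerate(CANONICAL_STATES)}

# 128-entry lookup: canonical index, or UNOBSERVED, or -2 (invalid).
_CODE_TABLE = np.full(128, -2, dtype=np.int8)
for _c, _i in _INDEX.items():
    _CODE_TABLE[ord(_c)] = _i
    _CODE_TABLE[ord(_c.lower())] = _i
for _c in GAP_CHARS | AMBIGUITY_CHARS:
    _CODE_TABLE[ord(_c)] = UNOBSERVED
    _CODE_TABLE[ord(_c.lower())] = UNOBSERVED


def classify(char: str) -> str:
    """Classify a single character as 'canonical', 'gap' or 'ambiguity'.

    Raises ``ValueError`` for anything outside the alphabet.
    """
    if char.upper() in _INDEX:
        return "canonical"
    if char in GAP_CHARS:
        return "gap"
    if char.upper() in AMBIGUITY_CHARS or char in AMBIGUITY_CHARS:
        return "ambiguity"
    raise ValueError(f"character {char!r} is not a valid amino-acid symbol")


def encode(char: str) -> int:
    """Map a character to its canonical index, or UNOBSERVED for gaps/ambiguities."""
    code = int(_CODE_TABLE[ord(char)]) if ord(char) < 128 else -2
    if code == -2:
        raise ValueError(f"character {char!r} is not a valid amino-acid symbol")
    return code


def encode_array(chars: np.ndarray) -> np.ndarray:
    """Vectorized :func:`encode` for an array of single characters."""
    arr = np.ascontiguousarray(np.asarray(chars, dtype="U1"))
    ords = np.frombuffer(arr.tobytes(), dtype=np.uint32).reshape(arr.shape)
    codes = _CODE_TABLE[np.where(ords < 128, ords, 0)]
    bad = (codes == -2) | (ords >= 128)
    if bad.any():
        offending = arr[bad].ravel()[0]
        raise ValueError(f"character {offending!r} is not a valid amino-acid symbol")
    return codes.astype(np.int8)


def decode_array(codes: np.ndarray, gap_char: str = "-") -> np.ndarray:
    """Inverse of :func:`encode_array`; unobserved cells become ``gap_char``."""
    lut = np.array(list(CANONICAL_STATES) + [gap_char], dtype="U1")
    return lut[np.where(codes < 0, N_STATES, codes)]
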