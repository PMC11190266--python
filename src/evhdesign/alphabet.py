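"""Symbol alphabets and integer encoding of aligned sequences.

The default modelling alphabet is the 20 standard amino acids in
alphabetical one-letter order followed by the gap symbol ``-`` (q = 21).
Ambiguous or nonstandard residue codes (B, J, O, U, X, Z) carry no usable
state information for a q=21 Potts model and are mapped to the gap symbol.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
GAP: str = "-"
DEFAULT_ALPHABET: str = AMINO_ACIDS + GAP

#: residue codes collapsed onto the gap state
AMBIGUOUS: str = "BJOUXZ*"


def encode(seq: str, alphabet: str = DEFAULT_ALPHABET) -> np.ndarray:
    """Encode a sequence string as an int array of alphabet indices.

    Characters not in ``alphabet`` (ambiguity codes, ``.``) map to the gap
    state when the alphabet contains one; otherwise they raise ValueError.
    """
    lut = {c: i for i, c in enumerate(alphabet)}
    gap_idx = lut.get(GAP)
    out = np.empty(len(seq), dtype=np.int64)
    for k, c in enumerate(seq.upper()):
        if c in lut:
            out[k] = lut[c]
        elif c == ".":
            if gap_idx is None:
                raise ValueError(f"gap character {c!r} but alphabet has no gap")
            out[k] = gap_idx
        elif c in AMBIGUOUS and gap_idx is not None:
            out[k] = gap_idx
        else:
            raise ValueError(f"symbol {c!r} not in alphabet {alphabet!r}")
    return out


def decode(idx: np.ndarray, alphabet: str = DEFAULT_ALPHABET) -> str:
    """Inverse of :func:`encode`."""
    arr = np.asarray(idx)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D index array")
    if arr.size and (arr.min() < 0 or arr.max() >= len(alphabet)):
        raise ValueError("index out of alphabet range")
    return "".join(alphabet[i] for i in arr)


def encode_matrix(rows: list[str], alphabet: str = DEFAULT_ALPHABET) -> np.ndarray:
    """Encode equal-length rows into an (n, L) int64 matrix."""
    if not rows:
        return np.empty((0, 0), dtype=np.int64)
    L = len(rows[0])
    if any(len(r) != L for r in rows):
        raise ValueError("rows have unequal lengths")
    return np.stack([encode(r, alphabet) for r in rows])
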