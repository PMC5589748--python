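"""Shared sequence primitives: encodings, translation, substitution matrices.

Amino acids are encoded as small integers over the 24-letter alphabet
``ARNDCQEGHILKMFPSTWYVBZX*`` (the alphabet of the NCBI scoring matrices);
nucleotides over ``ACGTN``.  Codons containing N translate to X, which the
matrices score as a mismatch against everything — assembly gaps never create
signal and never form splice sites.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import product

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

AA_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
AA_INDEX = {c: i for i, c in enumerate(AA_ALPHABET)}
X_CODE = AA_INDEX["X"]
STOP_CODE = AA_INDEX["*"]

NT_ALPHABET = "ACGTN"
NT_INDEX = {c: i for i, c in enumerate(NT_ALPHABET)}
_NT_LOOKUP = np.full(256, 4, dtype=np.int8)  # unknown bases behave like N
for _c, _i in NT_INDEX.items():
    _NT_LOOKUP[ord(_c)] = _i

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

STOP_CODONS = ("TAA", "TAG", "TGA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_nt(seq: str) -> np.ndarray:
    return _NT_LOOKUP[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_aa(seq: str) -> np.ndarray:
    return np.array([AA_INDEX.get(c, X_CODE) for c in seq], dtype=np.int8)


def _build_codon_table() -> np.ndarray:
    """125-entry lookup: codon code 25*a+5*b+c -> amino-acid code (N -> X)."""
    table = np.full(125, X_CODE, dtype=np.int8)
    for codon in product("ACGT", repeat=3):
        aa = str(Seq("".join(codon)).translate())
        code = 25 * NT_INDEX[codon[0]] + 5 * NT_INDEX[codon[1]] + NT_INDEX[codon[2]]
        table[code] = AA_INDEX.get(aa, X_CODE)
    return table


CODON_AA = _build_codon_table()


def translate_codes(nt_codes: np.ndarray, frame: int = 0) -> np.ndarray:
    """Translate an encoded nucleotide array in the given frame to aa codes."""
    usable = (len(nt_codes) - frame) // 3
    if usable <= 0:
        return np.empty(0, dtype=np.int8)
    c = nt_codes[frame:frame + 3 * usable].reshape(usable, 3).astype(np.int32)
    return CODON_AA[25 * c[:, 0] + 5 * c[:, 1] + c[:, 2]]


def translate(seq: str) -> str:
    """Translate a nucleotide string (frame 0); N-codons give X, stops give *."""
    codes = translate_codes(encode_nt(seq))
    return "".join(AA_ALPHABET[c] for c in codes)


def aa_string(codes: np.ndarray) -> str:
    return "".join(AA_ALPHABET[c] for c in codes)


@lru_cache(maxsize=None)
def load_matrix(name: str) -> np.ndarray:
    """Return a (24, 24) int16 substitution matrix over ``AA_ALPHABET``."""
    mat = substitution_matrices.load(name)
    out = np.zeros((24, 24), dtype=np.int16)
    alpha = mat.alphabet
    for i, a in enumerate(AA_ALPHABET):
        for j, b in enumerate(AA_ALPHABET):
            if a in alpha and b in alpha:
                out[i, j] = int(mat[a, b])
            else:  # pragma: no cover - all letters present in NCBI matrices
                out[i, j] = -1
    # X (incl. translated N-codons) must score as a mismatch, not neutral
    out[X_CODE, :] = -1
    out[:, X_CODE] = -1
    return out
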