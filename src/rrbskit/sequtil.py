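"""Small vectorised sequence helpers shared by the simulator and aligner."""

from __future__ import annotations

import numpy as np

# byte-code alphabet: A=0 C=1 G=2 T=3 N=4
_CODE = np.full(256, 4, dtype=np.uint8)
for i, base in enumerate("ACGT"):
    _CODE[ord(base)] = i
    _CODE[ord(base.lower())] = i
A, C, G, T, N = 0, 1, 2, 3, 4
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)
_COMP = np.array([T, G, C, A, N], dtype=np.uint8)

_COMP_TABLE = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Sequence string -> uint8 code array (A=0 C=1 G=2 T=3 N=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP_TABLE)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes][::-1]


def cytosine_sites(codes: np.ndarray):
    """All cytosines on both strands of one chromosome.

    Returns ``(pos, strand, context)`` arrays sorted by (pos, strand), where
    ``pos`` is the forward-reference coordinate of the C on its own strand
    (i.e. the G position for minus-strand cytosines).  Context is read from
    the two bases 3' of the C on its own strand; a C within 2 bp of the
    chromosome end with missing downstream bases falls back to CHH.
    """
    n = len(codes)
    padded = np.concatenate([np.full(2, N, dtype=np.uint8), codes,
                             np.full(2, N, dtype=np.uint8)])
    ctx_names = np.array(["CG", "CHG", "CHH"])

    pos_plus = np.flatnonzero(codes == C)
    nxt1 = padded[pos_plus + 3]  # codes[pos+1]
    nxt2 = padded[pos_plus + 4]
    ctx_plus = np.where(nxt1 == G, 0, np.where(nxt2 == G, 1, 2)).astype(np.int8)

    pos_minus = np.flatnonzero(codes == G)
    prv1 = padded[pos_minus + 1]  # codes[pos-1]; complement is the next base 3'
    prv2 = padded[pos_minus]
    ctx_minus = np.where(prv1 == C, 0, np.where(prv2 == C, 1, 2)).astype(np.int8)

    pos = np.concatenate([pos_plus, pos_minus])
    strand = np.concatenate(
        [np.zeros(len(pos_plus), dtype=np.int8), np.ones(len(pos_minus), dtype=np.int8)]
    )
    ctx = np.concatenate([ctx_plus, ctx_minus])
    order = np.lexsort((strand, pos))
    strand_names = np.array(["+", "-"])
    return pos[order], strand_names[strand[order]], ctx_names[ctx[order]]
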