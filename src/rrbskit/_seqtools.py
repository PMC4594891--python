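"""Low-level nucleotide helpers shared by the simulator, the digester and the caller.

Sequences are handled as uppercase ASCII ``bytes`` (or the equivalent
``numpy.uint8`` views); coordinates are 0-based, half-open throughout.
"""
from __future__ import annotations

import numpy as np

A, C, G, T, N = 65, 67, 71, 84, 78

C2T = bytes.maketrans(b"C", b"T")
G2A = bytes.maketrans(b"G", b"A")
_RC = bytes.maketrans(b"ACGTN", b"TGCAN")

#: context codes used everywhere a cytosine context is stored
CPG, CHG, CHH, UNKNOWN = 0, 1, 2, 3
CONTEXT_LABELS = ("CpG", "CHG", "CHH", "unknown")


def as_bytes(seq) -> bytes:
    if isinstance(seq, bytes):
        return seq
    if isinstance(seq, np.ndarray):
        return seq.tobytes()
    return str(seq).upper().encode()


def seq_array(seq) -> np.ndarray:
    """View a sequence as a uint8 array (no copy for bytes input)."""
    return np.frombuffer(as_bytes(seq), dtype=np.uint8)


def revcomp(seq: bytes) -> bytes:
    return seq.translate(_RC)[::-1]


def cpg_starts(arr: np.ndarray) -> np.ndarray:
    """Start positions of plus-strand CpG dinucleotides."""
    if arr.size < 2:
        return np.empty(0, dtype=np.int64)
    return np.where((arr[:-1] == C) & (arr[1:] == G))[0]


def dinuc_starts(arr: np.ndarray, dinuc: str) -> np.ndarray:
    """Start positions of an arbitrary plus-strand dinucleotide (e.g. "TG")."""
    if arr.size < 2:
        return np.empty(0, dtype=np.int64)
    b = dinuc.upper().encode()
    return np.where((arr[:-1] == b[0]) & (arr[1:] == b[1]))[0]


def cytosine_contexts(arr: np.ndarray):
    """Classify every cytosine on both strands of a sequence.

    Returns ``(plus_pos, plus_ctx, minus_pos, minus_ctx)``. ``minus_pos``
    holds the *genomic* index of the G whose complement is the minus-strand
    cytosine. Contexts are read 5'->3' on the respective strand; positions
    whose one or two downstream bases fall off the sequence or touch an N
    are labelled ``UNKNOWN``.
    """
    n = arr.size
    plus_pos = np.where(arr == C)[0]
    nxt1 = np.full(plus_pos.size, N, dtype=np.uint8)
    nxt2 = np.full(plus_pos.size, N, dtype=np.uint8)
    ok1 = plus_pos + 1 < n
    ok2 = plus_pos + 2 < n
    nxt1[ok1] = arr[plus_pos[ok1] + 1]
    nxt2[ok2] = arr[plus_pos[ok2] + 2]
    plus_ctx = _classify(nxt1, nxt2)

    minus_pos = np.where(arr == G)[0]
    # on the minus strand the 3'-adjacent base sits at genomic pos-1
    prv1 = np.full(minus_pos.size, N, dtype=np.uint8)
    prv2 = np.full(minus_pos.size, N, dtype=np.uint8)
    ok1 = minus_pos - 1 >= 0
    ok2 = minus_pos - 2 >= 0
    prv1[ok1] = arr[minus_pos[ok1] - 1]
    prv2[ok2] = arr[minus_pos[ok2] - 2]
    # complement: genomic C upstream == G on the minus strand read
    minus_ctx = _classify_comp(prv1, prv2)
    return plus_pos, plus_ctx, minus_pos, minus_ctx


def _classify(b1: np.ndarray, b2: np.ndarray) -> np.ndarray:
    ctx = np.full(b1.size, CHH, dtype=np.int8)
    ctx[b1 == G] = CPG
    chg = (b1 != G) & (b1 != N) & (b2 == G)
    ctx[chg] = CHG
    unknown = (b1 == N) | ((b1 != G) & (b2 == N))
    ctx[unknown] = UNKNOWN
    return ctx


def _classify_comp(b1: np.ndarray, b2: np.ndarray) -> np.ndarray:
    # b1/b2 are genomic bases at pos-1/pos-2; their complements are the
    # minus-strand downstream bases, so genomic C plays the role of G.
    ctx = np.full(b1.size, CHH, dtype=np.int8)
    ctx[b1 == C] = CPG
    chg = (b1 != C) & (b1 != N) & (b2 == C)
    ctx[chg] = CHG
    unknown = (b1 == N) | ((b1 != C) & (b2 == N))
    ctx[unknown] = UNKNOWN
    return ctx
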