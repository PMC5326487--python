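"""Shared low-level ungapped alignment helpers (diagonal match counting).

Used by the assembler (dovetail/containment overlap detection) and by the
exclusion filter (identity/coverage screening).  Only exact character
matches over A/C/G/T(U) count; ambiguity codes never match anything.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate("ACGU"):
    _CODE[ord(b)] = i
_CODE[ord("T")] = 3  # T and U are equivalent everywhere in this package


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as uint8 codes: A=0 C=1 G=2 U/T=3, other=4."""
    return _CODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]


def diagonal_matches(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Match counts for every ungapped offset of ``b`` against ``a``.

    Returns an array ``m`` of length ``len(a) + len(b) - 1`` where
    ``m[t + len(b) - 1]`` is the number of positions ``j`` with
    ``a[t + j] == b[j]`` (codes 0..3 only).
    """
    out = np.zeros(len(a) + len(b) - 1)
    for base in range(4):
        av = (a == base).astype(np.float64)
        bv = (b == base).astype(np.float64)
        out += np.correlate(av, bv, mode="full")
    return np.rint(out).astype(np.int64)


def overlap_span(t: int, la: int, lb: int) -> int:
    """Length of the overlap between ``a`` and ``b`` shifted by offset ``t``."""
    return max(0, min(la, t + lb) - max(0, t))


def best_ungapped_overlap(
    a: np.ndarray, b: np.ndarray, min_len: int, min_identity: float
) -> tuple[int, int, float] | None:
    """Best dovetail/containment overlap of ``b`` on ``a``.

    Returns ``(offset, overlap_len, identity)`` for the longest overlap of
    length >= ``min_len`` with identity strictly greater than
    ``min_identity`` (ties broken by higher identity, then smaller offset),
    or ``None`` if no offset qualifies.
    """
    la, lb = len(a), len(b)
    matches = diagonal_matches(a, b)
    best: tuple[int, int, float] | None = None
    for n in range(len(matches)):
        t = n - (lb - 1)
        span = overlap_span(t, la, lb)
        if span < min_len:
            continue
        ident = matches[n] / span
        if ident <= min_identity:
            continue
        if best is None or (span, ident, -t) > (best[1], best[2], -best[0]):
            best = (t, span, ident)
    return best


def has_local_match(
    a: np.ndarray, b: np.ndarray, min_identity: float, min_cov: float
) -> bool:
    """True if some ungapped offset aligns >= ``min_cov`` of ``b`` on ``a``
    with identity >= ``min_identity`` (identity over the aligned part of b)."""
    la, lb = len(a), len(b)
    need = min_cov * lb
    matches = diagonal_matches(a, b)
    for n in range(len(matches)):
        span = overlap_span(n - (lb - 1), la, lb)
        if span >= need and span > 0 and matches[n] / span >= min_identity:
            return True
    return False
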