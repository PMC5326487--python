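"""Homology scan of unigenes against known mature miRNAs.

Candidate generation is an exhaustive window scan on both strands: every
unigene window that can be aligned to a reference mature miRNA within an
edit budget of ``max_mismatch_scan`` -- substitutions and bulged
nucleotides together -- is reported, with bulge events further capped by
``max_bulges_scan`` (count) and ``max_bulge_size_scan`` (nt per event).
Counting bulged nucleotides against the same budget keeps the stage
discriminative: a hit must stay a near-full-length homolog of the mature,
not a fragment rescued by large gaps.  G:U wobble counts as a mismatch
(plain Hamming semantics) and T/U are equivalent.

Alignment grammar: an alignment is a sequence of match/mismatch columns
interleaved with bulge runs (1..max_bulge_size insertions of unigene bases
or deletions of reference bases).  Bulge runs are interior -- they are
preceded and followed by at least one match/mismatch column -- and two
runs are never adjacent, so a gap of length g is a single bulge of size g,
never two smaller ones.  With ``max_bulges_scan = 0`` the scan reduces
exactly to a sliding-window Hamming comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from . import _align
from .io import RunConfig, SeqRecord, revcomp, to_rna
from .preprocess import Unigene

logger = logging.getLogger(__name__)

__all__ = ["CandidateHit", "hamming", "scan_unigene", "exclusion_filter"]

_INF = np.int16(900)


@dataclass(frozen=True)
class CandidateHit:
    """A unigene region homologous to a known mature miRNA."""

    unigene_id: str
    mirna_ref_id: str
    strand: str             # "+" | "-"
    start: int              # 1-based inclusive on the unigene (forward coords)
    stop: int
    predicted_mature: str   # RNA string, miRNA-sense orientation
    n_mismatch: int
    n_bulges: int
    max_bulge_size: int


def hamming(a: str, b: str) -> int:
    """Number of differing positions between two equal-length sequences.

    T and U are equivalent; any ambiguity code differs from everything,
    including itself.
    """
    x, y = to_rna(a), to_rna(b)
    if len(x) != len(y):
        raise ValueError(f"hamming requires equal lengths ({len(x)} vs {len(y)})")
    ca, cb = _align.encode(x), _align.encode(y)
    return int(((ca != cb) | (ca > 3) | (cb > 3)).sum())


# ---------------------------------------------------------------------------
# bounded-bulge scanning DP
# ---------------------------------------------------------------------------

def _mismatch_rows(seqp: np.ndarray, ref_code: int, i: int, GB: int, S: int, L: int) -> np.ndarray:
    """Row d-index -> per-start mismatch cost of matching ref[i] at offset d."""
    D = 2 * GB + 1
    rows = np.empty((D, S), dtype=np.int16)
    for didx in range(D):
        d = didx - GB
        p0 = i + d
        if p0 < 0:
            rows[didx] = _INF
            continue
        win = seqp[p0 : p0 + S]
        cost = ((win != ref_code) | (win > 3)).astype(np.int16)
        cost[win == 5] = _INF  # consumed past the end of the unigene
        rows[didx] = cost
    return rows


def _scan_dp(codes: np.ndarray, ref: np.ndarray, B: int, G: int) -> np.ndarray:
    """Minimal edit weight per start position under the bulge caps.

    Edit weight = substitutions + bulged nucleotides.  Returns an array of
    shape (B+1, D, S): entry [b, didx, s] is the minimal weight of any
    alignment of the full reference starting at unigene position ``s``
    with net offset ``didx - GB`` and at most ``b`` bulge events.
    Unreachable states are ~``_INF``.
    """
    m = len(ref)
    L = len(codes)
    GB = B * G
    S = max(L - m + GB + 1, 1)
    seqp = np.full(L + m + GB + 2, 5, dtype=np.uint8)
    seqp[:L] = codes
    D = 2 * GB + 1
    dp = np.full((B + 1, D, S), _INF, dtype=np.int16)
    dp[0, GB, :] = 0
    hist: list[np.ndarray] = []
    for i in range(m):
        hist.append(dp)
        mis = _mismatch_rows(seqp, int(ref[i]), i, GB, S, L)
        dp_next = np.minimum(dp + mis[None, :, :], _INF)
        if i >= 1:
            for k in range(1, G + 1):
                # insertion run of k unigene bases (weight k), then match ref[i]
                cand = dp[:-1, :-k, :] + mis[None, k:, :] + np.int16(k)
                np.minimum(dp_next[1:, k:, :], cand, out=dp_next[1:, k:, :])
                # deletion run of k reference bases (weight k) ending at ref[i-1]
                if i - k >= 1:
                    src = hist[i - k]
                    cand = src[:-1, k:, :] + mis[None, : D - k, :] + np.int16(k)
                    np.minimum(dp_next[1:, : D - k, :], cand,
                               out=dp_next[1:, : D - k, :])
        dp = dp_next
    return dp


def _alignment_details(
    sub: str, ref: str, B: int, G: int
) -> tuple[int, int, int, int, int] | None:
    """Best alignment of ``ref`` against a prefix of ``sub`` under the caps.

    Returns ``(weight, n_mismatch, n_bulges, max_bulge, window_len)``
    minimising the tuple lexicographically (weight = substitutions +
    bulged nucleotides), or None if nothing aligns.  Exhaustive over the
    small state space; used only on accepted starts.
    """
    cs = _align.encode(sub)
    cr = _align.encode(ref)
    m = len(cr)

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, b: int, after_run: bool):
        if i == m:
            return (0, 0, 0, 0, j)
        best = None
        # match/mismatch column
        if j < len(cs):
            cost = int(cs[j] != cr[i] or cs[j] > 3 or cr[i] > 3)
            tail = rec(i + 1, j + 1, b, False)
            if tail is not None:
                cand = (tail[0] + cost, tail[1] + cost, tail[2], tail[3], tail[4])
                best = cand if best is None else min(best, cand)
        if not after_run and b < B and 0 < i < m:
            for k in range(1, G + 1):
                if j + k <= len(cs):  # insertion of k unigene bases
                    tail = rec(i, j + k, b + 1, True)
                    if tail is not None:
                        cand = (tail[0] + k, tail[1], tail[2] + 1,
                                max(tail[3], k), tail[4])
                        best = cand if best is None else min(best, cand)
                if i + k <= m - 1:   # deletion of k reference bases
                    tail = rec(i + k, j, b + 1, True)
                    if tail is not None:
                        cand = (tail[0] + k, tail[1], tail[2] + 1,
                                max(tail[3], k), tail[4])
                        best = cand if best is None else min(best, cand)
        return best

    return rec(0, 0, 0, False)


def _collapse(weighted: list[tuple[int, CandidateHit]]) -> list[CandidateHit]:
    """Collapse overlapping hits to the same reference, keeping the most
    parsimonious alignment (lowest edit weight, then lowest mismatch
    count, then leftmost, then '+' strand)."""
    out: list[CandidateHit] = []
    by_ref: dict[str, list[tuple[int, CandidateHit]]] = {}
    for w, h in weighted:
        by_ref.setdefault(h.mirna_ref_id, []).append((w, h))
    for ref_id in sorted(by_ref):
        kept: list[CandidateHit] = []
        for w, h in sorted(by_ref[ref_id],
                           key=lambda t: (t[0], t[1].n_mismatch, t[1].start,
                                          t[1].strand != "+")):
            if all(h.stop < k.start or h.start > k.stop for k in kept):
                kept.append(h)
        out.extend(sorted(kept, key=lambda h: h.start))
    return out


def scan_unigene(
    unigene: Unigene | SeqRecord, refs: list[SeqRecord], cfg: RunConfig
) -> list[CandidateHit]:
    """All homology hits of the reference matures on one unigene."""
    if not refs:
        raise ValueError("empty reference miRNA set")
    useq = to_rna(unigene.seq)
    L = len(useq)
    raw: list[tuple[int, CandidateHit]] = []
    for ref in refs:
        if len(ref.seq) < 15:
            logger.warning("reference %s shorter than 15 nt: skipped", ref.id)
            continue
        rcode = _align.encode(to_rna(ref.seq))
        m = len(rcode)
        if L < m - cfg.max_bulges_scan * cfg.max_bulge_size_scan:
            continue
        ref_rna = to_rna(ref.seq)
        for strand, sseq in (("+", useq), ("-", revcomp(useq))):
            codes = _align.encode(sseq)
            for s, weight, mism, nb, maxb, wl in _scan_one(codes, sseq, rcode,
                                                           ref_rna, cfg):
                if strand == "+":
                    start, stop = s + 1, s + wl
                else:
                    start, stop = L - (s + wl) + 1, L - s
                raw.append((weight, CandidateHit(
                    unigene_id=unigene.id, mirna_ref_id=ref.id, strand=strand,
                    start=start, stop=stop, predicted_mature=sseq[s : s + wl],
                    n_mismatch=mism, n_bulges=nb, max_bulge_size=maxb,
                )))
    return _collapse(raw)


def _scan_one(codes: np.ndarray, sseq: str, ref: np.ndarray, ref_rna: str,
              cfg: RunConfig):
    """Yield (start, weight, n_mismatch, n_bulges, max_bulge, window_len)
    per accepted start on one strand."""
    m = len(ref)
    L = len(codes)
    mm = cfg.max_mismatch_scan
    B, G = cfg.max_bulges_scan, cfg.max_bulge_size_scan
    if B == 0 or G == 0:
        if L < m:
            return
        wins = sliding_window_view(codes, m)
        mis = ((wins != ref[None, :]) | (wins > 3)).sum(axis=1)
        for s in np.nonzero(mis <= mm)[0]:
            yield int(s), int(mis[s]), int(mis[s]), 0, 0, m
        return
    dp = _scan_dp(codes, ref, B, G)
    per_start = dp.min(axis=(0, 1))[: max(L - m + B * G + 1, 1)]
    GB = B * G
    for s in np.nonzero(per_start <= mm)[0]:
        s = int(s)
        details = _alignment_details(sseq[s : s + m + GB], ref_rna, B, G)
        if details is None or details[0] > mm:
            continue
        weight, mismatches, nb, maxb, wl = details
        if s + wl > L:
            continue
        yield s, weight, mismatches, nb, maxb, wl


def exclusion_filter(
    hits: list[CandidateHit],
    unigenes: list[Unigene],
    exclusion_refs: list[SeqRecord],
    min_identity: float = 0.9,
    min_cov: float = 0.8,
) -> list[CandidateHit]:
    """Drop hits hosted on unigenes that resemble known non-miRNA sequences.

    A unigene is excluded when it shares an ungapped local match with any
    exclusion reference (either strand) of identity >= ``min_identity``
    covering >= ``min_cov`` of that reference.  With an empty exclusion
    set the hits pass through unchanged.
    """
    if not exclusion_refs or not hits:
        return list(hits)
    by_id = {u.id: u for u in unigenes}
    excluded: set[str] = set()
    for uid in sorted({h.unigene_id for h in hits}):
        uni = by_id.get(uid)
        if uni is None:
            continue
        ucodes = _align.encode(to_rna(uni.seq))
        for ref in exclusion_refs:
            for rseq in (ref.seq, revcomp(ref.seq)):
                if _align.has_local_match(ucodes, _align.encode(to_rna(rseq)),
                                          min_identity, min_cov):
                    excluded.add(uid)
                    break
            if uid in excluded:
                break
    kept = [h for h in hits if h.unigene_id not in excluded]
    if excluded:
        logger.info("exclusion_filter: removed %d hits on %d unigenes",
                    len(hits) - len(kept), len(excluded))
    return kept
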