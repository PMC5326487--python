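"""Precursor excision, folding, MFEI computation and stem-loop validation.

A candidate hit is surrounded by a ladder of excision windows (total
lengths from mature+20 up to ``precursor_max_window`` in steps of
``precursor_window_step``, with the flank split symmetrically and fully to
either side).  Each window is folded at the configured temperature with a
nearest-neighbour thermodynamic model (ViennaRNA; interior loops are
capped at 30 nt by the engine, matching the configured ``max_loop_size``),
and validated on three criteria:

* the mature lies wholly on one arm of the stem-loop (not in the loop,
  not straddling it);
* the MFEI magnitude, ``|MFE| * 100 / (length * GC%)``, reaches the
  configured threshold (default 0.6);
* the miRNA:miRNA* duplex contains at most ``max_duplex_mismatch``
  mismatches;
* at most ``max_flanked_bases`` mature bases are unpaired at the duplex
  ends -- a mature that pairs over less than half its length has no real
  star partner, whatever the window's folding energy;
* the duplex helix is interrupted by at most
  ``max_duplex_interruptions`` internal loops or bulges -- a Dicer
  substrate is a largely regular helix, and chance complementarity
  assembled from many small gapped fragments is not.

The passing window with the largest MFEI magnitude wins (ties: shortest
window, then leftmost); if none passes, the best-scoring failure is
returned with machine-readable reasons.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import RNA

from .io import RunConfig, SeqRecord, revcomp, to_rna
from .preprocess import Unigene
from .scan import CandidateHit

logger = logging.getLogger(__name__)

__all__ = ["PrecursorCandidate", "DuplexStats", "fold", "compute_mfei",
           "duplex_stats", "excise_and_fold"]

FOLD_ENGINE = f"ViennaRNA {RNA.__version__}"


def fold(seq: str, temperature: float = 25.0, max_loop: int = 30) -> tuple[str, float]:
    """Deterministic MFE fold: returns (dot-bracket structure, MFE kcal/mol).

    ``max_loop`` is the interior-loop size cap; the folding engine fixes it
    at 30 nt, which is the configured default.  Non-A/C/G/U characters are
    fatal.
    """
    s = to_rna(seq)
    if len(s) < 10:
        raise ValueError("fold requires at least 10 nt")
    bad = set(s) - set("ACGUNRYSWKMBDHV")
    if bad:
        raise ValueError(f"fold requires nucleotide characters; found {sorted(bad)}")
    # ambiguity codes are treated as unpairable by the engine
    s = "".join(c if c in "ACGU" else "N" for c in s)
    if max_loop != 30:
        logger.warning("interior-loop cap is fixed at 30 nt by the folding engine; "
                       "requested %d ignored", max_loop)
    md = RNA.md()
    md.temperature = float(temperature)
    fc = RNA.fold_compound(s, md)
    structure, mfe = fc.mfe()
    return structure, float(mfe)


def compute_mfei(mfe: float, seq: str) -> tuple[float, float, float]:
    """AMFE, MFEI and GC fraction of a folded sequence.

    ``AMFE = MFE / length * 100`` (kcal/mol per 100 nt) and
    ``MFEI = AMFE / GC%``.  Signs are preserved: a negative MFE gives a
    negative MFEI.  A GC-free sequence has an undefined MFEI (NaN), which
    downstream validation flags as a failure.
    """
    s = to_rna(seq)
    if not s:
        raise ValueError("empty sequence")
    amfe = mfe / len(s) * 100.0
    gc_frac = (s.count("G") + s.count("C")) / len(s)
    if mfe == 0.0:
        mfei = 0.0
    elif gc_frac > 0:
        mfei = amfe / (gc_frac * 100.0)
    else:
        mfei = math.nan
    return amfe, mfei, gc_frac


@dataclass(frozen=True)
class DuplexStats:
    duplex_mismatch: int
    duplex_bulges: int       # asymmetric interruptions (one strand open)
    max_bulge: int
    duplex_interruptions: int  # all helix interruptions, symmetric or not
    mature_arm: str          # five_prime | three_prime | loop | split
    n_flanked_bases: int     # unpaired mature bases at the duplex ends
    star_start: int = 0      # miRNA* span (1-based on the folded sequence;
    star_stop: int = 0       # 0/0 when the mature has no duplex partner)


def _hairpin_loops(pt: list[int], n: int) -> list[tuple[int, int]]:
    """Intervals (1-based, closed) of hairpin loops: the unpaired stretch
    enclosed by a pair with no other pair inside."""
    loops = []
    for i in range(1, n + 1):
        j = pt[i]
        if j > i and all(pt[k] == 0 for k in range(i + 1, j)):
            loops.append((i + 1, j - 1))
    return loops


# interior loops larger than this end a miRNA:miRNA* duplex: the mature and
# its star must pair as one continuous helix, interrupted only by small
# mismatch loops and bulges (real duplex loops are 1-3 nt)
DUPLEX_MAX_GAP = 3


def _longest_duplex_chain(pairs: list[tuple[int, int]],
                          max_gap: int = DUPLEX_MAX_GAP) -> list[tuple[int, int]]:
    """Longest subset of (position, partner) pairs with positions increasing
    and partners strictly decreasing -- the single antiparallel helix the
    miRNA:miRNA* duplex must form.  Consecutive chain pairs may be separated
    by at most ``max_gap`` bases on either strand, so pairing into two
    unrelated helices cannot masquerade as one duplex.  O(n^2) DP."""
    if not pairs:
        return []
    n = len(pairs)
    best_len = [1] * n
    prev = [-1] * n
    for j in range(n):
        for i in range(j):
            run = pairs[j][0] - pairs[i][0] - 1
            opp = pairs[i][1] - pairs[j][1] - 1
            if (pairs[i][1] > pairs[j][1] and run <= max_gap and opp <= max_gap
                    and best_len[i] + 1 > best_len[j]):
                best_len[j] = best_len[i] + 1
                prev[j] = i
    end = max(range(n), key=lambda j: (best_len[j], -j))
    chain = []
    while end != -1:
        chain.append(pairs[end])
        end = prev[end]
    return chain[::-1]


def duplex_stats(seq: str, structure: str, mature_start: int, mature_stop: int) -> DuplexStats:
    """Duplex statistics of the mature within a folded precursor.

    Coordinates are 1-based inclusive on the folded sequence.  The
    miRNA:miRNA* duplex is taken to be the longest antiparallel pairing
    chain of the mature (positions increasing, partners strictly
    decreasing, partners outside the mature itself): mature bases pairing
    off that chain do not belong to a duplex and count like unpaired
    bases.  Unpaired/off-chain mature bases at the mature ends are the
    flanked bases; interior stretches are decomposed against the
    opposite-strand gap into mismatches (both strands open) and bulges
    (one strand open).
    """
    n = len(seq)
    if len(structure) != n:
        raise ValueError("structure length does not match sequence")
    if not (1 <= mature_start <= mature_stop <= n):
        raise ValueError("mature interval outside the precursor")
    pt = list(RNA.ptable(structure))  # pt[0] = n, 1-based pairs
    mature = list(range(mature_start, mature_stop + 1))
    # candidate duplex pairs: partners strictly outside the mature interval
    pairs = [(i, pt[i]) for i in mature
             if pt[i] != 0 and not (mature_start <= pt[i] <= mature_stop)]
    chain = _longest_duplex_chain(pairs)

    # arm localisation relative to the terminal (hairpin) loops
    loops = _hairpin_loops(pt, n)
    inside = [lo for lo in loops if not (mature_stop < lo[0] or mature_start > lo[1])]
    arm: str
    if inside:
        lo = inside[0]
        arm = "loop" if (lo[0] <= mature_start and mature_stop <= lo[1]) else "split"
    elif not chain:
        arm = "loop"
    else:
        above = sum(1 for _, q in chain if q > mature_stop)
        below = sum(1 for _, q in chain if q < mature_start)
        if above and below:
            arm = "split"
        else:
            arm = "five_prime" if above else "three_prime"
            # mature and star must be arms of one stem-loop: exactly one
            # terminal loop between the innermost duplex pair -- a partner
            # region across a multibranched fold is not a miRNA* arm
            innermost = chain[-1] if arm == "five_prime" else chain[0]
            lo, hi = sorted(innermost)
            inner = [l for l in loops if lo < l[0] and l[1] < hi]
            if len(inner) != 1:
                arm = "split"

    if not chain:
        return DuplexStats(duplex_mismatch=len(mature), duplex_bulges=0,
                           max_bulge=0, duplex_interruptions=0,
                           mature_arm=arm, n_flanked_bases=0)

    first, last = chain[0][0], chain[-1][0]
    n_flanked = (first - mature_start) + (mature_stop - last)

    # Strict duplex accounting: every mature base between the duplex ends
    # that is not Watson-Crick paired within the chain is a mismatch --
    # interior unpaired bases, bulged-out bases, off-chain pairings and
    # G:U wobbles alike (a wobble is a pair to the folding engine but not
    # a complementary one; the homology scan applies the same semantics).
    wc = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
    n_wc = sum(1 for i, q in chain if (seq[i - 1], seq[q - 1]) in wc)
    mismatches = (mature_stop - mature_start + 1) - n_wc - n_flanked
    bulges = 0
    max_bulge = 0
    interruptions = 0
    for (a, qa), (b, qb) in zip(chain, chain[1:]):
        run = b - a - 1          # mature bases between chain pairs
        opp = qa - qb - 1        # opposite-strand gap (chain is decreasing)
        if run or opp:
            interruptions += 1
        diff = abs(run - opp)
        if diff > 0:
            bulges += 1
            max_bulge = max(max_bulge, diff)
    partners = [q for _, q in chain]
    return DuplexStats(duplex_mismatch=mismatches, duplex_bulges=bulges,
                       max_bulge=max_bulge, duplex_interruptions=interruptions,
                       mature_arm=arm, n_flanked_bases=n_flanked,
                       star_start=min(partners), star_stop=max(partners))


@dataclass(frozen=True)
class PrecursorCandidate:
    """An excised, folded window around a candidate hit with its verdict."""

    hit: CandidateHit
    start: int            # 1-based inclusive on the unigene (forward coords)
    stop: int
    seq: str              # RNA, mature-sense orientation
    structure: str
    pri_mfe: float        # MFE of the whole unigene fold
    pre_mfe: float
    amfe: float
    mfei: float
    gc_frac: float
    mature_arm: str
    duplex_mismatch: int
    duplex_bulges: int
    max_bulge: int
    duplex_interruptions: int
    n_flanked_bases: int
    star_start: int          # miRNA* span, 1-based unigene forward coords
    star_stop: int           # (0/0 when the mature has no duplex partner)
    verdict: bool
    reasons: tuple[str, ...]

    def __post_init__(self) -> None:
        assert len(self.seq) == self.stop - self.start + 1 == len(self.structure)


def _windows(hit: CandidateHit, length: int, cfg: RunConfig,
             fracs: tuple[float, ...] = (0.0, 0.5, 1.0)) -> list[tuple[int, int]]:
    mlen = hit.stop - hit.start + 1
    seen: set[tuple[int, int]] = set()
    out: list[tuple[int, int]] = []
    for total in range(mlen + 20, cfg.precursor_max_window + 1,
                       cfg.precursor_window_step):
        flank = total - mlen
        for frac in fracs:
            up = round(flank * frac)
            down = flank - up
            start = max(1, hit.start - up)
            stop = min(length, hit.stop + down)
            if stop - start + 1 < mlen + 10:
                continue
            if (start, stop) not in seen:
                seen.add((start, stop))
                out.append((start, stop))
    return out


def evaluate_window(
    useq: str, hit: CandidateHit, start: int, stop: int, pri_mfe: float,
    cfg: RunConfig,
) -> PrecursorCandidate:
    """Fold and validate one excision window (1-based on the unigene)."""
    window = useq[start - 1 : stop]
    if hit.strand == "-":
        window = revcomp(window)
        m_start = stop - hit.stop + 1
        m_stop = stop - hit.start + 1
    else:
        m_start = hit.start - start + 1
        m_stop = hit.stop - start + 1
    structure, mfe = fold(window, cfg.fold_temperature, cfg.max_loop_size)
    amfe, mfei, gc = compute_mfei(mfe, window)
    ds = duplex_stats(window, structure, m_start, m_stop)
    reasons = []
    if ds.mature_arm not in ("five_prime", "three_prime"):
        reasons.append("arm")
    if math.isnan(mfei) or abs(mfei) < cfg.mfei_threshold:
        reasons.append("mfei")
    if ds.duplex_mismatch > cfg.max_duplex_mismatch:
        reasons.append("duplex")
    if ds.n_flanked_bases > cfg.max_flanked_bases:
        reasons.append("flank")
    if ds.duplex_interruptions > cfg.max_duplex_interruptions:
        reasons.append("gaps")
    # map the star span from window coordinates to unigene forward coords
    if ds.star_start:
        if hit.strand == "-":
            star_u = (stop - ds.star_stop + 1, stop - ds.star_start + 1)
        else:
            star_u = (start + ds.star_start - 1, start + ds.star_stop - 1)
    else:
        star_u = (0, 0)
    return PrecursorCandidate(
        hit=hit, start=start, stop=stop, seq=window, structure=structure,
        pri_mfe=pri_mfe, pre_mfe=mfe, amfe=amfe, mfei=mfei, gc_frac=gc,
        mature_arm=ds.mature_arm, duplex_mismatch=ds.duplex_mismatch,
        duplex_bulges=ds.duplex_bulges, max_bulge=ds.max_bulge,
        duplex_interruptions=ds.duplex_interruptions,
        n_flanked_bases=ds.n_flanked_bases,
        star_start=star_u[0], star_stop=star_u[1], verdict=not reasons,
        reasons=tuple(reasons),
    )


def excise_and_fold(
    unigene: Unigene | SeqRecord, hit: CandidateHit, cfg: RunConfig,
    pri_mfe: float | None = None,
) -> PrecursorCandidate:
    """Evaluate the excision-window ladder around a hit; return the best.

    The best is the passing candidate with the largest MFEI magnitude
    (ties: shortest window, then leftmost); if no window passes, the
    failure with the largest MFEI magnitude, carrying its reasons.
    """
    useq = to_rna(unigene.seq)
    if not (1 <= hit.start <= hit.stop <= len(useq)):
        raise ValueError(f"hit {hit} outside unigene {unigene.id}")
    if pri_mfe is None:
        _, pri_mfe = fold(useq, cfg.fold_temperature, cfg.max_loop_size) \
            if len(useq) >= 10 else ("", 0.0)
    candidates = [
        evaluate_window(useq, hit, start, stop, pri_mfe, cfg)
        for start, stop in _windows(hit, len(useq), cfg)
    ]
    if not candidates:
        raise ValueError("no admissible excision window around the hit")

    def rank(c: PrecursorCandidate):
        score = -abs(c.mfei) if not math.isnan(c.mfei) else math.inf
        return (not c.verdict, score, c.stop - c.start + 1, c.start)

    return min(candidates, key=rank)
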