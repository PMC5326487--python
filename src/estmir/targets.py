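"""miRNA target prediction under positional complementarity rules.

A transcript window of miRNA length (sense strand, ungapped) is a target
site when, pairing the miRNA antiparallel against it:

* at most one mismatch falls at miRNA positions 1-9 (1 = miRNA 5' end),
* no mismatch falls at positions 10 or 11,
* no more than two mismatches are consecutive,
* the total number of mismatches does not exceed the configured cap.

G:U wobble counts as a full mismatch by default; an optional half-weight
mode (``wobble_weight = 0.5``) scores wobbles at half a mismatch in the
positional counts, except at positions 10-11 where any non-Watson-Crick
pair is disqualifying.  The inhibition mechanism is called ``cleavage``
when positions 9-11 are all perfectly Watson-Crick paired and
``translation`` otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._align import encode
from .io import RunConfig, SeqRecord, to_rna

logger = logging.getLogger(__name__)

__all__ = ["MismatchProfile", "TargetSite", "score_site", "evaluate_window",
           "predict_targets", "classify_inhibition"]

# pairing lookup over codes A=0 C=1 G=2 U=3 (+4 = ambiguous)
_WC = np.zeros((5, 5), dtype=bool)
for a, b in ((0, 3), (3, 0), (2, 1), (1, 2)):
    _WC[a, b] = True
_WOBBLE = np.zeros((5, 5), dtype=bool)
for a, b in ((2, 3), (3, 2)):
    _WOBBLE[a, b] = True


@dataclass(frozen=True)
class MismatchProfile:
    """Positions are miRNA coordinates, 1 = miRNA 5' end."""

    mismatch_positions: tuple[int, ...]   # non-paired positions (incl. wobbles)
    wobble_positions: tuple[int, ...]     # subset that are G:U wobbles
    total_mismatch: float                 # wobbles weighted by wobble_weight
    max_consecutive: int                  # longest mismatch run (wobbles join at full weight)


@dataclass(frozen=True)
class TargetSite:
    mirna_id: str
    transcript_id: str
    start: int             # 1-based inclusive on the transcript
    stop: int
    site_seq: str
    mismatch_positions: tuple[int, ...]
    total_mismatch: float
    max_consecutive: int
    inhibition: str        # cleavage | translation


def _profile(mirna_codes: np.ndarray, window_codes: np.ndarray,
             wobble_weight: float) -> MismatchProfile:
    L = len(mirna_codes)
    # antiparallel: miRNA position p (1-based) pairs transcript window
    # index L - p (0-based)
    opp = window_codes[::-1]
    wc = _WC[mirna_codes, opp]
    wob = _WOBBLE[mirna_codes, opp]
    mism = ~wc
    full = ~wc & ~wob
    positions = tuple(int(p) + 1 for p in np.nonzero(mism)[0])
    wobbles = tuple(int(p) + 1 for p in np.nonzero(wob)[0])
    total = float(full.sum()) + wobble_weight * float(wob.sum())
    # with full-weight wobbles, wobbles take part in consecutive runs
    run_mask = mism if wobble_weight >= 1.0 else full
    best = run = 0
    for f in run_mask:
        run = run + 1 if f else 0
        best = max(best, run)
    return MismatchProfile(positions, wobbles, total, best)


def score_site(mirna: str, window: str, wobble_weight: float = 1.0) -> MismatchProfile:
    """Mismatch profile of a miRNA against one transcript-sense window."""
    m = to_rna(mirna)
    w = to_rna(window)
    if len(m) != len(w):
        raise ValueError(f"length mismatch ({len(m)} vs {len(w)})")
    return _profile(encode(m), encode(w), wobble_weight)


def evaluate_window(mirna: str, window: str, cfg: RunConfig) -> tuple[MismatchProfile, list[str]]:
    """Profile plus the list of violated rules (empty = accepted)."""
    prof = score_site(mirna, window, cfg.wobble_weight)
    violations: list[str] = []
    w = cfg.wobble_weight
    seed_weight = sum(
        (w if p in prof.wobble_positions else 1.0)
        for p in prof.mismatch_positions if p <= 9
    )
    if seed_weight > cfg.max_mismatch_pos1_9:
        violations.append("pos1_9")
    if any(p in (10, 11) for p in prof.mismatch_positions):
        violations.append("pos10_11")
    if prof.max_consecutive > cfg.max_consecutive_mismatch:
        violations.append("consecutive")
    if prof.total_mismatch > cfg.max_target_mismatch:
        violations.append("total")
    return prof, violations


def classify_inhibition(mirna: str, site_seq: str) -> str:
    """``cleavage`` iff miRNA positions 9-11 are perfect Watson-Crick pairs
    (wobble excluded); ``translation`` otherwise."""
    prof = score_site(mirna, site_seq, wobble_weight=1.0)
    central = set(prof.mismatch_positions) | set(prof.wobble_positions)
    return "translation" if central & {9, 10, 11} else "cleavage"


def predict_targets(
    mirnas: list[SeqRecord], transcripts: list[SeqRecord], cfg: RunConfig
) -> list[TargetSite]:
    """All accepted target sites, overlapping sites per miRNA-transcript
    pair collapsed to the lowest-total (tie: leftmost) one."""
    sites: list[TargetSite] = []
    for mir in mirnas:
        m = to_rna(mir.seq)
        mc = encode(m)
        L = len(mc)
        for tx in transcripts:
            t = to_rna(tx.seq)
            if len(t) < L:
                continue
            wins = sliding_window_view(encode(t), L)
            opp = wins[:, ::-1]
            wc = _WC[mc[None, :], opp]
            wob = _WOBBLE[mc[None, :], opp]
            full = ~wc & ~wob
            total = full.sum(axis=1) + cfg.wobble_weight * wob.sum(axis=1)
            # quick reject on the total before the per-window rule check
            cand = np.nonzero(total <= cfg.max_target_mismatch)[0]
            accepted: list[TargetSite] = []
            for s in cand:
                window = t[s : s + L]
                prof, violations = evaluate_window(m, window, cfg)
                if violations:
                    continue
                accepted.append(TargetSite(
                    mirna_id=mir.id, transcript_id=tx.id,
                    start=int(s) + 1, stop=int(s) + L, site_seq=window,
                    mismatch_positions=prof.mismatch_positions,
                    total_mismatch=prof.total_mismatch,
                    max_consecutive=prof.max_consecutive,
                    inhibition=classify_inhibition(m, window),
                ))
            # collapse overlapping accepted windows
            kept: list[TargetSite] = []
            for site in sorted(accepted, key=lambda x: (x.total_mismatch, x.start)):
                if all(site.stop < k.start or site.start > k.stop for k in kept):
                    kept.append(site)
            sites.extend(sorted(kept, key=lambda x: x.start))
    return sites
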