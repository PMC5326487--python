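"""EST cleaning and greedy overlap assembly into unigenes.

Cleaning masks contaminant-matching stretches to N, trims terminal N runs,
and discards reads that end up shorter than ``min_est_len`` or carry more
than ``max_ambig_frac`` ambiguous bases (strictly greater; exactly at the
threshold is kept).

Assembly is a greedy ungapped overlap-layout-consensus: the pair of units
with the longest dovetail/containment overlap of length >= ``min_overlap_len``
and identity strictly above ``overlap_identity`` is merged first, with a
majority-vote consensus (ties go to the base of the longest covering
member).  Reverse-complement overlaps are considered; each merged contig is
reported on the strand of its lexicographically first member.  The result
is deterministic for a given input.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from . import _align
from .io import RunConfig, SeqRecord, revcomp

logger = logging.getLogger(__name__)

__all__ = ["Unigene", "CleanReport", "mask_contaminants", "clean_ests",
           "assemble", "unigene_stats"]


@dataclass(frozen=True)
class Unigene:
    """An assembled contig (>= 2 member ESTs) or a singleton."""

    id: str
    seq: str
    kind: str  # "contig" | "singleton"
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind == "contig" and len(self.members) < 2:
            raise ValueError(f"contig {self.id} must have >= 2 members")
        if self.kind == "singleton" and len(self.members) != 1:
            raise ValueError(f"singleton {self.id} must have exactly 1 member")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class CleanReport:
    n_input: int = 0
    n_discarded_short: int = 0
    n_discarded_ambig: int = 0
    n_masked: int = 0
    n_passed: int = 0


def mask_contaminants(
    record: SeqRecord, contaminants: list[SeqRecord], min_match: int
) -> SeqRecord:
    """Replace every exact shared substring of length >= ``min_match``
    between the record and any contaminant (either strand) with N.

    Masking is idempotent: runs of N never match a contaminant again.
    """
    if min_match < 12:
        raise ValueError("min_match must be >= 12")
    if not contaminants:
        return record
    kmers: set[str] = set()
    for contam in contaminants:
        for s in (contam.seq.upper().replace("U", "T"), revcomp(contam.seq).replace("U", "T")):
            for i in range(len(s) - min_match + 1):
                kmers.add(s[i : i + min_match])
    if not kmers:
        return record
    seq = record.seq.upper().replace("U", "T")
    masked = np.zeros(len(seq), dtype=bool)
    for i in range(len(seq) - min_match + 1):
        if seq[i : i + min_match] in kmers:
            masked[i : i + min_match] = True
    if not masked.any():
        return record
    out = "".join("N" if m else c for c, m in zip(record.seq, masked))
    return dataclasses.replace(record, seq=out)


_UNAMBIG = set("ACGTU")


def clean_ests(
    records: list[SeqRecord],
    contaminants: list[SeqRecord] | None,
    cfg: RunConfig,
) -> tuple[list[SeqRecord], CleanReport]:
    """Mask, trim and filter an EST library; survivors keep input order."""
    if not records:
        raise ValueError("empty EST library")
    contaminants = contaminants or []
    report = CleanReport(n_input=len(records))
    survivors: list[SeqRecord] = []
    for rec in records:
        masked = mask_contaminants(rec, contaminants, cfg.mask_min_match)
        if masked.seq != rec.seq:
            report.n_masked += 1
        seq = masked.seq.strip("N")
        if len(seq) < cfg.min_est_len:
            report.n_discarded_short += 1
            continue
        ambig = sum(1 for c in seq if c not in _UNAMBIG)
        if ambig / len(seq) > cfg.max_ambig_frac:
            report.n_discarded_ambig += 1
            continue
        survivors.append(dataclasses.replace(masked, seq=seq))
    report.n_passed = len(survivors)
    logger.info(
        "clean_ests: %d in -> %d passed (%d short, %d ambiguous, %d masked; "
        "min_len=%d, max_ambig=%.3f)",
        report.n_input, report.n_passed, report.n_discarded_short,
        report.n_discarded_ambig, report.n_masked, cfg.min_est_len,
        cfg.max_ambig_frac,
    )
    return survivors, report


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

@dataclass
class _Member:
    est_id: str
    offset: int      # 0-based offset of the member in the unit consensus
    strand: str      # orientation of the member within the unit
    seq: str         # member sequence, oriented to the unit strand


@dataclass
class _Unit:
    members: list[_Member]
    consensus: str

    @property
    def key(self) -> str:
        return min(m.est_id for m in self.members)


def _consensus(members: list[_Member], length: int) -> str:
    out = []
    for col in range(length):
        covering = [(m.seq[col - m.offset], len(m.seq)) for m in members
                    if m.offset <= col < m.offset + len(m.seq)]
        if not covering:
            out.append("N")
            continue
        counts = Counter(base for base, _ in covering)
        top = max(counts.values())
        tied = sorted(b for b, c in counts.items() if c == top)
        if len(tied) == 1:
            out.append(tied[0])
        else:
            # tie: base of the longest covering member (then alphabetical)
            best = max(((ln, base) for base, ln in covering if base in tied),
                       key=lambda t: (t[0], -ord(t[1][0])))
            out.append(best[1])
    return "".join(out)


def _flip(unit: _Unit) -> _Unit:
    L = len(unit.consensus)
    members = [
        _Member(m.est_id, L - (m.offset + len(m.seq)), "-" if m.strand == "+" else "+",
                revcomp(m.seq))
        for m in unit.members
    ]
    return _Unit(members=members, consensus=revcomp(unit.consensus))


def _canonical(unit: _Unit) -> _Unit:
    lead = min(unit.members, key=lambda m: m.est_id)
    return _flip(unit) if lead.strand == "-" else unit


def _best_pair_overlap(a: _Unit, b: _Unit, cfg: RunConfig):
    """Best qualifying overlap of unit b (either strand) on unit a.

    Returns (overlap_len, identity, strand, offset) or None.
    """
    ac = _align.encode(a.consensus)
    best = None
    for strand, bseq in (("+", b.consensus), ("-", revcomp(b.consensus))):
        hit = _align.best_ungapped_overlap(
            ac, _align.encode(bseq), cfg.min_overlap_len, cfg.overlap_identity
        )
        if hit is None:
            continue
        t, span, ident = hit
        cand = (span, ident, strand, t)
        if best is None or (cand[0], cand[1]) > (best[0], best[1]):
            best = cand
    return best


def _merge(a: _Unit, b: _Unit, strand: str, offset: int) -> _Unit:
    if strand == "-":
        b = _flip(b)
    shift = max(0, -offset)
    members = [_Member(m.est_id, m.offset + shift, m.strand, m.seq) for m in a.members]
    members += [_Member(m.est_id, m.offset + offset + shift, m.strand, m.seq)
                for m in b.members]
    length = max(m.offset + len(m.seq) for m in members)
    unit = _Unit(members=members, consensus="")
    unit.consensus = _consensus(members, length)
    return _canonical(unit)


def assemble(records: list[SeqRecord], cfg: RunConfig) -> list[Unigene]:
    """Greedily assemble cleaned ESTs into contigs and singletons."""
    units = [
        _Unit(members=[_Member(r.id, 0, "+", r.seq.upper().replace("U", "T"))],
              consensus=r.seq.upper().replace("U", "T"))
        for r in records
    ]
    # score all pairs, then repeatedly merge the global best
    scores: dict[tuple[int, int], tuple] = {}

    def score(i: int, j: int) -> None:
        hit = _best_pair_overlap(units[i], units[j], cfg)
        if hit is not None:
            scores[(i, j)] = hit

    n = len(units)
    for i in range(n):
        for j in range(i + 1, n):
            score(i, j)

    active = set(range(n))
    while scores:
        # deterministic choice: longest overlap, then identity, then the
        # lexicographically smallest pair of unit keys
        best_key = None
        best_val = None
        for (x, y), val in scores.items():
            rank = (val[0], val[1], tuple(sorted((units[x].key, units[y].key))))
            if best_val is None or (rank[0], rank[1]) > (best_val[0], best_val[1]) or (
                (rank[0], rank[1]) == (best_val[0], best_val[1]) and rank[2] < best_val[2]
            ):
                best_val = rank
                best_key = (x, y)
        i, j = best_key  # type: ignore[misc]
        span, ident, strand, offset = scores[(i, j)]
        merged = _merge(units[i], units[j], strand, offset)
        units.append(merged)
        k = len(units) - 1
        active.discard(i)
        active.discard(j)
        scores = {key: v for key, v in scores.items()
                  if i not in key and j not in key}
        for other in sorted(active):
            score(*sorted((other, k)))
        active.add(k)

    out: list[Unigene] = []
    finals = sorted((units[i] for i in active), key=lambda u: u.key)
    contig_n = 0
    for unit in finals:
        members = tuple(sorted(m.est_id for m in unit.members))
        if len(members) >= 2:
            contig_n += 1
            out.append(Unigene(id=f"contig{contig_n}", seq=unit.consensus,
                               kind="contig", members=members))
        else:
            out.append(Unigene(id=members[0], seq=unit.consensus,
                               kind="singleton", members=members))
    logger.info("assemble: %d ESTs -> %d unigenes (%d contigs, %d singletons; "
                "overlap>=%dnt, identity>%.2f)",
                len(records), len(out),
                sum(1 for u in out if u.kind == "contig"),
                sum(1 for u in out if u.kind == "singleton"),
                cfg.min_overlap_len, cfg.overlap_identity)
    return out


def unigene_stats(unigenes: list[Unigene]) -> dict:
    """Corpus-level summary: contig/singleton counts, EST capture, lengths."""
    if not unigenes:
        raise ValueError("no unigenes")
    contigs = [u for u in unigenes if u.kind == "contig"]
    singletons = [u for u in unigenes if u.kind == "singleton"]
    n_ests = sum(len(u.members) for u in unigenes)
    in_contigs = sum(len(u.members) for u in contigs)
    stats = {
        "n_contigs": len(contigs),
        "n_singletons": len(singletons),
        "n_unigenes": len(unigenes),
        "n_ests": n_ests,
        "pct_ests_in_contigs": round(100.0 * in_contigs / n_ests, 2) if n_ests else 0.0,
        "mean_contig_len": (sum(len(u) for u in contigs) / len(contigs)) if contigs else 0.0,
        "mean_contig_len_defined": bool(contigs),
        "min_members_per_contig": min((len(u.members) for u in contigs), default=0),
        "max_members_per_contig": max((len(u.members) for u in contigs), default=0),
    }
    return stats
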