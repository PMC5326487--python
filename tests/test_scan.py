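"""Homology scanning: Hamming oracle equivalence, strand symmetry, caps."""

import numpy as np
import pytest

from conftest import random_seq
from estmir import RunConfig, SeqRecord, revcomp, to_rna
from estmir.preprocess import Unigene
from estmir.scan import (CandidateHit, _alignment_details, _scan_one,
                         exclusion_filter, hamming, scan_unigene)
from estmir._align import encode


def _uni(seq, uid="u1"):
    return Unigene(id=uid, seq=seq, kind="singleton", members=(uid,))


# ---------------------------------------------------------------------------
# hamming
# ---------------------------------------------------------------------------

def test_hamming_on_known_vs_predicted_matures():
    """The printed known/predicted mature pairs differ at 4 positions each."""
    assert hamming("UCAUCCUCAUCAUCCUCGUCC", "UCCCUCUCAUCAUCCUCGUCG") == 4
    assert hamming("CAUUGUUUCUUGUUUUUUUCA", "CUUUGUUUCUUGUUUUCCUCC") == 4


def test_hamming_identity_t_u_equivalence_and_errors():
    assert hamming("ACGUACGU", "ACGUACGU") == 0
    assert hamming("ACGT", "ACGU") == 0
    assert hamming("ANGU", "AAGU") == 1  # ambiguity codes never match
    with pytest.raises(ValueError):
        hamming("ACG", "ACGU")


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def test_exact_copy_gives_zero_mismatch_plus_strand(cfg, rng):
    ref = SeqRecord(id="m", seq=random_seq(rng, 21, "ACGU"))
    host = random_seq(rng, 100) + ref.seq.replace("U", "T") + random_seq(rng, 100)
    hits = scan_unigene(_uni(host), [ref], cfg)
    exact = [h for h in hits if h.n_mismatch == 0]
    assert len(exact) == 1
    h = exact[0]
    assert (h.strand, h.start, h.stop) == ("+", 101, 121)
    assert h.predicted_mature == to_rna(ref.seq)


def test_reverse_complement_copy_gives_minus_strand(cfg, rng):
    ref = SeqRecord(id="m", seq=random_seq(rng, 21, "ACGU"))
    host = random_seq(rng, 80) + revcomp(ref.seq).replace("U", "T") + random_seq(rng, 60)
    hits = scan_unigene(_uni(host), [ref], cfg)
    exact = [h for h in hits if h.n_mismatch == 0]
    assert len(exact) == 1
    h = exact[0]
    assert (h.strand, h.start, h.stop) == ("-", 81, 101)
    assert h.predicted_mature == to_rna(ref.seq)


def test_short_reference_skipped(cfg, rng):
    ref = SeqRecord(id="tiny", seq="ACGUACGUACGUAC")  # 14 nt < 15
    hits = scan_unigene(_uni(random_seq(rng, 100)), [ref], cfg)
    assert hits == []


def _collapse_oracle(hits):
    out = []
    by_ref = {}
    for h in hits:
        by_ref.setdefault(h[0], []).append(h)
    for ref_id in sorted(by_ref):
        kept = []
        for h in sorted(by_ref[ref_id], key=lambda h: (h[4], h[2], h[1] != "+")):
            if all(h[3] < k[2] or h[2] > k[3] for k in kept):
                kept.append(h)
        out.extend(kept)
    return set(out)


def test_bulge_free_scan_equals_sliding_window_hamming_oracle(cfg):
    """With the bulge machinery off, the scan must agree exactly with an
    independently written sliding-window Hamming oracle on random inputs."""
    cfg0 = cfg.replace(max_bulges_scan=0)
    rng = np.random.default_rng(42)
    for trial in range(100):
        useq = random_seq(rng, int(rng.integers(40, 200)))
        refs = [SeqRecord(id=f"r{j}", seq=random_seq(rng, int(rng.integers(16, 23)), "ACGU"))
                for j in range(3)]
        got = {(h.mirna_ref_id, h.strand, h.start, h.stop, h.n_mismatch)
               for h in scan_unigene(_uni(useq), refs, cfg0)}
        # oracle: plain python character comparison on both strands
        raw = []
        L = len(useq)
        for ref in refs:
            r = to_rna(ref.seq)
            m = len(r)
            for strand, s_seq in (("+", to_rna(useq)), ("-", to_rna(revcomp(useq)))):
                for s in range(L - m + 1):
                    win = s_seq[s : s + m]
                    d = sum(1 for a, b in zip(win, r)
                            if a != b or a not in "ACGU" or b not in "ACGU")
                    if d <= cfg0.max_mismatch_scan:
                        if strand == "+":
                            start, stop = s + 1, s + m
                        else:
                            start, stop = L - (s + m) + 1, L - s
                        raw.append((ref.id, strand, start, stop, d))
        assert got == _collapse_oracle(raw), f"trial {trial}"


def _gapped_oracle_min_weight(sub, ref, mm, B, G):
    """Exhaustive enumeration of the alignment grammar: interior,
    non-adjacent bulge runs of 1..G nt on either strand, each followed by a
    match column; weight = substitutions + bulged nucleotides."""
    m = len(ref)
    best = [None]

    def rec(i, j, b, after_run, weight):
        if weight > mm:
            return
        if i == m:
            if best[0] is None or weight < best[0]:
                best[0] = weight
            return
        if j < len(sub):
            cost = 0 if (sub[j] == ref[i] and sub[j] in "ACGU") else 1
            rec(i + 1, j + 1, b, False, weight + cost)
        if not after_run and b < B and 0 < i < m:
            for k in range(1, G + 1):
                if j + k <= len(sub):
                    rec(i, j + k, b + 1, True, weight + k)
                if i + k <= m - 1:
                    rec(i + k, j, b + 1, True, weight + k)

    rec(0, 0, 0, False, 0)
    return best[0]


def test_gapped_scan_matches_brute_force_enumeration():
    """The bounded-bulge DP accepts exactly the starts the brute-force
    enumeration of windows and gap placements accepts, with equal weight."""
    rng = np.random.default_rng(7)
    cfg = RunConfig(max_mismatch_scan=2, max_bulges_scan=1, max_bulge_size_scan=2)
    for trial in range(15):
        useq = to_rna(random_seq(rng, 60))
        ref = random_seq(rng, 15, "ACGU")
        got = {(s, w) for s, w, *_ in
               _scan_one(encode(useq), useq, encode(ref), ref, cfg)}
        want = set()
        GB = cfg.max_bulges_scan * cfg.max_bulge_size_scan
        for s in range(len(useq)):
            w = _gapped_oracle_min_weight(useq[s : s + 15 + GB], ref,
                                          cfg.max_mismatch_scan,
                                          cfg.max_bulges_scan,
                                          cfg.max_bulge_size_scan)
            if w is not None:
                want.add((s, w))
        assert got == want, f"trial {trial}"


def test_scan_is_strand_symmetric(cfg, rng):
    refs = [SeqRecord(id="m", seq=random_seq(rng, 21, "ACGU"))]
    host = random_seq(rng, 150) + refs[0].seq.replace("U", "T") + random_seq(rng, 80)
    fwd = scan_unigene(_uni(host), refs, cfg)
    rev = scan_unigene(_uni(revcomp(host)), refs, cfg)
    L = len(host)
    mirrored = {(h.mirna_ref_id, "-" if h.strand == "+" else "+",
                 L - h.stop + 1, L - h.start + 1, h.n_mismatch) for h in rev}
    assert {(h.mirna_ref_id, h.strand, h.start, h.stop, h.n_mismatch)
            for h in fwd} == mirrored


def test_hits_respect_cap_invariants(cfg, rng):
    refs = [SeqRecord(id=f"m{j}", seq=random_seq(rng, 21, "ACGU")) for j in range(4)]
    host = random_seq(rng, 400)
    for h in scan_unigene(_uni(host), refs, cfg):
        assert h.n_mismatch <= cfg.max_mismatch_scan
        assert h.n_bulges <= cfg.max_bulges_scan
        assert h.max_bulge_size <= cfg.max_bulge_size_scan
        assert 1 <= h.start <= h.stop <= len(host)
        assert len(h.predicted_mature) == h.stop - h.start + 1


# ---------------------------------------------------------------------------
# exclusion filter
# ---------------------------------------------------------------------------

def _hit(uid):
    return CandidateHit(unigene_id=uid, mirna_ref_id="m", strand="+", start=1,
                        stop=21, predicted_mature="A" * 21, n_mismatch=0,
                        n_bulges=0, max_bulge_size=0)


def test_exclusion_empty_reference_set_is_identity(rng):
    unis = [_uni(random_seq(rng, 100))]
    hits = [_hit("u1")]
    assert exclusion_filter(hits, unis, []) == hits


def test_exclusion_removes_hits_on_matching_unigene(rng):
    seq = random_seq(rng, 200)
    unis = [_uni(seq, "u1"), _uni(random_seq(rng, 200), "u2")]
    excl = [SeqRecord(id="rRNA", seq=seq[20:180])]
    kept = exclusion_filter([_hit("u1"), _hit("u2")], unis, excl)
    assert [h.unigene_id for h in kept] == ["u2"]


def test_exclusion_threshold_spares_weak_similarity(rng):
    seq = random_seq(rng, 200)
    corrupted = list(seq[20:180])
    for pos in rng.choice(len(corrupted), size=80, replace=False):  # 50% identity
        corrupted[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[corrupted[pos]]
    excl = [SeqRecord(id="rRNA", seq="".join(corrupted))]
    kept = exclusion_filter([_hit("u1")], [_uni(seq, "u1")], excl,
                            min_identity=0.9, min_cov=0.8)
    assert [h.unigene_id for h in kept] == ["u1"]
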