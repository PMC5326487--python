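"""Folding, MFEI arithmetic, duplex statistics and hairpin validation."""

import math

import pytest

from conftest import random_seq
from estmir import RunConfig, SeqRecord
from estmir.precursor import (compute_mfei, duplex_stats, excise_and_fold,
                              fold)
from estmir.preprocess import Unigene
from estmir.scan import scan_unigene
from estmir.simulate import (make_est_library, make_hairpin,
                             make_reference_mirnas)


def _uni(seq, uid="u1"):
    return Unigene(id=uid, seq=seq, kind="singleton", members=(uid,))


# ---------------------------------------------------------------------------
# fold
# ---------------------------------------------------------------------------

def test_fold_forced_stem_pairs_and_negative_mfe():
    structure, mfe = fold("GGGGAAAACCCC")
    assert structure.count("(") == structure.count(")") >= 3
    assert mfe < 0


def test_fold_unpairable_sequence_is_open():
    structure, mfe = fold("AAAAAAAAAAAA")
    assert structure == "." * 12
    assert mfe == 0.0


def test_fold_rejects_bad_input():
    with pytest.raises(ValueError):
        fold("ACGUACGUX" + "ACGU")
    with pytest.raises(ValueError):
        fold("ACGUA")


def test_fold_of_perfect_inverted_repeat_pairs_every_mature_base():
    mature = make_reference_mirnas(1, (21, 21), seed=11)[0]
    plan = make_hairpin(mature, loop_len=8, n_internal_mismatch=0, seed=0)
    structure, mfe = fold(plan.record.seq)
    ds = duplex_stats(plan.record.seq, structure, plan.mature_start, plan.mature_stop)
    assert ds.duplex_mismatch == 0
    assert ds.n_flanked_bases == 0
    assert ds.mature_arm == "three_prime"
    assert mfe < -20


# ---------------------------------------------------------------------------
# MFEI
# ---------------------------------------------------------------------------

def test_compute_mfei_simple_arithmetic():
    amfe, mfei, gc = compute_mfei(-40.0, "G" * 25 + "C" * 25 + "A" * 50)
    assert amfe == pytest.approx(-40.0)
    assert gc == pytest.approx(0.5)
    assert mfei == pytest.approx(-0.8)


def test_compute_mfei_zero_mfe_and_zero_gc():
    _, mfei, _ = compute_mfei(0.0, "AUAUAUAUAU")
    assert mfei == 0.0
    _, mfei_nan, gc0 = compute_mfei(-5.0, "AUAUAUAUAU".replace("G", ""))
    assert gc0 == 0.0 and math.isnan(mfei_nan)


def test_mfei_reproduces_printed_precursor_value():
    """A 58-nt precursor at MFE -28.295 with 34/58 G+C has MFEI -0.832.

    The implied GC content is derived independently by brute force over
    integer G+C counts rather than assumed.
    """
    implied = min(
        range(1, 59),
        key=lambda gc: abs((-28.295 / 58 * 100) / (gc / 58 * 100) + 0.832),
    )
    assert implied == 34
    seq = "G" * 17 + "C" * 17 + "A" * 24
    amfe, mfei, gc = compute_mfei(-28.295, seq)
    assert round(mfei, 3) == -0.832
    assert gc == pytest.approx(34 / 58)


# ---------------------------------------------------------------------------
# duplex statistics
# ---------------------------------------------------------------------------

def test_duplex_stats_counts_injected_internal_mismatches():
    mature = make_reference_mirnas(1, (21, 21), seed=12)[0]
    for n in (1, 2, 3, 4):
        plan = make_hairpin(mature, n_internal_mismatch=n, seed=n)
        structure, _ = fold(plan.record.seq)
        ds = duplex_stats(plan.record.seq, structure,
                          plan.mature_start, plan.mature_stop)
        assert ds.duplex_mismatch == n
        assert ds.mature_arm == "three_prime"


def test_duplex_stats_five_prime_arm():
    mature = make_reference_mirnas(1, (21, 21), seed=13)[0]
    plan = make_hairpin(mature, arm="five_prime", seed=2)
    structure, _ = fold(plan.record.seq)
    ds = duplex_stats(plan.record.seq, structure,
                      plan.mature_start, plan.mature_stop)
    assert ds.mature_arm == "five_prime"
    assert ds.duplex_mismatch == 0


def test_duplex_stats_mature_straddling_loop_is_split_or_loop():
    mature = make_reference_mirnas(1, (21, 21), seed=14)[0]
    plan = make_hairpin(mature, loop_len=8, seed=3)
    structure, _ = fold(plan.record.seq)
    # shift the "mature" interval so it covers the terminal loop
    mid = (plan.mature_start + plan.star_stop) // 2
    ds = duplex_stats(plan.record.seq, structure, mid - 10, mid + 10)
    assert ds.mature_arm in ("split", "loop")


def test_duplex_stats_validates_inputs():
    with pytest.raises(ValueError):
        duplex_stats("ACGU", "...", 1, 2)
    with pytest.raises(ValueError):
        duplex_stats("ACGU", "....", 2, 9)


# ---------------------------------------------------------------------------
# excision ladder
# ---------------------------------------------------------------------------

def _planted_host(seed=21, n_internal=0, mutations=0):
    refs = make_reference_mirnas(1, (21, 21), seed=seed)
    plan = make_hairpin(refs[0], n_internal_mismatch=n_internal, seed=seed)
    records, truth = make_est_library(0, [plan], mature_mutations=mutations,
                                     seed=seed, include_defective=False)
    return refs, records[0], truth.planted_premirnas[0]


def test_excise_recovers_planted_58nt_precursor(cfg):
    refs, host, p = _planted_host()
    uni = _uni(host.seq, host.id)
    hits = scan_unigene(uni, refs, cfg)
    assert hits
    best = None
    for h in hits:
        c = excise_and_fold(uni, h, cfg)
        if c.verdict:
            best = c
    assert best is not None, "planted precursor must validate"
    # the chosen window covers the planted precursor interval
    assert best.start <= p.mature_start and best.stop >= p.mature_stop
    assert abs(best.mfei) >= cfg.mfei_threshold
    assert best.stop - best.start + 1 == len(best.seq) == len(best.structure)


def test_excise_handles_hit_at_sequence_edge(cfg):
    refs = make_reference_mirnas(1, (21, 21), seed=22)
    plan = make_hairpin(refs[0], seed=22)
    # no upstream flank at all: precursor starts at position 1
    import numpy as np
    tail = random_seq(np.random.default_rng(22), 120)
    host = plan.record.seq.replace("U", "T") + tail
    uni = _uni(host)
    hits = scan_unigene(uni, refs, cfg)
    assert hits
    for h in hits:
        c = excise_and_fold(uni, h, cfg)  # must not raise
        assert 1 <= c.start <= c.stop <= len(host)


def test_excise_random_context_fails_with_reasons(cfg, rng):
    refs = [SeqRecord(id="m", seq=random_seq(rng, 21, "ACGU"))]
    host = (random_seq(rng, 150) + refs[0].seq.replace("U", "T")
            + random_seq(rng, 150))
    uni = _uni(host)
    hits = scan_unigene(uni, refs, cfg)
    assert hits
    for h in hits:
        c = excise_and_fold(uni, h, cfg)
        assert not c.verdict
        assert c.reasons  # machine-readable failure reasons
        assert set(c.reasons) <= {"arm", "mfei", "duplex", "flank", "gaps"}


def test_shuffled_precursor_controls_never_validate(cfg):
    """Destroying the hairpin destroys the validation: across 50 shuffled
    precursors (mature kept verbatim, all other bases permuted) no passing
    candidate draws its miRNA* from the shuffled precursor region."""
    from estmir.simulate import make_reference_mirnas as _refs
    from estmir.simulate import make_hairpin as _hp
    from estmir.simulate import shuffle_precursor_except_mature as _shuf
    refs = _refs(6, (21, 21), seed=1)
    controls = [_shuf(_hp(refs[i % 6], seed=200 + i), seed=300 + i)
                for i in range(50)]
    records, truth = make_est_library(0, controls, mature_mutations=0,
                                      seed=11, include_defective=False)
    truth_by = {p.est_id: p for p in truth.planted_premirnas}
    leaked = []
    for rec in records:
        p = truth_by[rec.id]
        uni = _uni(rec.seq, rec.id)
        for h in scan_unigene(uni, refs, cfg):
            c = excise_and_fold(uni, h, cfg)
            if (c.verdict and c.star_start
                    and not (c.star_stop < p.precursor_start
                             or c.star_start > p.precursor_stop)):
                leaked.append(rec.id)
    assert leaked == []


def test_verdict_pass_implies_all_criteria(cfg):
    refs, host, _ = _planted_host(seed=23, n_internal=2)
    uni = _uni(host.seq, host.id)
    for h in scan_unigene(uni, refs, cfg):
        c = excise_and_fold(uni, h, cfg)
        if c.verdict:
            assert c.mature_arm in ("five_prime", "three_prime")
            assert abs(c.mfei) >= cfg.mfei_threshold
            assert c.duplex_mismatch <= cfg.max_duplex_mismatch
            assert c.n_flanked_bases <= cfg.max_flanked_bases
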