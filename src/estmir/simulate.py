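"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the shape of a small 5'-EST study: single-pass cDNA
reads of 100-900 nt with occasional ambiguous bases, a reference set of
mature plant miRNAs (19-24 nt), EST hosts carrying planted stem-loop
precursors whose mature sequence diverges from a reference by a known
number of substitutions, transcripts carrying target sites that obey or
violate the positional complementarity rules, and a gene-by-sample
expression matrix with planted correlated modules.

Every generator is a pure function of its arguments including the seed;
identical calls give byte-identical output.  Background sequence is i.i.d.
uniform over A/C/G/T -- the simplest null that folds poorly, which keeps
hairpin validation discriminative.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import SeqRecord, revcomp, to_dna, to_rna

__all__ = [
    "HairpinPlan",
    "PlantedTruth",
    "make_reference_mirnas",
    "make_hairpin",
    "make_est_library",
    "shuffle_precursor_except_mature",
    "make_target_transcripts",
    "make_expression_matrix",
]

_RNA = "ACGU"
_DNA = "ACGT"
_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}
# bases that pair (Watson-Crick or G:U wobble) with the key
_PAIRS_WITH = {"A": {"U"}, "U": {"A", "G"}, "G": {"C", "U"}, "C": {"G"}}

VIOLATION_RULES = ("pos1_9", "pos10_11", "consecutive")


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Independent generator per (seed, generator) pair.

    Seeding each generator with ``[seed, stream]`` decorrelates their
    streams: with a bare shared seed the first background EST would
    replay the very draws that produced the reference miRNAs.
    """
    return np.random.default_rng([int(seed), stream])



def _rand_seq(rng: np.random.Generator, n: int, alphabet: str = _DNA) -> str:
    return "".join(rng.choice(list(alphabet), size=n))


# ---------------------------------------------------------------------------
# truth bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class PlantedPremirna:
    est_id: str
    precursor_start: int  # 1-based inclusive on the host EST
    precursor_stop: int
    mature_start: int
    mature_stop: int
    mirna_ref_id: str
    n_substitutions: int
    control: bool = False  # True for shuffled (hairpin-destroyed) controls


@dataclass
class PlantedTarget:
    transcript_id: str
    site_start: int  # 1-based inclusive on the transcript
    site_stop: int
    mirna_id: str
    rule_compliant: bool
    violated_rule: str = ""  # one of VIOLATION_RULES for violating sites


@dataclass
class PlantedModule:
    gene_ids: list[str]
    r: float


@dataclass
class PlantedTruth:
    """Ground truth emitted alongside every synthetic dataset."""

    planted_premirnas: list[PlantedPremirna] = field(default_factory=list)
    planted_targets: list[PlantedTarget] = field(default_factory=list)
    planted_modules: list[PlantedModule] = field(default_factory=list)
    discard_expected: list[tuple[str, str]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


# ---------------------------------------------------------------------------
# reference miRNAs and hairpins
# ---------------------------------------------------------------------------

def make_reference_mirnas(
    n: int, length_range: tuple[int, int] = (19, 24), seed: int = 0
) -> list[SeqRecord]:
    """Uniform-random mature miRNA references with miRBase-style ids.

    Plant mature miRNAs are 19-24 nt small RNAs; the default length range
    reflects that.  Ranges outside 15-30 nt are rejected as not miRNA-like.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = length_range
    if lo > hi or lo < 15 or hi > 30:
        raise ValueError(f"length_range {length_range} outside the miRNA-like span [15, 30]")
    rng = _rng(seed, 1)
    out = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        out.append(SeqRecord(id=f"sim-miR{i + 1:03d}", seq=_rand_seq(rng, length, _RNA),
                             description="synthetic mature miRNA"))
    return out


@dataclass
class HairpinPlan:
    """A planted precursor and the geometry needed to mutate it coherently."""

    record: SeqRecord          # precursor, RNA alphabet
    mirna_ref_id: str
    mature_start: int          # 1-based inclusive within the precursor
    mature_stop: int
    star_start: int
    star_stop: int
    arm: str                   # "five_prime" | "three_prime"
    n_internal_mismatch: int
    n_substitutions: int = 0   # mature substitutions vs the reference
    control: bool = False

    @property
    def mature_len(self) -> int:
        return self.mature_stop - self.mature_start + 1

    def star_partner(self, mature_offset: int) -> int:
        """0-based precursor index pairing with mature offset (0-based)."""
        # the star arm is the reverse complement of the mature arm, so
        # mature offset t pairs with star offset (len - 1 - t)
        return (self.star_start - 1) + (self.mature_len - 1 - mature_offset)


def make_hairpin(
    mature: SeqRecord,
    loop_len: int = 8,
    arm: str = "three_prime",
    n_internal_mismatch: int = 0,
    seed: int = 0,
    stem_pad: tuple[int, int] = (4, 0),
) -> HairpinPlan:
    """Build a stem-loop precursor carrying ``mature`` verbatim on one arm.

    The precursor is ``5'arm + loop + 3'arm`` where the two arms are exact
    reverse complements apart from ``n_internal_mismatch`` substitutions
    scattered (non-adjacent, away from the arm ends) in the non-mature arm.
    ``stem_pad = (outer, inner)`` extends the stem on both sides of the
    mature so precursors of arbitrary length (e.g. 58 or 200 nt) are
    representable.
    """
    if loop_len < 3:
        raise ValueError("loop_len must be >= 3")
    if arm not in ("five_prime", "three_prime"):
        raise ValueError(f"arm must be five_prime or three_prime, got {arm!r}")
    m = to_rna(mature.seq)
    k = len(m)
    if n_internal_mismatch >= k:
        raise ValueError("n_internal_mismatch must be smaller than the mature length")
    rng = _rng(seed, 2)
    pad_out, pad_in = stem_pad
    p_out = _rand_seq(rng, pad_out, _RNA)
    p_in = _rand_seq(rng, pad_in, _RNA)

    star = list(revcomp(m))
    if n_internal_mismatch:
        # margins and spacing keep the designed 1x1 loops isolated so the
        # minimum-free-energy fold cannot merge them or slip the helix
        margin = 3
        candidates = [i for i in range(margin, k - margin)]
        positions: list[int] = []
        for pos in rng.permutation(candidates):
            if all(abs(pos - p) >= 4 for p in positions):
                positions.append(int(pos))
            if len(positions) == n_internal_mismatch:
                break
        if len(positions) < n_internal_mismatch:
            # dense request: fall back to even deterministic spacing
            step = max(4, (candidates[-1] - candidates[0]) // max(n_internal_mismatch - 1, 1))
            positions = [candidates[0] + j * step for j in range(n_internal_mismatch)
                         if candidates[0] + j * step <= candidates[-1]]
        if len(positions) < n_internal_mismatch:
            raise ValueError("mature too short to scatter that many internal mismatches")
        for pos in positions:
            # avoid bases that could pair the designated partner or its
            # neighbours, otherwise the fold shifts instead of looping out
            local = {m[k - 1 - pos + d] for d in (-1, 0, 1) if 0 <= k - 1 - pos + d < k}
            banned = set().union(*(_PAIRS_WITH[b] for b in local))
            choices = [b for b in _RNA if b != star[pos] and b not in banned]
            if not choices:
                partner = m[k - 1 - pos]
                choices = [b for b in _RNA
                           if b != star[pos] and b not in _PAIRS_WITH[partner]]
            star[pos] = str(rng.choice(choices))
    star_seq = "".join(star)

    if arm == "three_prime":
        five = p_out + star_seq + p_in
        three = revcomp(p_in) + m + revcomp(p_out)
        mature_start = len(five) + loop_len + pad_in + 1
        star_start = pad_out + 1
    else:
        five = p_out + m + p_in
        three = revcomp(p_in) + star_seq + revcomp(p_out)
        mature_start = pad_out + 1
        star_start = len(five) + loop_len + pad_in + 1
    # the loop must not pair with the stem's inner ends, or the fold
    # shifts the helix register past the designed duplex
    banned = set().union(*(_PAIRS_WITH[b] for b in five[-2:] + three[:2]))
    loop_choices = [b for b in _RNA if b not in banned] or ["A"]
    loop = "".join(str(rng.choice(loop_choices)) for _ in range(loop_len))
    precursor = five + loop + three
    rec = SeqRecord(id=f"hp-{mature.id}", seq=precursor,
                    description=f"synthetic precursor ({arm} arm)")
    return HairpinPlan(
        record=rec,
        mirna_ref_id=mature.id,
        mature_start=mature_start,
        mature_stop=mature_start + k - 1,
        star_start=star_start,
        star_stop=star_start + k - 1,
        arm=arm,
        n_internal_mismatch=n_internal_mismatch,
    )


def shuffle_precursor_except_mature(plan: HairpinPlan, seed: int = 0,
                                    max_tries: int = 100) -> HairpinPlan:
    """Negative control: keep the mature verbatim, permute every other base.

    The shuffled precursor still triggers the homology scan (the mature is
    intact) but must no longer fold into a mature:star stem-loop.  Because
    the permuted bases contain the complement multiset of the mature, a
    blind permutation occasionally re-assembles a partial duplex by
    chance; the shuffle is therefore rejection-sampled (deterministically
    under the seed) until the mature has no well-formed duplex in the
    shuffled precursor's own fold, which is the ground truth the control
    flag advertises.
    """
    # deferred imports: the scan/fold machinery is used as the witness that
    # the shuffle really removed the duplex
    from . import _align
    from .io import RunConfig
    from .scan import _scan_one

    from .precursor import duplex_stats, fold  # deferred: avoids cycle at import

    rng = _rng(seed, 3)
    seq = list(plan.record.seq)
    keep = set(range(plan.mature_start - 1, plan.mature_stop))
    idx = [i for i in range(len(seq)) if i not in keep]
    # two independent flank contexts: a residual near-star sometimes only
    # pairs up when folded with surrounding sequence, so destruction is
    # certified in context, with a safety margin of 2 on every duplex bound
    pads = [(_rand_seq(rng, 60, _RNA), _rand_seq(rng, 60, _RNA)) for _ in range(2)]

    def duplex_destroyed(candidate: str) -> bool:
        for up, down in pads:
            structure, _ = fold(up + candidate + down)
            ds = duplex_stats(up + candidate + down, structure,
                              len(up) + plan.mature_start,
                              len(up) + plan.mature_stop)
            if (ds.mature_arm in ("five_prime", "three_prime")
                    and ds.duplex_mismatch <= 6 and ds.n_flanked_bases <= 6
                    and ds.duplex_interruptions <= 6):
                return False
        return True

    last = plan.record.seq
    destroyed = False
    for _ in range(max_tries):
        perm = rng.permutation(idx)
        shuffled = seq[:]
        for src, dst in zip(idx, perm):
            shuffled[dst] = seq[src]
        last = "".join(shuffled)
        if duplex_destroyed(last):
            destroyed = True
            break
    if not destroyed:
        # composition so complement-rich that every permutation keeps a
        # near-star: fall back to fresh random bases outside the mature
        for _ in range(max_tries):
            shuffled = seq[:]
            for i in idx:
                shuffled[i] = str(rng.choice(list(_RNA)))
            last = "".join(shuffled)
            if duplex_destroyed(last):
                break
    rec = dataclasses.replace(plan.record, id=plan.record.id + "-shuf",
                              seq=last,
                              description="shuffled precursor control")
    return dataclasses.replace(plan, record=rec, control=True)


def _mutate_mature(plan: HairpinPlan, n_mut: int, rng: np.random.Generator) -> HairpinPlan:
    """Apply ``n_mut`` substitutions to the mature, compensating the star arm.

    The planted hairpin stays intact (the star base is replaced by the
    complement of the new mature base) so the plant models a diverged
    ortholog of the reference mature, not a broken precursor.
    """
    if n_mut == 0:
        return plan
    seq = list(plan.record.seq)
    k = plan.mature_len
    offsets = rng.choice(k, size=n_mut, replace=False)
    for off in sorted(int(o) for o in offsets):
        pos = plan.mature_start - 1 + off
        old = seq[pos]
        new = str(rng.choice([b for b in _RNA if b != old]))
        seq[pos] = new
        star_pos = plan.star_partner(off)
        if plan.record.seq[star_pos] in _PAIRS_WITH.get(old, set()) | {_WC[old]}:
            # the position was paired: keep it paired with the new base
            seq[star_pos] = _WC[new]
        else:
            # planned internal mismatch: keep it mismatched against the new base
            choices = [b for b in _RNA if b not in _PAIRS_WITH[new]]
            seq[star_pos] = str(rng.choice(choices))
    rec = dataclasses.replace(plan.record, seq="".join(seq))
    return dataclasses.replace(plan, record=rec, n_substitutions=n_mut)


def make_est_library(
    n_background: int,
    planted: list[HairpinPlan] | None = None,
    mature_mutations: int | list[int] = 0,
    ambig_frac: float = 0.005,
    seed: int = 0,
    include_defective: bool = True,
) -> tuple[list[SeqRecord], PlantedTruth]:
    """An EST library (DNA alphabet) with planted precursors and truth flags.

    Background ESTs are 100-900 nt of uniform random DNA with ambiguous
    bases sprinkled at rate ``ambig_frac``.  Each planted precursor is
    embedded in a longer host EST at a recorded offset; ``mature_mutations``
    (scalar or one count per plant) substitutes mature bases with star-arm
    compensation before embedding.  When ``include_defective`` is set, a
    few deliberately short / N-rich background reads are added and flagged
    in the truth so the cleaning stage has known discards.
    """
    planted = list(planted or [])
    if n_background == 0 and not planted:
        raise ValueError("nothing to generate: no background and no planted precursors")
    if isinstance(mature_mutations, int):
        mutation_counts = [mature_mutations] * len(planted)
    else:
        mutation_counts = list(mature_mutations)
        if len(mutation_counts) != len(planted):
            raise ValueError("mature_mutations list must match the number of plants")
    rng = _rng(seed, 4)
    truth = PlantedTruth()
    records: list[SeqRecord] = []

    for i in range(n_background):
        length = int(rng.integers(100, 901))
        seq = list(_rand_seq(rng, length))
        n_ambig = rng.binomial(length, ambig_frac)
        if n_ambig:
            for pos in rng.choice(length, size=n_ambig, replace=False):
                seq[pos] = "N"
        records.append(SeqRecord(id=f"bgEST{i + 1:04d}", seq="".join(seq),
                                 description="synthetic background EST"))

    if include_defective:
        short = _rand_seq(rng, int(rng.integers(60, 100)))
        records.append(SeqRecord(id="badESTshort", seq=short,
                                 description="synthetic EST, too short"))
        truth.discard_expected.append(("badESTshort", "short"))
        length = 200
        seq = list(_rand_seq(rng, length))
        for pos in rng.choice(length, size=18, replace=False):  # 9% ambiguous
            seq[pos] = "N"
        records.append(SeqRecord(id="badESTambig", seq="".join(seq),
                                 description="synthetic EST, too ambiguous"))
        truth.discard_expected.append(("badESTambig", "ambiguous"))

    for i, (plan, n_mut) in enumerate(zip(planted, mutation_counts)):
        plan = _mutate_mature(plan, n_mut, rng)
        up = _rand_seq(rng, int(rng.integers(50, 151)))
        down = _rand_seq(rng, int(rng.integers(50, 151)))
        host_seq = up + to_dna(plan.record.seq) + down
        est_id = f"plantEST{i + 1:03d}"
        records.append(SeqRecord(id=est_id, seq=host_seq,
                                 description=f"synthetic host EST ({plan.record.id})"))
        off = len(up)
        truth.planted_premirnas.append(PlantedPremirna(
            est_id=est_id,
            precursor_start=off + 1,
            precursor_stop=off + len(plan.record.seq),
            mature_start=off + plan.mature_start,
            mature_stop=off + plan.mature_stop,
            mirna_ref_id=plan.mirna_ref_id,
            n_substitutions=plan.n_substitutions,
            control=plan.control,
        ))

    order = rng.permutation(len(records))
    records = [records[int(i)] for i in order]
    return records, truth


# ---------------------------------------------------------------------------
# target transcripts
# ---------------------------------------------------------------------------

def _non_pairing_base(mirna_base: str, rng: np.random.Generator) -> str:
    """A transcript (DNA) base that pairs with ``mirna_base`` neither by
    Watson-Crick nor by G:U wobble."""
    choices = [b for b in _DNA if ("U" if b == "T" else b) not in _PAIRS_WITH[mirna_base]]
    return str(rng.choice(choices))


def _site_for(mirna_rna: str, mismatch_positions: list[int], rng: np.random.Generator) -> str:
    """A transcript-sense (DNA) window targeted by ``mirna_rna`` with
    mismatches at the given 1-based miRNA positions."""
    window = list(to_dna(revcomp(mirna_rna)))  # perfect site
    L = len(mirna_rna)
    for p in mismatch_positions:
        j = L - p  # antiparallel pairing: miRNA position p <-> window index L-p (0-based)
        window[j] = _non_pairing_base(mirna_rna[p - 1], rng)
    return "".join(window)


def make_target_transcripts(
    mirnas: list[SeqRecord],
    n_compliant: int,
    n_violating: int,
    seed: int = 0,
) -> tuple[list[SeqRecord], PlantedTruth]:
    """Transcripts (DNA) carrying planted target sites.

    Compliant sites satisfy all three positional rules (at most one
    mismatch at miRNA positions 1-9, none at 10-11, no more than two
    consecutive); each violating site breaks exactly one named rule so
    per-rule rejection accounting is testable.
    """
    if not mirnas:
        raise ValueError("need at least one miRNA")
    if n_compliant < 0 or n_violating < 0 or (n_compliant == 0 and n_violating == 0):
        raise ValueError("need a positive number of planted sites")
    rng = _rng(seed, 5)
    truth = PlantedTruth()
    records: list[SeqRecord] = []
    counter = 0

    def plant(site: str, mirna_id: str, compliant: bool, rule: str) -> None:
        nonlocal counter
        counter += 1
        up = _rand_seq(rng, int(rng.integers(80, 200)))
        down = _rand_seq(rng, int(rng.integers(80, 200)))
        tx_id = f"tx{counter:03d}"
        records.append(SeqRecord(id=tx_id, seq=up + site + down,
                                 description="synthetic transcript"))
        truth.planted_targets.append(PlantedTarget(
            transcript_id=tx_id,
            site_start=len(up) + 1,
            site_stop=len(up) + len(site),
            mirna_id=mirna_id,
            rule_compliant=compliant,
            violated_rule=rule,
        ))

    for i in range(n_compliant):
        mir = mirnas[i % len(mirnas)]
        m = to_rna(mir.seq)
        L = len(m)
        kind = i % 3
        if kind == 0:
            positions: list[int] = []
        elif kind == 1:
            positions = [int(rng.integers(1, 10))]  # one mismatch in 1-9
        else:
            # two isolated mismatches in the 3' half, away from 10/11
            pool = [p for p in range(12, L + 1)]
            p1 = int(rng.choice(pool))
            p2_pool = [p for p in pool if abs(p - p1) > 2]
            positions = sorted([p1, int(rng.choice(p2_pool))])
        plant(_site_for(m, positions, rng), mir.id, True, "")

    for i in range(n_violating):
        mir = mirnas[i % len(mirnas)]
        m = to_rna(mir.seq)
        L = len(m)
        rule = VIOLATION_RULES[i % len(VIOLATION_RULES)]
        if rule == "pos1_9":
            p1 = int(rng.integers(1, 10))
            p2 = int(rng.choice([p for p in range(1, 10) if abs(p - p1) > 1]))
            positions = sorted([p1, p2])
        elif rule == "pos10_11":
            positions = [int(rng.choice([10, 11]))]
        else:  # consecutive: a run of three in the 3' region
            start = int(rng.integers(12, L - 2))
            positions = [start, start + 1, start + 2]
        plant(_site_for(m, positions, rng), mir.id, False, rule)

    return records, truth


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------

def make_expression_matrix(
    n_genes: int,
    n_samples: int,
    modules: list[tuple[int, float]] | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Gene-by-sample matrix with planted correlated modules.

    Genes of a module of strength ``r`` are ``sqrt(r) * latent +
    sqrt(1-r) * noise`` so the expected pairwise Pearson correlation
    within the module is ``r``; all other genes are independent noise.
    """
    if n_samples < 3:
        raise ValueError("n_samples must be >= 3 for correlations to be defined")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    modules = list(modules or [])
    total = sum(size for size, _ in modules)
    if total > n_genes:
        raise ValueError("module sizes exceed n_genes")
    for size, r in modules:
        if not (-1.0 <= r <= 1.0):
            raise ValueError(f"module correlation {r} outside [-1, 1]")
    rng = _rng(seed, 6)
    genes = [f"gene{i + 1:04d}" for i in range(n_genes)]
    X = rng.normal(0.0, 1.0, size=(n_genes, n_samples))
    truth = PlantedTruth()
    cursor = 0
    for size, r in modules:
        latent = rng.normal(0.0, 1.0, size=n_samples)
        a = np.sqrt(abs(r))
        b = np.sqrt(1.0 - abs(r))
        for g in range(cursor, cursor + size):
            # for r < 0 alternate the latent sign so adjacent module genes
            # are anticorrelated at magnitude |r|
            sign = -1.0 if (r < 0 and (g - cursor) % 2) else 1.0
            X[g] = sign * a * latent + b * X[g]
        truth.planted_modules.append(PlantedModule(gene_ids=genes[cursor:cursor + size], r=r))
        cursor += size
    X *= noise_sd
    df = pd.DataFrame(X, index=genes,
                      columns=[f"s{j + 1:02d}" for j in range(n_samples)])
    df.index.name = "gene_id"
    return df, truth
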