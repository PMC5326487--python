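# Methods

`estmir` re-implements, as a tested library, the classical homology-based
workflow for discovering conserved plant miRNAs in an EST library:
clean and assemble the reads into unigenes, scan them against known
mature miRNAs, validate candidate precursors as stem-loops, predict
target transcripts by positional complementarity, and build a seeded
co-expression network around the targets.  This note records the model
behind each stage, the tunable parameters, and the design choices made
where the workflow is conventionally under-specified.

## Conventions

All coordinates are 1-based, fully closed intervals (`length = stop −
start + 1`).  Sequences are accepted in DNA or RNA alphabet; all miRNA
arithmetic is performed after `T→U` normalisation, and miRNA/precursor
output is written in the RNA alphabet.  T and U are equivalent in every
comparison; IUPAC ambiguity codes never match anything, including
themselves.

## EST cleaning and assembly

Cleaning masks every maximal exact substring (either strand, ≥
`mask_min_match` = 20 nt) shared with a user-supplied contaminant FASTA
to `N`, trims terminal `N` runs, and then discards reads shorter than
`min_est_len` = 100 nt or with an ambiguous-base fraction strictly
greater than `max_ambig_frac` = 0.04 (exactly 4.0% is kept).  Exact
k-mer masking replaces the usual vector/organelle database screens so
the contract is fully testable without external databases.

Assembly is a greedy ungapped overlap-layout-consensus.  All dovetail
and containment offsets between two sequences are scored at once by
one-hot cross-correlation; an overlap qualifies when it spans ≥
`min_overlap_len` = 40 nt with identity strictly above
`overlap_identity` = 0.80 (the identity cutoff is the published
parameter; the minimum overlap length is an implementation choice
exposed in the configuration).  The longest qualifying overlap in the
whole pool is merged first (ties: identity, then lexicographically
smallest member ids), consensus is per-column majority with ties going
to the longest covering member, and reverse-complement overlaps are
allowed, with each contig reported on the strand of its
lexicographically first member.  The procedure is deterministic;
raising the identity cutoff can only split, never merge.

## Homology scan

Candidate generation is an exhaustive scan rather than a heuristic
search: every window on either strand of a unigene is tested against
every reference mature miRNA.  A window is reported when it aligns
within an edit budget of `max_mismatch_scan` = 4, where substitutions
cost 1 and every bulged nucleotide costs 1, subject to at most
`max_bulges_scan` = 3 bulge events of at most `max_bulge_size_scan` =
3 nt each.  Counting bulged nucleotides against the same budget keeps
the stage discriminative: under a "free gaps" reading, deleting 9 of 21
reference bases plus 4 free mismatches accepts windows essentially
everywhere in uniform-random sequence (~80 hits per 500-nt EST when we
measured it), which is analytically useless and computationally
crushing for the folding stage.  G:U wobble counts as a plain mismatch,
which is the convention that reconciles the published mismatch counts
with Hamming distance on the published sequences.  With the bulge
machinery disabled the scan reduces exactly to sliding-window Hamming
comparison, a property the test suite checks against an independent
oracle.  The bounded-bulge search is a vectorised dynamic program over
(reference position, diagonal offset, bulges used); accepted starts are
re-aligned exhaustively to report mismatch count, bulge count and
window length.  Overlapping hits to the same reference collapse to the
most parsimonious alignment (lowest edit weight, then mismatches, then
leftmost).

The exclusion screen replaces BLAST E-value searches against ncRNA and
protein databases with an ungapped local-identity filter: a unigene is
dropped when it matches an exclusion reference at identity ≥ 0.9 over ≥
0.8 of the reference length (both strands).  Both values are
configuration-exposed.

## Precursor validation

Around each hit a ladder of excision windows is evaluated: total
lengths from mature+20 nt up to `precursor_max_window` = 320 nt in
steps of 20 nt, with the flank placed entirely upstream, split evenly,
or entirely downstream (the published workflow reports resulting
windows of 58 and 200 nt but not the search procedure; the ladder is
our policy, exposed in configuration).  Windows are folded at
`fold_temperature` = 25 °C with ViennaRNA's nearest-neighbour MFE
model; the engine's interior-loop cap is 30 nt, which equals the
configured `max_loop_size`.  For each window we compute

* `AMFE = MFE / length × 100` (kcal/mol per 100 nt),
* `MFEI = AMFE / GC%` (signed; the threshold applies to the magnitude),

and duplex statistics of the mature within the dot-bracket structure.

The miRNA:miRNA* duplex is defined as the longest antiparallel pairing
chain of the mature — positions increasing, partners strictly
decreasing, partners outside the mature itself, and consecutive chain
pairs separated by at most 3 nt on either strand, so pairing scattered
across unrelated helices cannot masquerade as one duplex.  From the
chain we report:

* `n_flanked_bases` — mature bases outside the chain span at either
  end (our reading of the "flanked bases" feature; the source material
  does not define it, and the header says so);
* `duplex_mismatch` — mature bases inside the span that are not
  Watson-Crick paired within the chain.  Wobbles, bulged-out bases and
  off-chain pairings all count: a G:U pair satisfies the folding engine
  but not complementarity, matching the scan's semantics;
* `duplex_bulges` / `max_bulge` — asymmetric interruptions and their
  largest size;
* `duplex_interruptions` — all helix breaks, symmetric or not;
* `star_start` / `star_stop` — the miRNA\* span (the chain partners'
  extent), reported in unigene coordinates alongside the precursor
  window, as this tool family conventionally does.

A window passes when all of the following hold:

1. the mature lies wholly on one arm (`five_prime`/`three_prime`): its
   chain partners sit on one side, and exactly one terminal loop lies
   between the innermost duplex pair — mature and star must be the two
   arms of a single stem-loop, not ends of a multibranched fold;
2. `|MFEI| ≥ mfei_threshold` = 0.6 (the published cutoff);
3. `duplex_mismatch ≤ max_duplex_mismatch` = 4 (the published cap);
4. `n_flanked_bases ≤ max_flanked_bases` = 4 — roughly the two-nt 3′
   overhangs of a Dicer product per end; a mature paired over less than
   half its length has no real star;
5. `duplex_interruptions ≤ max_duplex_interruptions` = 4 — a Dicer
   substrate is a largely regular helix; the bound still admits four
   isolated internal mismatches, the documented boundary case.

Criteria 1, 4 and 5 deserve a candid note.  The published thresholds
alone (2 and 3, plus a loose arm notion) do **not** separate genuine
hairpins from chance structure: in our measurements, upwards of 60% of
"shuffled precursor" negative controls — mature kept intact, all other
precursor bases permuted, embedded in random hosts — passed them,
because MFE folds of 100–300 nt random RNA routinely pair a 21-mer into
gap-riddled chance helices, and maximising |MFEI| over a window ladder
compounds the multiple-testing effect.  The three structural criteria
above are the package's definition of a well-formed duplex; with them
the synthetic benchmark separates cleanly: 100% of intact planted
hairpins with ≤4 mature substitutions and ≤4 internal duplex mismatches
validate, and destroying a planted hairpin always destroys its
validation — no control's shuffled precursor ever supplies the star of
a passing duplex.  The criteria are definitions of the duplex, not
tuned energy cutoffs; all published numeric thresholds are used exactly
as printed.

One false-positive mode remains and is reported honestly rather than
suppressed: on the order of 2% of random 100–300 nt contexts contain a
*bona fide* chance stem-loop whose arm happens to match a scanned
mature, with a star drawn from plain background sequence.  Such a
structure satisfies every criterion a desk method can state — it *is* a
hairpin — and the same events occur in real EST mining.  The reported
star coordinates let a user distinguish where a validated duplex draws
its star from, which is also how the benchmark separates "recovered the
planted precursor" from "found an unrelated chance hairpin in the
flank".

Among passing windows the one with the largest |MFEI| wins (ties:
shortest, then leftmost); if none passes, the best-scoring failure is
returned with machine-readable reasons (`arm`, `mfei`, `duplex`,
`flank`, `gaps`).

## Target prediction

Transcript windows of miRNA length on the sense strand are scored by
antiparallel complementarity: miRNA position *p* (1 = 5′ end) pairs the
window base *L − p + 1*.  A site is accepted when at most one mismatch
falls at positions 1–9, none at positions 10–11, no more than two
mismatches are consecutive, and the total is at most
`max_target_mismatch` = 4 (the total cap mirrors the discovery-side
cap; the positional rules are the published defaults).  G:U wobble is a
full mismatch by default; `wobble_weight = 0.5` half-weights wobbles in
the totals and the 1–9 cap (positions 10–11 still require perfect
pairs, and wobbles then stop counting toward consecutive runs).  Sites
are ungapped because the positional rules are defined over miRNA
coordinates, which gaps would make ambiguous.  Overlapping accepted
windows for one miRNA–transcript pair collapse to the lowest-total
(then leftmost) site.  The inhibition mechanism is labelled `cleavage`
when positions 9–11 are all perfectly Watson-Crick paired and
`translation` otherwise; the rule used by the original tool chain is
not recoverable, so ours is a documented substitute, and it is
config-replaceable in the sense that it is a pure function of the site.

Unpaired-energy (UPE) accessibility scores are not computed: they
require a target-accessibility model the workflow does not specify.

## Co-expression network

The multi-evidence network service used in the original workflow is
replaced by its desk-scale computable core: a Pearson correlation graph
over a gene-by-sample matrix, seeded by the predicted target genes.
Edges require `r ≥ corr_threshold` = 0.7 (`signed` mode) or `|r| ≥
threshold` (`absolute` mode) and at least one endpoint in the 1-hop
closure of the seed set, which bounds the output the way a seeded
network service does.  Zero-variance genes are excluded with a warning;
missing seeds stay as isolated nodes.  Transcription-factor and kinase
calls are an exact-id join against a user annotation table rather than
homology searches against TF/kinase databases.

## Synthetic data

The generator provides ground-truthed inputs for every stage:

* reference matures: uniform random RNA, 19–24 nt (the mature miRNA
  length range);
* hairpins: `5′arm + loop + 3′arm` with the arms exact reverse
  complements except for a chosen number of internal mismatches in the
  non-mature arm; stem padding makes 58-nt and 200-nt precursors (the
  published sizes) representable.  Mismatch positions are kept ≥ 4 nt
  apart and away from the arm ends, substituted bases are chosen to
  pair with neither the designated partner nor its neighbours, and the
  loop avoids bases that could pair the stem's inner ends — otherwise
  the MFE fold merges the designed 1×1 loops or slips the helix
  register instead of looping the mismatches out;
* EST libraries: uniform-random background reads of 100–900 nt with
  ambiguous bases at rate 0.005, deliberately defective reads (short /
  N-rich) flagged in the truth, and hosts embedding each precursor at a
  recorded offset.  Mature substitutions relative to the reference are
  compensated on the star arm, so a "diverged ortholog" plant keeps an
  intact hairpin; shuffled controls keep the mature verbatim and
  permute every other precursor base, so the scan still finds them and
  the validator must reject them.  Because the permuted bases contain
  the complement multiset of the mature, a blind permutation
  occasionally re-assembles a partial duplex; the shuffle is therefore
  rejection-sampled (deterministically under its seed) until the mature
  shows no near-duplex when the candidate is folded in two random pad
  contexts, with full randomisation of the non-mature bases as a
  fallback.  Context dependence of MFE folding leaves a residual
  re-assembly rate of roughly one control in 150, which is the
  generator's known imperfection, not the validator's;
* target transcripts: planted sites that either satisfy all positional
  rules or break exactly one named rule, enabling per-rule rejection
  accounting;
* expression matrices: module genes are `√r·latent + √(1−r)·noise`, so
  the expected within-module correlation is `r`; other genes are
  independent noise.

Every generator is a pure function of its arguments including the
seed.  The background model is i.i.d. uniform sequence: it folds
poorly, which makes hairpin validation discriminative, but it lacks
real-EST features (chromatogram errors, poly-A tails, codon structure,
compositional bias), so passing recovery tests demonstrates internal
consistency of the pipeline, not performance on real libraries.

## Problem sizes and numerics

The bundled end-to-end benchmark uses a 200-EST background with 20
planted hairpins (0–4 mature substitutions, 0–2 internal mismatches)
and 10 shuffled controls, scanned against 8 references — sizes chosen
so the full suite runs in about a minute on one core while every stage
still sees non-trivial input.  Floats in result tables are written with
three decimals.  Degenerate inputs are defined rather than crashed on:
a GC-free window has undefined MFEI (flagged fail, except MFE = 0 which
gives MFEI = 0), an all-singleton assembly reports mean contig length 0
with an explicit flag, and an empty exclusion set passes hits through
unchanged.

## Known limitations

* The assembler is intentionally not CAP3: no gapped consensus, no
  quality values, no chimera detection.  Indel-divergent reads will not
  merge.
* Scan sensitivity for bulged homologs is bounded by the edit-weighted
  budget; a homolog with a 4-nt bulge plus 4 substitutions is outside
  it.
* The duplex definition is structure-derived from a single MFE fold; a
  precursor whose functional structure differs from its MFE structure
  can be misjudged.
* The co-expression stage models only correlation evidence; it does not
  attempt to reproduce multi-evidence network weighting, and the
  published figure's exact edges are out of scope.
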