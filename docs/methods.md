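# Methods

This note documents the models, parameter choices and numerical
behavior of `t2tkit` — what each stage assumes, where the design was
genuinely open, and what the synthetic-data tests do and do not show
about real assemblies.

## Coordinates and formats

All library coordinates are 0-based half-open. AGP is emitted 1-based
inclusive per the AGP v2.1 standard; BED is 0-based half-open. FASTA
input is uppercased on read; soft-masking is not preserved (masking is
out of scope). Spacer gaps introduced between anchored contigs are
written as AGP `N` rows with gap_type `scaffold`, linkage `yes`,
evidence `align_genus`, with a fixed length of `spacer_gap_len`
(default 100 bp) — gap sizes are not estimated.

## Global alignment (`pairwise`)

`global_align` is a Needleman–Wunsch dynamic program with linear gap
cost, defaults match +2 / mismatch −7 / gap −7, mirroring the
tandem-repeat weights used elsewhere so that one identity notion runs
through the whole toolkit. Two numerical choices matter:

- **Canonical statistics.** Optimal alignments are generally not
  unique, and different optima can decompose into different column
  counts. The DP therefore maximizes (score, matches)
  lexicographically. With mismatch ≠ 2·gap this determines matches,
  mismatches, insertions and deletions uniquely, making identity a
  well-defined, swap-symmetric function of the input pair. Residual
  traceback ties (which cannot change any count) break diagonal, then
  up, then left.
- **N scoring.** N is a mismatch against everything, including N, so
  ambiguous sequence can never inflate identity. A useful corollary,
  exploited by the tests: a flank carrying n N-substituted positions
  out of L has identity exactly (L−n)/L under any optimal alignment,
  whereas ordinary base substitutions can be partially recovered by
  gapped realignment (with these weights an aligner will happily trade
  gaps for chance matches inside a substituted block), so N is the only
  way to engineer an exact identity.

The implementation is vectorized row-wise and intended for pairs up to
a few tens of kilobases (memory grows as the product of lengths); the
toolkit only ever calls it on flank-sized or monomer-sized sequences.

`canonical_monomer` returns the lexicographically smallest string
among all rotations of a sequence and of its reverse complement. It
fixes a *reporting* convention. It is deliberately **not** used as the
basis of monomer comparison, because the minimal rotation is unstable
under divergence: a single substitution near the minimum moves the
chosen phase (or strand) arbitrarily far. Monomer identity for
clustering is instead rotation- and strand-aware: the best rotation of
the representative is located by an infix edit-distance search against
the representative doubled, then scored with the exact global
alignment, taking the better strand. This is deterministic and bounds
the phase error independently of divergence.

## Anchor mapping (`mapper`)

`map_query` finds exact k-mer anchors (k = 15, N-containing k-mers
excluded) on both strands and chains them greedily in target order: an
anchor extends a chain when it advances both query and target by at
most `chain_max_gap` (2 kb). Chains with fewer than 3 anchors are
dropped; matches are counted as non-overlapping anchor bases, and
identity = matches / max(query span, target span) is an
underestimate of true alignment identity — which is why gap filling
re-verifies every flank hit with `global_align` before applying the
0.80 threshold. Queries of 200 kb and larger are anchored at a stride
of 4 positions (still below k, so query coverage stays gapless) to
bound the chaining workload.

During contig anchoring, query k-mers occurring more than
`anchor_max_occ` (50) times in a target are skipped: anchors inside
satellite or telomeric arrays carry no placement information and make
chaining quadratic. The cap is *not* applied when mapping monomers for
centromere localization, where repetitive hits are the signal.

On i.i.d. random background (the generator's model) a chance 15-mer
match has probability 4^−15 ≈ 9·10^−10 per position pair, so a 5-kb
random query against a 100-kb target expects ≪ 1 anchor and the
no-hit assertions in the tests are essentially deterministic.

## Anchoring (`anchoring`)

Per contig: the best chromosome maximizes summed matches; orientation
is the strand with the larger matched total there; the anchor position
is the match-weighted median of target-interval midpoints, which is
robust to a minority of spurious chains. Contigs whose aligned-base
union covers less than `min_anchor_fraction` (0.5) of their length are
reported unplaced rather than forced into the plan — the premise of
reference-guided finishing is that contigs outrank the guide's joins,
so poor support is evidence of guide error. No contig is ever cut;
contigs with overlapping reference spans are both kept and ordered by
anchor position. Exact chromosome ties break lexicographically and are
logged.

## Gap filling (`gapfill`)

Flanks are up to `flank_window` (20 kb) of non-N sequence on each side
of a gap. For each donor and strand, the best hit per flank is
re-verified with `global_align` on the hit intervals; a candidate
needs block length ≥ `flank_min_len` (1000) **and** identity ≥
`flank_min_identity` (0.80) on *both* flanks — inclusive bounds — with
consistent left-to-right order on the (orientation-corrected) donor.
"Most consensus" donor selection is operationalized as the
deterministic argmax of (mean flank identity, total flank block
length, lexicographically smallest donor id); flank identity is the
only consensus signal the procedure quantifies.

The replaced object interval runs between the inner ends of the two
flank alignments (the gap-tied sequence, N run included), so eroded
gap edges are healed by the donor. Flank alignments that overlap on
the donor are treated as abutting contigs: the overlap is trimmed from
the right side of the splice, and a zero-length spanning segment is a
legitimate closure (this is exactly what happens when a spacer gap
joins two contigs that truly abut). If the trim exceeds either flank
alignment the gap is marked `inconsistent_span` and skipped. Gaps are
processed right-to-left so earlier coordinates stay valid; a liftover
table maps all unreplaced blocks old→new, and conservation outside the
replaced intervals is asserted in the tests. A single spanning donor
is required per gap; joint two-donor patches are out of scope.

## Telomeres (`telomere`)

The scanner searches exact occurrences of each configured unit and its
reverse complement inside a terminal window (50 kb) at each chromosome
end. The default unit set is `("AAACCCT", "CCCATTT")`: the plant
telomeric repeat appears in the literature both as the normalized
query AAACCCT (a rotation of the C-rich strand CCCTAAA) and as the
5′-arm written form CCCATTT, and the two are *not* rotations or
complements of one another, so a single 7-mer cannot cover both
conventions; scanning a small unit set, each with its reverse
complement, keeps the search strand-closed (the mirror law is exact)
and insensitive to which convention produced the data. Matches are
grouped into runs when consecutive occurrences are ≤
`telomere_max_gap` (100 bp) apart; the run nearest the chromosome end
is called once it has ≥ `telomere_min_units` (10) occurrences — chosen
because a single unit is never a telomere while the shortest
biologically reported arrays are ~70 units. Call polarity comes from
window position, not match strand. Because occurrences are counted in
a fixed phase, a planted array of n units yields n or n−1 counts and
its span may start/end up to one unit (7 bp) inside the array; the
tests assert recovery at that tolerance. Both span and unit count are
reported, since published telomere "lengths" are ambiguous between the
two.

## Tandem arrays and centromeres (`centromere`)

The detector's contract follows the classic TRF parameterization
(weights 2/7/7, minimum score 50, maximum period 500) but the
algorithm is this package's own; equivalence with the TRF binary's
output is not claimed — recovery of planted ground truth is the
correctness surface.

Detection: inside a tandem array, the distance between consecutive
occurrences of the same intact k-mer equals the period (plus the net
indel drift, which is zero more often than any other single value at
the divergence levels of interest), so the integer mode of
previous-occurrence distances recovers the period exactly. Distances
are clustered into bands (±3), bands are segmented positionally, and
each candidate is validated by stepping a seed monomer copy-by-copy
with a prefix edit-distance alignment, accepting copies at ≥ 0.7
identity, rebuilding the consensus by column-wise majority vote over
the aligned copies, then re-stepping with the voted consensus and
scoring Σ(2·matches − 7·mismatches − 7·indels). Arrays extend at both
ends while copies keep passing. Harmonic candidates (period ≈ m× a
stronger overlapping array's period, seeded by k-mers skipping mutated
copies) are dropped when the shorter period explains the region at
comparable score. Overlapping same-period arrays merge.

Localization: cluster representatives are mapped genome-wide (no
occurrence cap); per 10-kb bin the covered-base fraction is computed;
bins ≥ `cen_bin_cov_min` (0.2) merge across ≤ `cen_merge_gap_bins` (5)
non-qualifying bins; candidate regions < `cen_min_len` (50 kb) are
dropped; the region with most covered bases is the single call per
chromosome, its boundaries snapped to qualifying-bin edges and refined
to the outermost overlapping tandem-array edges. These four numbers
were fixed once so that planted arrays ≥ 100 kb at ≤ 10% divergence
are always recovered while i.i.d. random sequence never qualifies (the
probabilistic no-false-positive tests check this); they are
configurable for real data, where "continuous and high-frequency" has
no canonical quantification. The dominant monomer of a call is the
cluster covering most array bases inside it (ties: longer total array
span, then smaller cluster id), and the representative monomer length
is the mode of dominant lengths across chromosomes (ties: smaller
length).

The 50-kb window similarity matrix uses Jaccard similarity of
strand-canonical 15-mer sets — chosen over alignment-based similarity
for determinism and speed; for two i.i.d. random 50-kb windows the
expected Jaccard is ≈ 10^−4, so satellite blocks stand out by orders
of magnitude.

## Synthetic genomes (`synthetic`)

Each chromosome is: 5′ telomere array (CCCATTT, 400 units ≈ 2.8 kb by
default, inside the reported 0.5–16 kb range) + random sequence + one
centromeric array (153-bp monomer by default, 300-kb span, 2% per-base
divergence between copies, optionally a two-monomer mixture in stated
fractions or a higher-order unit of 2–3 distinct monomers repeated
head-to-tail) + random sequence + 3′ telomere array (TTTAGGG). The
divergence model is per-base substitution at the stated rate with 1-bp
indels at one tenth of it — enough to stress identity thresholds and
phase stability without modeling real mutational spectra. Haplotype 2
applies SNPs (0.002) and indels (0.0002) to everything *between* the
telomere arrays, so manifest telomere recounts stay exact while
centromere coordinates shift and are tracked. Everything is a pure
function of (parameters, seed).

What the generator does **not** emulate: sequencing error and read
structure, soft-masked or low-complexity background, segmental
duplications, interstitial telomeric sites, centromere drift between
haplotypes beyond point divergence, and realistic gap-length
uncertainty. Passing tests therefore demonstrate algorithmic
correctness on clean planted signal, not performance on real genomes —
on real data the mapper is expected to be replaced by an external
aligner via PAF import, and the localization thresholds revisited.

Breakpoints for contig fragmentation can be forced away from planted
repeat arrays (`avoid`): a junction inside a satellite array is
phase-ambiguous for any aligner, so byte-identical reconstruction is
only a well-posed target for breaks in unique sequence.

## Problem sizes in the test suite

The suite runs end-to-end finishing on a 2-chromosome × 3-Mb diploid
genome (nine junction gaps per haplotype), centromere recovery on
500-kb chromosomes with 100-kb arrays over five seeds × three
divergence levels × periods {120, 153, 178}, a 29-chromosome cohort
for the representative length, and 200 alignment-oracle pairs up to
300 bp. These sizes were chosen as the smallest at which every
detector operates in its intended regime (arrays ≫ `cen_min_len`,
contigs ≫ anchor resolution); all results are deterministic given the
seeds in the tests.

## Known limitations

- The mapper is a desk-scale stand-in: no minimizers, no base-level
  extension; genome-scale work should import PAF from a production
  aligner.
- `global_align` is quadratic in memory; it is a flank/monomer tool,
  not a chromosome aligner.
- The tandem detector reports one consensus per array; higher-order
  repeats are detected at their unit period and not decomposed into
  sub-monomers.
- Needle-style affine gap penalties (gapopen 10 / gapextend 0.5) are
  not reproduced; identity percentages from affine aligners can differ
  slightly near thresholds.
- One centromere call per chromosome by construction; secondary
  candidate regions surface only in diagnostics.
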