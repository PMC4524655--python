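# Methods

## The model

The PPARα/RXRα heterodimer binds a direct-repeat-1 (DR1) element: two
AGGTCA-like hexad half-sites in the same orientation separated by one spacer
base, with PPARα on the 5' half-site and RXRα on the 3' half-site.  PPARα
additionally reads sequence 5' of its hexad.  The package models the
composite site as 19 labelled positions in four segments:

    EXT5 −6 … −1 | HEXAD5 +1 … +6 | SPACER | HEXAD3 R+1 … R+6

Each (position, nucleotide) pair carries a **preference tier** derived from
competitive-inhibition strength: `OPTIMAL_GT80` (>80% inhibition),
`ALLOWED_60_80`, `ALLOWED_50_60`, or `NONPREFERRED`.  The tier matrix is
reconstructed from the three tier-wise consensus strings

| threshold | consensus |
|-----------|-----------|
| >80%      | `WAWVT-RGGBBA-H-RGKTYA` |
| 60–80%    | `DAWVT-RGGBBA-N-RGKTBA` |
| 50–60%    | `NAWVT-RGGBBA-N-RGKTBR` |

by assigning the optimal tier to nucleotides inside the strictest code and
each relaxed tier to the nucleotides that code newly admits.  The codes are
nested at every position, so the assignment is unambiguous, and
`consensus_at_threshold` inverts it exactly (a position admitting all four
bases prints `N`).

Two deliberate encoding choices:

- **Position −6 is modelled but never matched.**  The experimental series
  showed no binding preference at −6, so the matrix holds it uniformly
  unconstrained and the 18-position matching motif starts at −5.  The
  PPARα monomer model therefore constrains 12 contiguous bases
  (−5 … spacer) and the recognized 5' extension is 5 bp.
- **The 50–60% extension.**  The relaxed-most consensus is printed with a
  four-letter extension (`AWVT…`); the model treats −5 as fully
  unconstrained (`N`) at that tier, consistent with progressive relaxation
  outward from the core.  Nothing downstream depends on this tier; the two
  published scan/optimal tiers are unaffected.

## Matching and scanning

A `MatchPolicy` is a mismatch budget plus the set of positions where it may
be spent.  The default screen policy is budget 1 over `{+4, +5, +6, spacer}`
— one non-preferred base tolerated in the last three bases of the PPARα
hexad or the spacer.  Since the screen motif's spacer is already `N`, the
spacer can never actually consume budget; it is kept in the set for fidelity
to the stated rule (an alternative reading that excludes the spacer gives
identical results for exactly this reason).

Matching is per-window set membership: window base ∈ IUPAC set of the motif
code.  Anything outside A/C/G/T in the sequence (N, ambiguity codes) never
matches — conservative, so assembly gaps cannot produce hits.  Matching is
case-insensitive by default; `mask_lowercase=True` drops hits overlapping
soft-masked bases instead.  Scanning tests every offset; minus-strand
scanning compares each plus-strand window against the reverse-complemented
motif (compiled once), reports plus-strand coordinates, and returns the
matched word in motif orientation.  All overlapping hits are reported;
deduplication is the caller's concern.  Coordinates are 0-based half-open
internally and in BED output; the TSV report is 1-based inclusive.

Two oracles accompany the scanner and are used throughout the tests:
`motif_cardinality` / `enumerate_words` (exact word counts via the
product-over-positions formula summed over admissible mismatch patterns) and
`match_probability` (the same sum over per-position allowed/disallowed
frequency masses, giving the analytic per-window hit probability on i.i.d.
background).  The optimal motif accepts 12·18·3·8 = 5184 words; the screen
motif under budget 1 accepts 72 576.

## Promoter windows and the report

TSSs come from GTF transcript records (TSS = feature start on +, feature end
on −, converted to 0-based) or BED6 (chromStart on +, chromEnd−1 on −);
duplicate (gene, TSS, strand) triples are collapsed but distinct TSSs of one
gene are each scanned.  Windows are `[tss − flank, tss + flank + 1)` —
2·flank + 1 bp, the TSS base centred — clipped at contig ends; the default
flank is 2000.

Report rows annotate each hit relative to its gene: `ups`/`dns` by whether
the hit's gene-oriented 5'-most base precedes the TSS (a hit spanning the
TSS is classified by that lead base; a lead base exactly on the TSS counts
as `dns`), `forward`/`backward` by whether the hit strand equals the gene
strand, a gene-oriented signed distance (negative upstream), and the
highest stringency tier the matched word satisfies with zero mismatches.
The historical spellings `fowrd`/`bckwd` are accepted when reading reports.
Output is byte-stable: fixed column order, integer fields, deterministic row
sort by (contig, start, strand, gene).

## Synthetic data

`generate_background` draws bases i.i.d. with freq(G) = freq(C) = GC/2; the
default dataset is 50 windows of 4001 bp at GC 0.42 (window geometry
matching the ±2 kb screen; GC chosen as a typical mammalian
promoter-neighbourhood composition).  `sample_site` draws uniformly from a
motif's accepted words; `mutate_site` replaces chosen positions with a base
drawn uniformly from outside the optimal-tier set there, guaranteeing a
countable mismatch.  `plant_sites` inserts words (reverse-complemented for
minus-strand plants) at non-overlapping offsets and emits truth records;
`build_random_plan` places plants with cycling motifs, alternating strands
and cycling mutation loads (default cycle 0/1/2 — exact, within-budget, and
beyond-budget classes crossed with strand).  The generator is a pure
function of its spec: same spec, same bytes.

What the background does **not** emulate: dinucleotide/Markov structure,
CpG islands, repeats, and soft-masking of real promoters.  Passing recovery
tests therefore demonstrate correctness of the matching and bookkeeping
machinery (sensitivity and specificity against known truth under the stated
policy), not biological enrichment in real genomes.  A user-supplied
background can be substituted by passing pre-built records to
`plant_sites` directly.

## Numerical and degenerate-input choices

- Alignment consensus ties emit the IUPAC code of the tied set (lossless
  and deterministic) rather than an arbitrary winner.
- Empty inputs: scanning a sequence shorter than the motif returns an empty
  list; an empty report writes a header-only TSV; recovery ratios with zero
  denominators are reported as undefined (None/null), never 0.
- DR1 classification: the RXRα-compatible hexad set is the union of the
  three printed RXRα codes (`RGKTYA ∪ RGKTBA ∪ RGKTBR`), matching the
  observed 3' hexads of known response elements; a hexad in both the PPARα
  and RXRα sets is a dual PPRE/RXRE only when the spacer is A, because
  PPARα-independent RXRα binding requires the A spacer.
- Probability/cardinality sums iterate over mismatch-pattern subsets of the
  budget positions; with the default policy that is at most 5 terms, exact
  in integer arithmetic for cardinalities.

## Problem sizes used in the checks

The recovery experiment runs 50 × 4001 bp windows with 100 plants; the
scanner-vs-brute-force equivalence uses toy motifs exhaustively over all
length-8 sequences plus 10^5 random 24-mers; the empirical hit-rate check
uses 400 random 1.5-kb sequences against the analytic binomial interval.
These sizes give the statistical checks comfortable power (99% intervals)
while keeping the whole suite inside a coffee break on one core.

## Known limitations

- The reproduction of any published genome-wide hit list depends on the
  genome build and TSS annotation version; `scripts/mm9_scan.py` documents
  the published settings but ships no data and is not part of the tests.
- Tiers are categorical; the package deliberately does not model graded
  binding strength (no PWM/log-odds scoring) — the published definition is
  a tiered degenerate consensus, and the scan policy is defined in those
  terms.
- The mismatch budget is interpreted jointly across `{+4, +5, +6, spacer}`;
  with the screen motif this coincides with every alternative reading, but
  custom motifs with a non-N spacer code will feel the difference.
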