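# Methods

## Problem and model

`cnescan` identifies conserved non-coding elements (CNEs) between a
reference DNA sequence *x* and a query sequence *y*.  A CNE pair is
defined purely by user criteria: two substrings, one from each sequence,
whose lengths lie in `[l, u]` and whose *relative identity*

    identity(a, b) = 1 − d(a, b) / max(|a|, |b|)

reaches a threshold `t ∈ (0, 1]`, where `d` is the simple (unit-cost
Levenshtein) edit distance.  No whole-genome alignment or whole-genome
index (suffix array, BWT) is built; the search works directly on the two
sequences, which may be whole chromosomes, explicit coordinate ranges,
or windows around a gene of interest.

The identity denominator is a genuine design choice: normalising by the
longer of the two substrings penalises indel-length asymmetry and keeps
the score in `[0, 1]` (it equals the edit-distance budget `l − t·l` for
equal-length elements).  Users comparing scores against other tools
should note that reference-length or alignment-length normalisations
would give slightly different values on indel-bearing pairs.

## The three stages

**Seed.**  All maximal exact matches (MEMs) of length at least

    L_min = max( floor(l / (e + 1)),  user_anchor_len ),
    e = floor(l · (1 − t))

are enumerated.  The bound is the pigeonhole guarantee: two length-`l`
strings within `e` edits share an untouched aligned run of at least
`floor(l/(e+1))` bases, so no qualifying element can be missed at this
seed length.  `e` is floored because edit operations are integral, and
the product `l·(1−t)` is rounded at the 6th decimal before flooring so
that binary floating point cannot understate an integral budget (e.g.
`200 − 0.95·200` evaluates just below 10).  Seeding packs `k`-mers
(`k = min(L_min, 31)`, 2 bits/base in an int64) of the reference into a
sorted table, looks up the query `k`-mers, keeps only *left-maximal*
candidate pairs, and extends each to the right by direct comparison —
candidate verification is always literal, never probabilistic, so the
output is exactly the MEM set.  `N` terminates matches and never equals
anything, including another `N`: masked bases must not seed or inflate
identity.  The same convention is applied inside the edit distance by
renaming `N` to distinct sentinels on the two sides before calling the
Myers bit-vector routine (edlib).

**Merge.**  Anchors are chained greedily in (ref_start, query_start)
order.  A chain repeatedly absorbs, among unconsumed anchors that start
after its end in both sequences and within `merge_max_gap` of it, the
one minimising the summed ref+query gap (ties to the smaller query
start); each absorption pays the edit distance of the two gap
substrings.  The chain stops when no candidate exists, when a span would
exceed `u`, or when the next gap would push

    1 − gap_edit / max(ref_span, query_span)

below `t`.  Chains are kept only if their combined anchor length reaches
`min_chain_coverage`.  Greedy (rather than optimal DP) chaining is an
explicit choice: it matches the incremental-termination description of
the merging step, runs in near-linear time over millions of background
anchors, and the extension stage recovers modest chaining imperfections.
Anchors consumed by a discarded chain are not offered to later chains;
this keeps chaining single-pass and deterministic.

**Extend.**  Each chain hull is grown in windows of `ext_step` bases per
side.  The window pairing is straightforward: the left window of *x*
against the left window of *y*, right against right.  Both sides are
added when the *estimated* identity (accumulated gap + window distances
over the max span) stays at or above `t`, otherwise only the cheaper
side.  The estimate is an upper bound on the true edit distance of the
element, so when it would cross `t` the actual distance of the whole
current element is recomputed with the bit-vector algorithm and adopted
— identity can only be revised upward — and extension resumes; a second
refusal at the same point terminates.  Extension also stops at sequence
boundaries, at `N` runs, or when either span reaches `u`.  A hit is
emitted iff both final lengths lie in `[l, u]` and the re-measured
identity reaches `t`; every reported identity therefore comes from a
full-element distance computation, which is what makes the soundness
invariant (re-verification never fails) structural rather than
statistical.

**Deduplication.**  Hits whose reference AND query intervals
reciprocally overlap by more than 50% are grouped transitively; the
survivor has the highest identity, then the longest reference span, then
the smallest start.

## Preprocessing

Exons (GFF3 types `exon` and `CDS` by default) and repeats (BED tracks
and, by default, soft-masked lowercase runs) are masked by replacing
bases with `N` rather than deleting them, so all coordinates stay in
source-sequence space.  GFF3 (1-based inclusive) and BED (0-based
half-open) conversions happen only in the preprocessing module; output
is BED-convention half-open throughout.  Gene mode takes a fixed,
user-configurable flank (default 1 Mbp per side) around the single
feature matching the requested name; the window is not bounded by
neighbouring genes.

## Parameters

| name | default | meaning |
|---|---|---|
| `l` (`min_len`) | required | minimum element length, bp |
| `u` (`max_len`) | required | maximum element length, bp; either element reaching `u` halts extension |
| `t` (`identity_t`) | required | relative identity threshold in (0,1] |
| `user_anchor_len` | none | explicit seed length; the maximum of this and the derived bound is used |
| `min_chain_coverage` | `l // 2` | minimum combined anchor bp per chain |
| `merge_max_gap` | `l` | largest bridgeable gap; gaps longer than the minimum element rarely sit inside a ≥t element |
| `ext_step` | 5 bp | extension window per side per iteration; small enough to stop near the identity boundary, large enough to bound full-element recomputations |
| `--threads` | 1 | seed-stage blocking; output is provably identical for any value |
| `--flank` | 1,000,000 bp | gene-mode window per side |

Strand: the forward strand is searched by default; `--revcomp`
additionally searches against the reverse complement of the query and
reports those hits with strand `-` in original query coordinates.

## Synthetic data

The generator plants homologous segment pairs into independent random
backgrounds (default GC 0.41, human-like).  Each planted copy carries
*exactly* `ceil(divergence × length)` mutations at distinct positions —
substitutions always change the base, indels are single-base — so the
realized divergence is exact rather than binomially noisy and recovery
thresholds can be tight.  Decoys are planted the same way above the
divergence budget; fake exon features cover a configurable fraction of
the reference and never intersect planted elements.  The default
specification is the benchmark condition used throughout the tests:
1 Mbp reference, 0.5 Mbp query, 50 CNEs of 200–500 bp at 2% divergence,
10 decoys at 20% divergence.

The generator does **not** emulate substitution-rate heterogeneity,
multi-base indels, rearrangements, duplications, or real repeat
structure.  Passing recovery tests therefore demonstrates algorithmic
correctness under the stated divergence model, not performance on real
assemblies.

Recovery is scored by reciprocal overlap: a planted element counts as
recovered when some hit overlaps it by at least the threshold fraction
(default 0.8) of *both* intervals on *both* the reference and query
side.

## Numerical and degenerate-input choices

- Identity comparisons use a `1e-12` slack so a chain at exactly `t` is
  never rejected by floating-point noise.
- `identity_score("", "")` is an error; one-sided empties cost the
  length of the other string.
- Ambiguous IUPAC bases in input FASTA degrade to `N` (counted in the
  log); non-IUPAC characters are a hard error with position.
- All randomness flows through `numpy.random.default_rng(seed)`; the
  same seed reproduces generator output byte for byte.
- Worker blocking partitions query seed positions; extension reads the
  full sequences, so no block overlap is needed and the final sorted
  output is independent of block count by construction.

## Problem sizes in the test suite

Oracle-equivalence checks run the bit-vector distance against an
independent quadratic global-DP aligner (1000 random pairs, lengths
0–300) and the seeded MEM enumeration against a full match-matrix scan
(200 pairs, lengths ≤ 200, seed lengths 3/5/8).  The end-to-end
benchmark runs the default synthetic condition once (about half a minute
on one core); pipeline-level unit tests use a 30 kb / 20 kb pair.

## Known limitations

- Greedy chaining can, in adversarial anchor layouts, split what optimal
  chaining would join; extension usually, but not provably, repairs this.
- Elements longer than `u` (including a single exact match longer than
  `u`, as arises when `t = 1` on near-identical regions) are rejected
  rather than trimmed to a qualifying sub-interval.
- Affine or weighted gap costs, alignment traceback/CIGAR, multi-species
  comparison, and de novo repeat annotation are out of scope.
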