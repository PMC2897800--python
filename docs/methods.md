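# Methods

## Model

The library targets single-end short-read data (≈50 nt) from targeted
capture experiments, mapped by an aligner that refuses internal gaps but
tolerates unaligned read ends. A read crossing a small insertion or
deletion therefore appears as a soft-clipped alignment whose clip begins
at the breakpoint. Three layers of evidence are combined:

1. **Breakpoint statistic.** For every position `p` adjacent to a clip,
   with the gap-direction neighbour `p ± 1` (plus if `p` precedes the
   gap, minus if it follows it, on the forward strand), the counts
   `N(p)`, `N(p±1)` and `N(p & p±1)` are taken over *aligned spans only*
   — a clipped read does not cover positions under its clip, which is
   what makes the statistic sensitive. The score is the Jaccard index

   `r = N(p & p±1) / (N(p) + N(p±1) − N(p & p±1))`,

   defined as 1 when the union is empty (no reads ⇒ no breakpoint
   evidence; the least indel-like value). `r` is in [0, 1]; adding a
   read covering both positions can only raise it, adding a read
   covering only `p` can only lower it.

2. **Clipped-tail consensus.** All tails at one `(p, direction)` are
   stacked outward from `p` (left tails reversed), so index `i` of any
   tail corresponds to reference offset `i + 1` in the gap direction. At
   each offset the plurality base wins (ties lexicographic, for
   determinism), recording the agreement fraction; the consensus stops
   where the plurality drops below the agreement threshold or fewer than
   `min_consensus_support` tails extend.

3. **Classification by local realignment.** Hypotheses compared, for a
   consensus `c` at a right-side breakpoint (left is mirrored):
   * NULL — `c` matches the reference continuation at offset 1;
   * DELETION of `d ∈ 1..9` — `c` matches the reference starting at
     offset `d + 1`;
   * INSERTION of `i ∈ 1..9` — `c[i:]` matches the reference at offset
     1, and `c[:i]` is the inserted sequence.

   Each hypothesis gets a realignment score `matches − 2·mismatches`
   over its compared span; the best-scoring hypothesis wins provided its
   identity is ≥ 0.9 and its span ≥ 4 bases, with ties resolved toward
   NULL, then the smaller length, then deletion before insertion. A raw
   identity ranking was rejected because a short spurious perfect match
   would outrank a long near-perfect true hypothesis under realistic
   noise. For deletions the variant sequence is read from the reference
   (so it is exact by construction); for insertions it is read from the
   consensus.

   Opposite-direction sites describing the same variant are merged with
   summed support (a deletion leaves a right-clip site at its left edge
   and a left-clip site at its right edge). Sites that stay unresolved
   alone are re-examined jointly: the pair's geometry fixes the
   hypothesis (breakpoints `delta` apart ⇒ deletion of `delta − 1`;
   adjacent breakpoints ⇒ insertion, whose sequence must read identically
   from both tails), which resolves insertions whose tails are mostly
   novel sequence — a single tail bounded by the 20% clip cap rarely
   reaches `length + 4` bases past an insertion of ≥5 nt, but the two
   directions together do.

## Filters

Filters annotate candidates rather than delete them; PASS means the call
is resolved and fails nothing. All are independent, so annotation is
idempotent and order-free, and tightening any threshold can only shrink
the PASS set.

| filter | rule | default |
|---|---|---|
| r | pass iff `r <` threshold (strict) | 0.35 |
| support | pass iff clipped reads at the breakpoint ≥ min (inclusive) | 5 |
| known_variant | fail iff the affected span (deleted bases, or breakpoint + neighbour) covers a known polymorphic position | on |
| boundary | fail iff a breakpoint sits on the first/last base of a capture target, ± a window | window 0 |
| recurrent | fail iff otherwise-clean candidates occur at the same position in more than `max_samples` samples | 1 (indels), 2 (SNVs) |

Recurrence is keyed by position only, not allele: systematic capture and
mapping artifacts recur positionally. The boundary exclusion window
defaults to the bare first/last base because no principled wider width
exists; `--boundary-window` widens it.

Read admission, everywhere: primary alignment with MAPQ ≥ 1 ("uniquely
mapped"), at most 2 mismatches over the aligned span (NM), total clip at
most 20% of the read length. Reads whose CIGAR already contains internal
I/D operators still count for coverage and depth but are excluded from
clip-site evidence by default (their indel is the mapper's call, not
this library's); `--count-mapper-indels` reverses that. Their per-base
pileup contribution is also skipped, since a plain read-slice pairing
would be wrong for them.

## Single-base caller

Pileup over aligned bases only. A position is called when depth ≥ 3
(inclusive) and the plurality non-reference base exceeds 75% of the
*total* depth (strict: 3 of 4 does not call; N bases count in the
denominator, never as the alternate; tied alternates give no call). The
sub-unanimity allowance reflects sequencing of tumour material with a
minor normal-cell admixture; no explicit purity model is used.
Consequence annotation translates the containing codon with and without
the alternate, strand- and frame-aware (GFF-style phase), via the
standard nuclear codon table; codons truncated by a CDS edge are UNKNOWN.

## Synthetic data

The simulator emulates the study conditions the pipeline assumes: a
uniform-random reference (default 100 kb) carrying non-overlapping
capture targets (default 20 of 250–350 nt) each flanked by a read length
of accessible sequence; 50 nt single-end reads at mean depth 42 with a
uniform 1% per-base error rate across 12 samples; planted indels of 1–9
nt and substitutions with arbitrary carrier-sample sets. Reads are
placed at their true coordinates and a deterministic end-gapped rule
stands in for a mapper: the side of an indel junction keeping the clip
shortest is anchored and the remainder soft-clipped; reads whose clip
would exceed 20% of the read length are emitted unclipped at their best
ungapped placement, their unanchored side absorbed as mismatches (which
the NM filter then removes, as a real pipeline's mapping filter would).
Planted variants are kept ≥ 2 read lengths apart and ≥ 15 bases from
target edges so recovery scoring is unambiguous. Everything derives from
one seeded generator; identical configurations give byte-identical
FASTA/BED/SAM/truth outputs.

What this emulation deliberately omits: mapper-specific scoring, clips
caused by error clusters rather than variants, capture-efficiency and GC
bias, duplicates, quality strings, paired ends, and the two-base
color-space encoding of older ligation-based chemistry (its
double-mismatch error rule is subsumed by the nucleotide-space NM
filter). Passing tests therefore demonstrate the evidence logic —
statistic, consensus, realignment, filters — under the stated read
geometry, not robustness to every artifact of a particular instrument;
clips in this synthetic data arise only at true breakpoints, so observed
false-positive counts bound mapper-independent errors only.

## Numerical and design choices

* Internal coordinates are 0-based half-open everywhere; 1-based only in
  SAM/VCF/TSV output. Insertions anchor on the base to their left;
  deletions on their first deleted base — both clip directions then
  yield the same variant position, making merging exact.
* `min_consensus_support` defaults to 1: plurality still governs offsets
  where several tails extend, while single-tail extensions are retained
  because tails thin out linearly toward the clip cap and the
  classification identity threshold absorbs their rare errors. At
  Poisson-low-coverage sites, truncating at 2 can remove every
  reference-anchored base an insertion consensus has, making an
  otherwise clean variant unresolvable.
* Consensus ties, hypothesis ties and all output orderings are resolved
  deterministically; no randomness exists outside the simulator, and the
  run manifest records wall-clock time only on request, so every
  workflow is byte-reproducible.
* Degenerate inputs: sites whose neighbour falls outside the reference
  are reported as not evaluable rather than silently skipped; empty
  alignment sets produce header-only outputs; an empty union defines
  `r = 1`.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run on one to twelve samples
over a 100 kb reference with 20 targets (about 5–6 kb of target space,
roughly 6,000 reads per sample at 40×): large enough for Poisson depth
fluctuations and error-driven edge cases to appear, while a full run of
every check completes in well under a minute.

## Known limitations

* Indels of ≥ 10 nt, structural variants, inversions and translocations
  are out of scope by design; the clip cap truncates their evidence.
* Two real variants within two read lengths of each other violate the
  isolation assumption of both the classifier and the recovery scorer.
* The recurrence filter needs multiple samples to act; with one sample
  it is the identity.
* NM recomputation for records lacking the tag requires the reference
  and covers only reads without internal indels.
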