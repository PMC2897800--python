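# parmap

Detection of small (<10 nt) genomic insertions and deletions from
**partially mapped** single-end sequencing reads, together with a
companion pileup single-base variant caller, a candidate filter stack and
a synthetic exome-capture read simulator.

## The problem and the idea

Short-read mappers assign heavy penalties to gaps inside an alignment, so
a 50 nt read that crosses a small indel is usually not aligned through
it: the bases beyond the breakpoint are left unaligned as an end gap — a
SAM *soft clip*. Those clipped reads are exactly where the signal lives.
At a genuine indel, many independent reads terminate at the same
reference position `p`, so the set of reads covering `p` and the set
covering its neighbour in the gap direction, `p ± 1`, diverge. For each
clip-anchored site the library computes

```
N(p)        reads whose aligned span covers p
N(p ± 1)    reads covering the neighbour in the gap direction
N(p & p±1)  reads covering both

r = N(p & p±1) / ( N(p) + N(p±1) − N(p & p±1) )
```

i.e. the Jaccard index of the two read sets (`r = 1` when both sets are
empty). Low `r` means many reads stop dead at `p` — a putative
breakpoint. Candidate sites require `r < 0.35` (strict) and at least 5
clipped reads. The clipped tails are stacked into a per-offset plurality
consensus and realigned locally against the reference under deletion
hypotheses (the consensus matches the reference shifted `d` bases
outward) and insertion hypotheses (the first `i` consensus bases are
novel sequence), which recovers the variant's type, length and exact
sequence for indels of 1–9 nt. Candidates at capture-target boundaries,
over known polymorphisms, or recurring across many samples (systematic
capture/mapping artifacts) are filtered out.

The single-base caller is deliberately simple: a position is called when
at least 3 aligned reads cover it and the plurality non-reference base
exceeds 75% of the depth (strictly — 3 of 4 reads does **not** call),
with known-position exclusion, a cross-sample recurrence cap (kept only
when seen in ≤ 2 of the samples) and codon-aware synonymous /
non-synonymous annotation.

## Worked example

Simulate one sample at 40× depth, 50 nt reads, no errors, with two
deletions (3 and 6 nt) and two insertions (5 and 3 nt) planted, then call:

```
parmap simulate --seed 7 --samples 1 --depth 40 --error 0 \
    --indel DEL:3 --indel DEL:6 --indel INS:5 --indel INS:3 --out-dir sim
parmap parmap sim/S01.sam --reference sim/reference.fasta \
    --targets sim/targets.bed --out-dir run
```

`run/candidates.tsv` then contains one line per evaluated clip site; the
four PASS lines for this seed are:

```
sample  seq     pos_1based  direction  N_p  N_pm1  N_both  r  support  gap_consensus  call_type  call_length  call_sequence  filters_failed
S01     simref  33489       both       2    0      0       0  9        TTCGAGTTTC     DEL        3            GCA            PASS
S01     simref  64390       both       7    0      0       0  15       CACCGAGTTA     DEL        6            AATTTG         PASS
S01     simref  95593       both       12   9      0       0  19       TATTCGCGAC     INS        3            TAT            PASS
S01     simref  96870       both       14   10     0       0  24       CAAAGATTT      INS        5            CAAAG          PASS
```

Each planted variant is recovered at its exact position (`pos_1based` is
the first deleted base, or the anchor base left of an insertion), with
`r = 0` at the breakpoint (no read aligns across it), the summed clipped-read
support of both breakpoint directions, and the exact planted sequence in
`call_sequence`. `sim/truth.tsv` holds the planted variants for
comparison, and `parmap snv` / `parmap stats` run the single-base caller
and coverage summaries on the same inputs.

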