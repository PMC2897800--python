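"""Companion single-base variant caller.

Pileup of aligned (non-clipped) bases, threshold calling (depth >= 3 and
alternate fraction strictly > 75% of the total depth), known-polymorphism
exclusion, cross-sample recurrence filtering, and synonymous vs
non-synonymous classification against a CDS annotation.

The sub-100% consensus requirement reflects sequencing from tumour
material with a small admixture of normal cells; no explicit purity model
is attempted.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from .config import MappingParams
from .core import passes_mapping_filters
from .filters import cross_sample_filter
from .models import (
    CdsInterval,
    Consequence,
    KnownVariantSet,
    PartialAlignment,
    ReferenceSet,
    SNVCandidate,
)

logger = logging.getLogger("parmap")

_BASES = "ACGTN"
_BASE_LUT = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _BASE_LUT[ord(_b)] = _i
    _BASE_LUT[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class PileupColumn:
    """Aligned-base tally at one covered reference position."""

    seq_name: str
    pos: int
    counts: tuple[int, int, int, int, int]  # A, C, G, T, N

    @property
    def depth(self) -> int:
        return sum(self.counts)


def build_pileup(
    alignments: Iterable[PartialAlignment],
    reference: ReferenceSet,
) -> dict[str, np.ndarray]:
    """Per-sequence (5, L) base-count arrays; clipped bases are not counted.

    Reads whose CIGAR carries internal indels are skipped (their
    read-to-reference base pairing is the mapper's, not a plain slice).
    """
    piles = {name: np.zeros((5, reference.length(name)), dtype=np.int32)
             for name in reference.names()}
    for a in alignments:
        if a.has_internal_indel:
            continue
        sub = a.aligned_sequence()
        idx = _BASE_LUT[np.frombuffer(sub.encode(), dtype=np.uint8)]
        np.add.at(piles[a.seq_name], (idx, np.arange(a.start, a.end)), 1)
    return piles


def pileup_columns(piles: Mapping[str, np.ndarray]) -> Iterator[PileupColumn]:
    """Yield one PileupColumn per covered position, in genomic order."""
    for name in sorted(piles):
        counts = piles[name]
        covered = np.flatnonzero(counts.sum(axis=0) > 0)
        for pos in covered:
            yield PileupColumn(name, int(pos), tuple(int(x) for x in counts[:, pos]))


def call_snvs(
    piles: Mapping[str, np.ndarray],
    reference: ReferenceSet,
    min_depth: int = 3,
    min_fraction: float = 0.75,
    sample_id: str = "S1",
) -> list[SNVCandidate]:
    """Emit one candidate per position where the plurality alternate base
    reaches depth >= min_depth and fraction strictly > min_fraction.

    The fraction's denominator is the total depth at the position
    (N bases included); N never counts as an alternate; ties between
    alternates yield no call.
    """
    out: list[SNVCandidate] = []
    for name in sorted(piles):
        counts = piles[name]
        depth = counts.sum(axis=0)
        ref_idx = _BASE_LUT[np.frombuffer(reference[name].encode(), dtype=np.uint8)]
        alt_counts = counts[:4].astype(np.int64).copy()
        cols = np.arange(alt_counts.shape[1])
        acgt = ref_idx < 4
        alt_counts[ref_idx[acgt], cols[acgt]] = 0
        best_idx = alt_counts.argmax(axis=0)
        best_count = alt_counts.max(axis=0)
        ties = (alt_counts == best_count).sum(axis=0) > 1
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(depth > 0, best_count / np.maximum(depth, 1), 0.0)
        callable_mask = (
            (depth >= min_depth)
            & (best_count > 0)
            & (frac > min_fraction)
            & acgt
        )
        for pos in np.flatnonzero(callable_mask & ties):
            logger.info("%s:%d: tied alternate bases, no call", name, pos + 1)
        callable_mask &= ~ties
        for pos in np.flatnonzero(callable_mask):
            out.append(SNVCandidate(
                sample_id=sample_id,
                seq_name=name,
                pos=int(pos),
                ref_base=_BASES[ref_idx[pos]],
                alt_base=_BASES[best_idx[pos]],
                depth=int(depth[pos]),
                alt_count=int(best_count[pos]),
            ))
    return out


def _codon_at(
    reference: ReferenceSet, cds: CdsInterval, pos: int
) -> tuple[str, int] | None:
    """Reference codon containing ``pos`` (coding orientation) and the
    0-based offset of ``pos`` within it, or None when truncated."""
    seq = reference[cds.seq_name]
    if cds.strand == "+":
        first = cds.start + cds.frame
        if pos < first:
            return None
        codon_start = first + 3 * ((pos - first) // 3)
        if codon_start + 3 > cds.end:
            return None
        return seq[codon_start:codon_start + 3], pos - codon_start
    first = cds.end - 1 - cds.frame
    if pos > first:
        return None
    offset = first - pos
    hi = first - 3 * (offset // 3)   # highest genomic pos of the codon
    lo = hi - 2
    if lo < cds.start:
        return None
    codon_fwd = seq[lo:hi + 1]
    codon = codon_fwd.translate(_COMPLEMENT)[::-1]
    return codon, hi - pos


def annotate_consequence(
    candidate: SNVCandidate,
    annotation: Sequence[CdsInterval] | None,
    reference: ReferenceSet,
) -> Consequence:
    """Classify a substitution as synonymous/non-synonymous via the
    standard nuclear codon table, strand- and frame-aware."""
    if annotation is None:
        return Consequence.UNKNOWN
    containing = [c for c in annotation
                  if c.seq_name == candidate.seq_name and c.start <= candidate.pos < c.end]
    if not containing:
        return Consequence.NONCODING
    cds = containing[0]
    got = _codon_at(reference, cds, candidate.pos)
    if got is None:
        logger.info("%s:%d: codon truncated by CDS edge", candidate.seq_name, candidate.pos + 1)
        return Consequence.UNKNOWN
    codon, offset = got
    alt = candidate.alt_base
    if cds.strand == "-":
        alt = alt.translate(_COMPLEMENT)
    if any(b not in "ACGT" for b in codon) or alt not in "ACGT":
        return Consequence.UNKNOWN
    alt_codon = codon[:offset] + alt + codon[offset + 1:]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    return Consequence.SYNONYMOUS if aa_ref == aa_alt else Consequence.NONSYNONYMOUS


def snv_pipeline(
    per_sample_alignments: Mapping[str, Iterable[PartialAlignment]],
    reference: ReferenceSet,
    annotation: Sequence[CdsInterval] | None = None,
    known: KnownVariantSet | None = None,
    min_depth: int = 3,
    min_fraction: float = 0.75,
    max_samples: int = 2,
    nonsynonymous_only: bool = False,
    mapping: MappingParams | None = None,
) -> dict[str, list[SNVCandidate]]:
    """Multi-sample calling workflow.

    Per sample: admit reads, pile up, call.  Across samples: drop known
    polymorphic positions, drop positions recurring in more than
    ``max_samples`` samples (systematic artifacts), annotate consequences
    and optionally keep only non-synonymous changes.
    """
    mapping = mapping or MappingParams()
    calls: dict[str, list[SNVCandidate]] = {}
    for sample in sorted(per_sample_alignments):
        admitted = [a for a in per_sample_alignments[sample]
                    if passes_mapping_filters(a, mapping)]
        piles = build_pileup(admitted, reference)
        cands = call_snvs(piles, reference, min_depth, min_fraction, sample)
        if known is not None and len(known):
            cands = [c for c in cands if (c.seq_name, c.pos) not in known]
        calls[sample] = cands
    kept, _ = cross_sample_filter(calls, max_samples, key=lambda c: (c.seq_name, c.pos))
    out: dict[str, list[SNVCandidate]] = {}
    for sample, cands in kept.items():
        annotated = []
        for c in cands:
            c.consequence = annotate_consequence(c, annotation, reference)
            if nonsynonymous_only and c.consequence is not Consequence.NONSYNONYMOUS:
                continue
            annotated.append(c)
        out[sample] = annotated
    return out
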