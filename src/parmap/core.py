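"""Breakpoint evidence from end-clipped reads.

A read whose end the mapper could not align (a soft clip) leaves a
breakpoint at the last aligned base.  At a genuine indel many independent
reads terminate at the same position, so the sets of reads covering the
breakpoint ``p`` and its gap-direction neighbour ``p±1`` diverge.  The r
statistic is the Jaccard index of those two read sets: r near 1 means the
sets coincide (no evidence), r near 0 means many reads stop exactly at
``p``.  The clipped tails are then stacked into a plurality consensus and
realigned against the local reference under insertion/deletion hypotheses
of 1..9 nt to recover the variant type, length and sequence.

Coverage of a position always means the aligned (non-clipped) span
contains it; a clipped read does not cover positions under its clip.
That convention is what makes r sensitive at breakpoints.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from typing import Iterable, Sequence

import numpy as np

from .config import CoreParams, MappingParams
from .models import (
    CallType,
    ClipDirection,
    ClipEvent,
    GapConsensus,
    IndelCall,
    IndelCandidate,
    PartialAlignment,
    ReferenceSet,
    SiteCounts,
    TargetRegion,
)

logger = logging.getLogger("parmap")

SiteKey = tuple[str, int, ClipDirection]


class SiteOutOfBoundsError(ValueError):
    """The neighbour position p±1 falls outside the reference sequence."""


def passes_mapping_filters(aln: PartialAlignment, params: MappingParams) -> bool:
    """Read admission: unique, few mismatches, clip within the allowed fraction."""
    if not aln.is_unique or aln.mapq < params.unique_mapq:
        return False
    if aln.nm > params.max_mismatches:
        return False
    if aln.total_clip > params.max_clip_fraction * aln.read_length:
        return False
    return True


def collect_clip_events(
    alignments: Iterable[PartialAlignment],
    include_mapper_indels: bool = False,
) -> dict[SiteKey, list[ClipEvent]]:
    """Group clipped read ends by (sequence, breakpoint, direction).

    A right clip anchors at the last aligned base (p = end - 1) with the
    clipped bases in read order; a left clip anchors at the first aligned
    base (p = start) with the clipped bases reversed, so that index i of
    either tail corresponds to reference offset i + 1 in the gap direction.
    """
    events: dict[SiteKey, list[ClipEvent]] = defaultdict(list)
    for aln in alignments:
        if aln.has_internal_indel and not include_mapper_indels:
            continue
        if aln.right_clip:
            tail = aln.read_seq[len(aln.read_seq) - aln.right_clip:]
            ev = ClipEvent(aln.read_id, aln.end - 1, ClipDirection.RIGHT, tail)
            events[(aln.seq_name, ev.p, ev.direction)].append(ev)
        if aln.left_clip:
            tail = aln.read_seq[:aln.left_clip][::-1]
            ev = ClipEvent(aln.read_id, aln.start, ClipDirection.LEFT, tail)
            events[(aln.seq_name, ev.p, ev.direction)].append(ev)
    return dict(events)


class CoverageIndex:
    """Aligned-span interval index for fast covering-read counts."""

    def __init__(self, alignments: Iterable[PartialAlignment]):
        by_seq: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for a in alignments:
            by_seq[a.seq_name].append((a.start, a.end))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for seq, spans in by_seq.items():
            arr = np.asarray(spans, dtype=np.int64)
            self._starts[seq] = arr[:, 0]
            self._ends[seq] = arr[:, 1]

    def n_cover(self, seq_name: str, pos: int) -> int:
        starts = self._starts.get(seq_name)
        if starts is None:
            return 0
        return int(np.count_nonzero((starts <= pos) & (self._ends[seq_name] > pos)))

    def n_cover_pair(self, seq_name: str, a: int, b: int) -> int:
        """Reads covering both positions a and b (a < b)."""
        starts = self._starts.get(seq_name)
        if starts is None:
            return 0
        return int(np.count_nonzero((starts <= a) & (self._ends[seq_name] > b)))


def site_counts(
    index: CoverageIndex,
    seq_name: str,
    p: int,
    direction: ClipDirection,
    seq_length: int,
) -> SiteCounts:
    """N(p), N(p±1), N(p & p±1) and r = |∩| / |∪| at one clip site.

    r is defined as N_both / (N_p + N_pm1 - N_both), with r = 1 when both
    counts are zero (no reads, hence no evidence of a breakpoint).
    """
    neighbour = p + direction.step
    if not (0 <= p < seq_length) or not (0 <= neighbour < seq_length):
        raise SiteOutOfBoundsError(
            f"{seq_name}:{p} ({direction.name}): neighbour outside reference"
        )
    n_p = index.n_cover(seq_name, p)
    n_pm1 = index.n_cover(seq_name, neighbour)
    lo, hi = (p, neighbour) if direction is ClipDirection.RIGHT else (neighbour, p)
    n_both = index.n_cover_pair(seq_name, lo, hi)
    denom = n_p + n_pm1 - n_both
    r = 1.0 if denom == 0 else n_both / denom
    return SiteCounts(p, direction, n_p, n_pm1, n_both, r)


def site_counts_from_alignments(
    alignments: Iterable[PartialAlignment],
    seq_name: str,
    p: int,
    direction: ClipDirection,
    seq_length: int,
) -> SiteCounts:
    """Convenience wrapper building a one-shot CoverageIndex."""
    return site_counts(CoverageIndex(alignments), seq_name, p, direction, seq_length)


def gap_consensus(
    events: Sequence[ClipEvent],
    agreement: float = 0.5,
    min_support: int = 1,
) -> GapConsensus:
    """Per-offset plurality consensus of the clipped tails at one site.

    The consensus is truncated at the first offset where fewer than
    ``min_support`` tails still extend, or where the plurality fraction
    drops below ``agreement``.  Ties break by lexicographic base order.
    """
    if not events:
        raise ValueError("gap_consensus requires at least one clip event")
    key = (events[0].p, events[0].direction)
    if any((e.p, e.direction) != key for e in events):
        raise ValueError("clip events at mixed sites")
    tails = [e.clipped_seq for e in events]
    max_len = max(len(t) for t in tails)
    bases: list[str] = []
    fractions: list[float] = []
    for i in range(max_len):
        extending = [t[i] for t in tails if len(t) > i]
        if len(extending) < min_support:
            break
        counts: dict[str, int] = {}
        for b in extending:
            counts[b] = counts.get(b, 0) + 1
        top = max(counts.values())
        winner = min(b for b, c in counts.items() if c == top)
        frac = top / len(extending)
        if frac < agreement:
            break
        bases.append(winner)
        fractions.append(frac)
    return GapConsensus("".join(bases), len(events), tuple(fractions))


# --------------------------------------------------------------------------
# classification: hypothesis scan over the local reference


def _ref_offset_base(
    reference: ReferenceSet, seq_name: str, p: int, direction: ClipDirection, offset: int
) -> str | None:
    """Reference base at ``offset`` (>= 1) beyond p in the gap direction."""
    return reference.base(seq_name, p + direction.step * offset)


def _score_tail(
    cons: str,
    cons_start: int,
    reference: ReferenceSet,
    seq_name: str,
    p: int,
    direction: ClipDirection,
    ref_offset: int,
) -> tuple[int, int]:
    """Compare cons[cons_start:] against the reference starting at ref_offset.

    Returns (span, matches); the span shortens at the sequence end.
    """
    span = matches = 0
    for j in range(cons_start, len(cons)):
        base = _ref_offset_base(reference, seq_name, p, direction, ref_offset + (j - cons_start))
        if base is None:
            break
        span += 1
        if cons[j] == base:
            matches += 1
    return span, matches


def _deleted_sequence(
    reference: ReferenceSet, seq_name: str, p: int, direction: ClipDirection, d: int
) -> str:
    if direction is ClipDirection.RIGHT:
        return reference.fetch(seq_name, p + 1, p + 1 + d)
    return reference.fetch(seq_name, p - d, p)


def variant_position(call: IndelCall, p: int, direction: ClipDirection) -> int | None:
    """Canonical 0-based variant anchor shared by both clip directions.

    DELETION: first deleted base.  INSERTION: the reference base
    immediately left of the inserted sequence.
    """
    if call.call_type is CallType.DELETION:
        return p + 1 if direction is ClipDirection.RIGHT else p - call.length
    if call.call_type is CallType.INSERTION:
        return p if direction is ClipDirection.RIGHT else p - 1
    return None


def classify_indel(
    consensus: str,
    reference: ReferenceSet,
    seq_name: str,
    p: int,
    direction: ClipDirection,
    params: CoreParams | None = None,
) -> IndelCall:
    """Decide insertion vs deletion (and size/sequence) for one clip site.

    Hypotheses compared by realignment of the consensus tail against the
    local reference: DELETION of d shifts the expected reference
    continuation d bases outward; INSERTION of i treats the first i
    consensus bases as novel sequence and aligns the remainder at offset 1;
    the NULL hypothesis aligns the whole consensus at offset 1.  The
    highest-scoring hypothesis wins (score = matches - penalty*mismatches),
    subject to identity and span minima; ties prefer NULL, then the
    smaller length, then DELETION over INSERTION.
    """
    params = params or CoreParams()
    if len(consensus) < params.min_classify_length:
        return IndelCall(CallType.UNRESOLVED)

    # (score, null_rank, length, type_rank, call_type, length, identity)
    candidates: list[tuple[float, int, int, int, CallType, int, float]] = []

    def consider(call_type: CallType, length: int, span: int, matches: int, null: bool) -> None:
        if span < params.min_classify_span:
            return
        identity = matches / span
        score = matches - params.mismatch_penalty * (span - matches)
        type_rank = 0 if call_type is CallType.DELETION else 1
        candidates.append((score, 0 if null else 1, length, type_rank, call_type, length, identity))

    span, matches = _score_tail(consensus, 0, reference, seq_name, p, direction, 1)
    consider(CallType.UNRESOLVED, 0, span, matches, null=True)
    for d in range(1, params.max_indel_length + 1):
        span, matches = _score_tail(consensus, 0, reference, seq_name, p, direction, d + 1)
        consider(CallType.DELETION, d, span, matches, null=False)
    for i in range(1, min(params.max_indel_length, len(consensus)) + 1):
        span, matches = _score_tail(consensus, i, reference, seq_name, p, direction, 1)
        consider(CallType.INSERTION, i, span, matches, null=False)

    if not candidates:
        return IndelCall(CallType.UNRESOLVED)
    best = min(candidates, key=lambda c: (-c[0], c[1], c[2], c[3]))
    score, _, _, _, call_type, length, identity = best
    if call_type is CallType.UNRESOLVED or identity < params.classify_identity:
        return IndelCall(CallType.UNRESOLVED, score=score)
    if call_type is CallType.DELETION:
        seq = _deleted_sequence(reference, seq_name, p, direction, length)
        if len(seq) != length:
            return IndelCall(CallType.UNRESOLVED, score=score)
    else:
        seq = consensus[:length]
        if direction is ClipDirection.LEFT:
            seq = seq[::-1]
    return IndelCall(call_type, length, seq, score)


def classify_joint(
    cons_right: str,
    p_right: int,
    cons_left: str,
    p_left: int,
    reference: ReferenceSet,
    seq_name: str,
    params: CoreParams | None = None,
) -> tuple[IndelCall, int] | None:
    """Joint local realignment of an opposite-direction clip-site pair.

    The geometry of the pair fixes the hypothesis family: a left
    breakpoint ``delta = p_left - p_right`` positions downstream of a
    right breakpoint is consistent with a deletion of ``delta - 1`` bases,
    while ``delta == 1`` (adjacent breakpoints) is consistent with an
    insertion between them, whose sequence must read the same from both
    clipped tails.  Returns (call, variant position) or None.
    """
    params = params or CoreParams()
    delta = p_left - p_right
    best: tuple[float, IndelCall, int] | None = None

    def tally(pairs: list[tuple[str, str]]) -> tuple[int, int]:
        span = len(pairs)
        matches = sum(1 for a, b in pairs if a == b)
        return span, matches

    if 2 <= delta <= params.max_indel_length + 1:
        d = delta - 1
        pairs: list[tuple[str, str]] = []
        for j, base in enumerate(cons_right):
            ref = reference.base(seq_name, p_left + j)
            if ref is None:
                break
            pairs.append((base, ref))
        for j, base in enumerate(cons_left):
            ref = reference.base(seq_name, p_right - j)
            if ref is None:
                break
            pairs.append((base, ref))
        span, matches = tally(pairs)
        if span >= params.min_classify_span:
            identity = matches / span
            score = matches - params.mismatch_penalty * (span - matches)
            if identity >= params.classify_identity:
                seq = reference.fetch(seq_name, p_right + 1, p_left)
                best = (score, IndelCall(CallType.DELETION, d, seq, score), p_right + 1)
    elif delta == 1:
        for length in range(1, params.max_indel_length + 1):
            inserted: list[str] = []
            pairs = []
            feasible = True
            for g in range(length):
                from_right = cons_right[g] if g < len(cons_right) else None
                from_left = cons_left[length - 1 - g] if length - 1 - g < len(cons_left) else None
                if from_right is None and from_left is None:
                    feasible = False
                    break
                if from_right is not None and from_left is not None:
                    pairs.append((from_right, from_left))
                inserted.append(from_right if from_right is not None else from_left)
            if not feasible:
                continue
            for j in range(length, len(cons_right)):
                ref = reference.base(seq_name, p_left + (j - length))
                if ref is None:
                    break
                pairs.append((cons_right[j], ref))
            for j in range(length, len(cons_left)):
                ref = reference.base(seq_name, p_right - (j - length))
                if ref is None:
                    break
                pairs.append((cons_left[j], ref))
            span, matches = tally(pairs)
            if span < params.min_classify_span:
                continue
            identity = matches / span
            if identity < params.classify_identity:
                continue
            score = matches - params.mismatch_penalty * (span - matches)
            if best is None or score > best[0]:
                best = (score, IndelCall(CallType.INSERTION, length, "".join(inserted), score), p_right)
    if best is None:
        return None
    return best[1], best[2]


# --------------------------------------------------------------------------
# candidate assembly


def call_candidates(
    alignments: Iterable[PartialAlignment],
    reference: ReferenceSet,
    targets: Sequence[TargetRegion] | None = None,
    sample_id: str = "S1",
    mapping: MappingParams | None = None,
    core: CoreParams | None = None,
) -> list[IndelCandidate]:
    """Full per-sample evidence pass: clip sites -> r -> consensus -> call.

    Sites at an exact target start or end are not evaluated (read ends
    pile up at capture edges for reasons unrelated to variation).
    Opposite-direction sites supporting the same variant are merged with
    summed support; sites unresolved in isolation are re-examined jointly.
    Returned candidates are unfiltered (``filters_failed`` empty): run
    ``filters.apply_all`` to annotate them.
    """
    mapping = mapping or MappingParams()
    core = core or CoreParams()
    admitted = [a for a in alignments if passes_mapping_filters(a, mapping)]
    events = collect_clip_events(admitted, include_mapper_indels=mapping.count_mapper_indels)
    index = CoverageIndex(admitted)
    boundary: set[tuple[str, int]] = set()
    if targets:
        for t in targets:
            boundary.add((t.seq_name, t.start))
            boundary.add((t.seq_name, t.end - 1))

    raw: list[IndelCandidate] = []
    for key in sorted(events, key=lambda k: (k[0], k[1], k[2].value)):
        seq_name, p, direction = key
        if (seq_name, p) in boundary:
            continue
        try:
            counts = site_counts(index, seq_name, p, direction, reference.length(seq_name))
        except SiteOutOfBoundsError:
            logger.warning("site %s:%d (%s) not evaluable: neighbour out of bounds",
                           seq_name, p, direction.name)
            continue
        cons = gap_consensus(events[key], core.consensus_agreement, core.min_consensus_support)
        call = classify_indel(cons.sequence, reference, seq_name, p, direction, core)
        raw.append(IndelCandidate(
            sample_id=sample_id,
            seq_name=seq_name,
            site=counts,
            consensus=cons,
            call=call,
            var_pos=variant_position(call, p, direction),
            support=len(events[key]),
            breakpoints=((p, direction),),
        ))
    return _merge_candidates(raw, reference, core)


def _merge_pair(primary: IndelCandidate, other: IndelCandidate) -> IndelCandidate:
    """Fold ``other`` into ``primary`` (which keeps site/consensus/call)."""
    return IndelCandidate(
        sample_id=primary.sample_id,
        seq_name=primary.seq_name,
        site=primary.site,
        consensus=primary.consensus,
        call=primary.call,
        var_pos=primary.var_pos,
        support=primary.support + other.support,
        breakpoints=tuple(sorted(primary.breakpoints + other.breakpoints,
                                 key=lambda bp: (bp[0], bp[1].value))),
    )


def _merge_candidates(
    raw: list[IndelCandidate],
    reference: ReferenceSet,
    core: CoreParams,
) -> list[IndelCandidate]:
    by_seq: dict[str, list[IndelCandidate]] = defaultdict(list)
    for c in raw:
        by_seq[c.seq_name].append(c)
    out: list[IndelCandidate] = []
    for seq_name in sorted(by_seq):
        out.extend(_merge_one_sequence(by_seq[seq_name], reference, core))
    out.sort(key=lambda c: (c.seq_name, c.key_pos, c.site.p))
    return out

def _direction_of(c: IndelCandidate) -> ClipDirection:
    return c.breakpoints[0][1]


def _merge_one_sequence(
    cands: list[IndelCandidate],
    reference: ReferenceSet,
    core: CoreParams,
) -> list[IndelCandidate]:
    resolved = [c for c in cands if c.call.resolved]
    unresolved = [c for c in cands if not c.call.resolved]

    # 1. pair-merge resolved opposite-direction candidates for the same variant
    merged: list[IndelCandidate] = []
    rights = [c for c in resolved if _direction_of(c) is ClipDirection.RIGHT]
    lefts = [c for c in resolved if _direction_of(c) is ClipDirection.LEFT]
    used_left: set[int] = set()
    for rc in rights:
        match_idx = None
        match_dist = None
        for i, lc in enumerate(lefts):
            if i in used_left:
                continue
            if lc.call.call_type is not rc.call.call_type or lc.call.length != rc.call.length:
                continue
            dist = abs((lc.var_pos or 0) - (rc.var_pos or 0))
            if dist <= core.merge_tolerance and (match_dist is None or dist < match_dist):
                match_idx, match_dist = i, dist
        if match_idx is not None:
            lc = lefts[match_idx]
            used_left.add(match_idx)
            primary, other = (rc, lc) if rc.site.r <= lc.site.r else (lc, rc)
            merged.append(_merge_pair(primary, other))
        else:
            merged.append(rc)
    merged.extend(lc for i, lc in enumerate(lefts) if i not in used_left)

    # 2. joint resolution of unresolved opposite-direction pairs
    u_rights = [c for c in unresolved if _direction_of(c) is ClipDirection.RIGHT]
    u_lefts = [c for c in unresolved if _direction_of(c) is ClipDirection.LEFT]
    used_r: set[int] = set()
    used_l: set[int] = set()
    joint_hits: list[tuple[float, int, int, IndelCall, int]] = []
    for ri, rc in enumerate(u_rights):
        for li, lc in enumerate(u_lefts):
            delta = lc.site.p - rc.site.p
            if not 1 <= delta <= core.max_indel_length + 1:
                continue
            hit = classify_joint(
                rc.consensus.sequence, rc.site.p,
                lc.consensus.sequence, lc.site.p,
                reference, rc.seq_name, core,
            )
            if hit is not None:
                joint_hits.append((hit[0].score, ri, li, hit[0], hit[1]))
    for score, ri, li, call, var_pos in sorted(joint_hits, key=lambda h: (-h[0], h[1], h[2])):
        if ri in used_r or li in used_l:
            continue
        used_r.add(ri)
        used_l.add(li)
        rc, lc = u_rights[ri], u_lefts[li]
        primary, other = (rc, lc) if rc.site.r <= lc.site.r else (lc, rc)
        resolved_pair = IndelCandidate(
            sample_id=primary.sample_id,
            seq_name=primary.seq_name,
            site=primary.site,
            consensus=primary.consensus,
            call=call,
            var_pos=var_pos,
            support=rc.support + lc.support,
            breakpoints=tuple(sorted(rc.breakpoints + lc.breakpoints,
                                     key=lambda bp: (bp[0], bp[1].value))),
        )
        merged.append(resolved_pair)
    leftovers = [c for i, c in enumerate(u_rights) if i not in used_r]
    leftovers += [c for i, c in enumerate(u_lefts) if i not in used_l]

    # 3. absorb position-consistent leftover unresolved sites into resolved calls
    still: list[IndelCandidate] = []
    for uc in leftovers:
        host = None
        host_dist = None
        for i, mc in enumerate(merged):
            if not mc.call.resolved:
                continue
            dirs = {d for _, d in mc.breakpoints}
            if _direction_of(uc) in dirs:
                continue
            dist = abs(uc.site.p - (mc.var_pos or mc.site.p))
            if dist <= core.merge_tolerance + 1 and (host_dist is None or dist < host_dist):
                host, host_dist = i, dist
        if host is not None:
            merged[host] = _merge_pair(merged[host], uc)
        else:
            still.append(uc)
    return merged + still
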