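"""The candidate filter stack.

Filters annotate rather than delete: every candidate carries the set of
filter names it fails, a PASS candidate fails none, and each filter is
evaluated independently of the others (order-independent, idempotent).
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Callable, Hashable, Iterable, Mapping, Sequence

from .models import IndelCandidate, KnownVariantSet, TargetRegion

FILTER_R = "r"
FILTER_SUPPORT = "support"
FILTER_KNOWN = "known_variant"
FILTER_BOUNDARY = "boundary"
FILTER_RECURRENT = "recurrent"
FILTER_UNRESOLVED = "unresolved"


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the candidate filter stack.

    r_threshold: candidates pass only with r strictly below this.
    min_reads: minimum clip events supporting the breakpoint (inclusive).
    boundary_window: extra bases around a target start/end inside which
        candidates are discarded (0 = only the exact first/last base).
    max_samples_indel / max_samples_snv: recurrence caps — a variant seen
        at the same position in more samples than this is treated as a
        systematic artifact.
    exclude_known: drop candidates whose affected span covers a known
        polymorphism.
    """

    r_threshold: float = 0.35
    min_reads: int = 5
    boundary_window: int = 0
    max_samples_indel: int = 1
    max_samples_snv: int = 2
    exclude_known: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.r_threshold <= 1.0:
            raise ValueError("r_threshold must be in (0, 1]")
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")
        if self.boundary_window < 0:
            raise ValueError("boundary_window must be >= 0")


def filter_r(candidate: IndelCandidate, config: FilterConfig) -> bool:
    """Pass iff r < threshold (strict inequality)."""
    return candidate.site.r < config.r_threshold


def filter_support(candidate: IndelCandidate, config: FilterConfig) -> bool:
    """Pass iff at least ``min_reads`` clipped reads anchor the breakpoint."""
    return candidate.support >= config.min_reads


def filter_known_variants(candidate: IndelCandidate, known: KnownVariantSet | None) -> bool:
    """Pass iff the candidate's affected span covers no known polymorphism."""
    if known is None or len(known) == 0:
        return True
    start, end = candidate.affected_interval()
    return not known.overlaps(candidate.seq_name, start, end)


def _boundary_positions(targets: Sequence[TargetRegion]) -> dict[str, list[int]]:
    out: dict[str, list[int]] = defaultdict(list)
    for t in targets:
        out[t.seq_name].append(t.start)
        out[t.seq_name].append(t.end - 1)
    return out


def filter_boundary(
    candidate: IndelCandidate,
    targets: Sequence[TargetRegion] | None,
    config: FilterConfig,
) -> bool:
    """Pass iff no breakpoint sits on (or within the window of) a target edge."""
    if not targets:
        return True
    edges = _boundary_positions(targets).get(candidate.seq_name, [])
    for p, _ in candidate.breakpoints:
        if any(abs(p - b) <= config.boundary_window for b in edges):
            return False
    return True


def apply_all(
    candidates: Iterable[IndelCandidate],
    config: FilterConfig | None = None,
    known: KnownVariantSet | None = None,
    targets: Sequence[TargetRegion] | None = None,
) -> list[IndelCandidate]:
    """Annotate every candidate with the full set of failed filter names.

    Recomputes from scratch (idempotent).  Candidates whose call could not
    be resolved are additionally marked ``unresolved`` so that PASS means
    a concrete, fully-thresholded variant call.
    """
    config = config or FilterConfig()
    out = []
    for c in candidates:
        failed: set[str] = set()
        if not filter_r(c, config):
            failed.add(FILTER_R)
        if not filter_support(c, config):
            failed.add(FILTER_SUPPORT)
        if config.exclude_known and not filter_known_variants(c, known):
            failed.add(FILTER_KNOWN)
        if not filter_boundary(c, targets, config):
            failed.add(FILTER_BOUNDARY)
        if not c.call.resolved:
            failed.add(FILTER_UNRESOLVED)
        c.filters_failed = failed
        out.append(c)
    return out


def cross_sample_filter(
    per_sample: Mapping[str, Sequence],
    max_samples: int,
    key: Callable[[object], Hashable],
) -> tuple[dict[str, list], set[Hashable]]:
    """Remove candidates recurring across too many samples.

    A candidate is kept iff the number of distinct samples with any
    candidate at its key (position-based by convention) is <= max_samples.
    Returns the kept lists and the set of recurrent keys.
    """
    samples_per_key: dict[Hashable, set[str]] = defaultdict(set)
    for sample, cands in per_sample.items():
        for c in cands:
            samples_per_key[key(c)].add(sample)
    recurrent = {k for k, s in samples_per_key.items() if len(s) > max_samples}
    kept = {
        sample: [c for c in cands if key(c) not in recurrent]
        for sample, cands in per_sample.items()
    }
    return kept, recurrent


def annotate_recurrent_indels(
    per_sample: Mapping[str, Sequence[IndelCandidate]],
    max_samples: int,
) -> None:
    """Mark indel candidates at positions recurring in > max_samples samples.

    Recurrence is assessed among candidates that fail nothing else, so a
    position rejected everywhere cannot veto a clean singleton; the key is
    (sequence, position) only.
    """
    eligible = {
        sample: [c for c in cands if not (c.filters_failed - {FILTER_RECURRENT})]
        for sample, cands in per_sample.items()
    }
    _, recurrent = cross_sample_filter(
        eligible, max_samples, key=lambda c: (c.seq_name, c.key_pos)
    )
    for cands in per_sample.values():
        for c in cands:
            c.filters_failed.discard(FILTER_RECURRENT)
            if (c.seq_name, c.key_pos) in recurrent:
                c.filters_failed.add(FILTER_RECURRENT)
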