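"""Domain types shared across the pipeline.

Coordinates are 0-based half-open everywhere inside the library; 1-based
coordinates appear only at the SAM/VCF boundaries.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

_ALPHABET = set("ACGTN")


class ClipDirection(Enum):
    """Side of a read on which the unaligned (soft-clipped) tail sits.

    RIGHT: the clip extends toward higher reference coordinates; the
    breakpoint ``p`` is the last aligned base and its neighbour is ``p + 1``.
    LEFT: the clip extends toward lower reference coordinates; ``p`` is the
    first aligned base and its neighbour is ``p - 1``.
    """

    RIGHT = "+"
    LEFT = "-"

    @property
    def step(self) -> int:
        """Unit step along the reference in the direction of the gap."""
        return 1 if self is ClipDirection.RIGHT else -1


class CallType(Enum):
    INSERTION = "INS"
    DELETION = "DEL"
    UNRESOLVED = "UNRESOLVED"


class Consequence(Enum):
    SYNONYMOUS = "SYNONYMOUS"
    NONSYNONYMOUS = "NONSYNONYMOUS"
    NONCODING = "NONCODING"
    UNKNOWN = "UNKNOWN"


class ReferenceSet:
    """In-memory reference sequences: name -> uppercase A/C/G/T/N string."""

    def __init__(self, sequences: Mapping[str, str]):
        if not sequences:
            raise ValueError("reference set is empty")
        self._sequences: dict[str, str] = {}
        for name, seq in sequences.items():
            if not seq:
                raise ValueError(f"reference sequence {name!r} is empty")
            bad = set(seq) - _ALPHABET
            if bad:
                raise ValueError(
                    f"reference sequence {name!r} contains invalid characters {sorted(bad)}"
                )
            self._sequences[name] = seq

    @property
    def sequences(self) -> dict[str, str]:
        return self._sequences

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._sequences.items()}

    def names(self) -> list[str]:
        return list(self._sequences)

    def length(self, name: str) -> int:
        return len(self._sequences[name])

    def __contains__(self, name: str) -> bool:
        return name in self._sequences

    def __getitem__(self, name: str) -> str:
        return self._sequences[name]

    def fetch(self, name: str, start: int, end: int) -> str:
        """Substring [start, end) clamped to the sequence bounds."""
        seq = self._sequences[name]
        return seq[max(0, start):max(0, end)]

    def base(self, name: str, pos: int) -> str | None:
        """Base at ``pos`` or None when out of bounds."""
        seq = self._sequences[name]
        if 0 <= pos < len(seq):
            return seq[pos]
        return None


@dataclass(frozen=True)
class TargetRegion:
    """One capture-target interval (the 'exon' of the boundary filter)."""

    seq_name: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    label: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid target interval {self.start}..{self.end}")

    def __len__(self) -> int:
        return self.end - self.start


class KnownVariantSet:
    """Positions of known polymorphic sites, as (seq-name, 0-based pos)."""

    def __init__(self, positions: Iterable[tuple[str, int]] = ()):
        self._positions = frozenset(positions)

    @property
    def positions(self) -> frozenset[tuple[str, int]]:
        return self._positions

    def __len__(self) -> int:
        return len(self._positions)

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self._positions

    def overlaps(self, seq_name: str, start: int, end: int) -> bool:
        """True when any known position falls in [start, end)."""
        return any((seq_name, p) in self._positions for p in range(start, end))


@dataclass
class PartialAlignment:
    """One mapped read, possibly with soft-clipped (unaligned) end tails.

    ``read_seq`` is the full read in reference orientation; ``start``/``end``
    delimit the aligned reference span (clips excluded).
    """

    read_id: str
    seq_name: str
    start: int
    end: int
    strand: str
    read_seq: str
    left_clip: int = 0
    right_clip: int = 0
    nm: int = 0
    mapq: int = 0
    is_unique: bool = True
    has_internal_indel: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.read_id}: empty aligned span")
        if self.left_clip < 0 or self.right_clip < 0:
            raise ValueError(f"{self.read_id}: negative clip length")
        if not self.has_internal_indel:
            span = self.end - self.start
            if self.left_clip + span + self.right_clip != len(self.read_seq):
                raise ValueError(
                    f"{self.read_id}: clip/span/read-length mismatch "
                    f"({self.left_clip}+{span}+{self.right_clip} != {len(self.read_seq)})"
                )

    @property
    def read_length(self) -> int:
        return len(self.read_seq)

    @property
    def aligned_span(self) -> int:
        return self.end - self.start

    @property
    def total_clip(self) -> int:
        return self.left_clip + self.right_clip

    def aligned_sequence(self) -> str:
        """Read bases over the aligned span (valid for reads without internal indels)."""
        return self.read_seq[self.left_clip:len(self.read_seq) - self.right_clip]

    def covers(self, pos: int) -> bool:
        """A read covers a position only with its aligned (non-clipped) span."""
        return self.start <= pos < self.end


@dataclass(frozen=True)
class ClipEvent:
    """A single clipped read end anchored at breakpoint ``p``.

    ``clipped_seq`` is ordered outward from ``p``: index ``i`` corresponds to
    reference offset ``i + 1`` in the direction of the gap.
    """

    read_id: str
    p: int
    direction: ClipDirection
    clipped_seq: str

    def __post_init__(self) -> None:
        if not self.clipped_seq:
            raise ValueError("clip event with empty clipped sequence")


@dataclass(frozen=True)
class SiteCounts:
    """Read-set counts and the r statistic at one (position, direction)."""

    p: int
    direction: ClipDirection
    n_p: int
    n_pm1: int
    n_both: int
    r: float

    def __post_init__(self) -> None:
        if self.n_both > min(self.n_p, self.n_pm1):
            raise ValueError("N_both exceeds min(N_p, N_pm1)")
        if not 0.0 <= self.r <= 1.0:
            raise ValueError(f"r out of range: {self.r}")


@dataclass(frozen=True)
class GapConsensus:
    """Plurality consensus over the clipped tails at one site."""

    sequence: str
    support: int  # number of clip events at the site
    agreement: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.support < 1:
            raise ValueError("consensus with support < 1")
        if any(not (0.0 < a <= 1.0) for a in self.agreement):
            raise ValueError("agreement fraction outside (0, 1]")


@dataclass(frozen=True)
class IndelCall:
    """Resolved variant hypothesis for a clip site (or UNRESOLVED).

    For a DELETION, ``sequence`` is the deleted reference substring; for an
    INSERTION it is the inserted bases, both in genomic (plus-strand) order.
    """

    call_type: CallType
    length: int = 0
    sequence: str = ""
    score: float = 0.0

    @property
    def resolved(self) -> bool:
        return self.call_type is not CallType.UNRESOLVED


@dataclass
class IndelCandidate:
    """A candidate indel aggregating site counts, consensus and call."""

    sample_id: str
    seq_name: str
    site: SiteCounts
    consensus: GapConsensus
    call: IndelCall
    var_pos: int | None
    support: int
    breakpoints: tuple[tuple[int, ClipDirection], ...]
    filters_failed: set[str] = field(default_factory=set)

    @property
    def is_pass(self) -> bool:
        return not self.filters_failed

    @property
    def key_pos(self) -> int:
        """Position used for reporting and cross-sample recurrence."""
        return self.var_pos if self.var_pos is not None else self.site.p

    def affected_interval(self) -> tuple[int, int]:
        """Reference span implicated by the candidate (for known-variant overlap).

        Deletions implicate the deleted span; insertions and unresolved
        candidates implicate the breakpoint and its gap-direction neighbour.
        """
        if self.call.call_type is CallType.DELETION and self.var_pos is not None:
            return self.var_pos, self.var_pos + self.call.length
        if self.call.call_type is CallType.INSERTION and self.var_pos is not None:
            return self.var_pos, self.var_pos + 2
        p = self.site.p
        if self.site.direction is ClipDirection.RIGHT:
            return p, p + 2
        return p - 1, p + 1


@dataclass
class SNVCandidate:
    """A single-base substitution candidate from the pileup caller."""

    sample_id: str
    seq_name: str
    pos: int
    ref_base: str
    alt_base: str
    depth: int
    alt_count: int
    consequence: Consequence = Consequence.UNKNOWN

    def __post_init__(self) -> None:
        if self.alt_base == self.ref_base:
            raise ValueError("alternate equals reference base")

    @property
    def alt_fraction(self) -> float:
        return self.alt_count / self.depth


@dataclass(frozen=True)
class CdsInterval:
    """One CDS interval with strand and frame (GFF-style phase)."""

    seq_name: str
    start: int
    end: int
    strand: str
    frame: int
    gene: str = ""

    def __post_init__(self) -> None:
        if self.frame not in (0, 1, 2):
            raise ValueError(f"frame must be 0/1/2, got {self.frame}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.start < 0 or self.start >= self.end:
            raise ValueError("invalid CDS interval")


@dataclass(frozen=True)
class TruthVariant:
    """A planted variant in the simulator's truth set.

    ``pos`` conventions: SNV = the substituted base; DEL = first deleted
    base; INS = the reference base immediately left of the inserted bases.
    """

    seq_name: str
    pos: int
    kind: str      # "SNV" | "INS" | "DEL"
    length: int
    sequence: str  # alt base / inserted bases / deleted reference bases
    samples: tuple[int, ...]
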