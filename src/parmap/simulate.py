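"""Synthetic exome-capture data generator with planted variants.

Emulates the data shape the pipeline was designed for: a multi-target
reference with flanking sequence, ~50 nt single-end reads at ~40x depth
with ~1% uniform base error across 12 samples, and a mapper that aligns
reads end-gapped so that read tails crossing an indel breakpoint appear
as soft clips of up to 20% of the read length.  No real aligner is run:
each read is placed at its true coordinate and the maximal ungapped
anchor consistent with the reference determines the clip — the pipeline's
contract is about clip patterns, not any specific mapper.

Everything is driven by one seeded generator, so identical configs give
byte-identical FASTA/BED/SAM/truth outputs.
"""
from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io import write_bed, write_fasta, write_sam
from .models import (
    CallType,
    IndelCandidate,
    PartialAlignment,
    ReferenceSet,
    TargetRegion,
    TruthVariant,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_STR = "ACGT"


@dataclass(frozen=True)
class IndelSpec:
    """One planted indel: kind 'INS' or 'DEL', length 1..9, carrier samples."""

    kind: str
    length: int
    samples: tuple[int, ...] = (0,)

    def __post_init__(self) -> None:
        if self.kind not in ("INS", "DEL"):
            raise ValueError(f"indel kind must be INS or DEL, got {self.kind!r}")
        if not 1 <= self.length <= 9:
            raise ValueError("indel length must be 1..9")


@dataclass(frozen=True)
class SnvSpec:
    """One planted substitution; ``alt`` None lets the generator choose."""

    samples: tuple[int, ...] = (0,)
    alt: str | None = None


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 1
    reference_length: int = 100_000
    n_targets: int = 20
    target_length: tuple[int, int] = (250, 350)
    read_length: int = 50
    mean_depth: float = 42.0
    error_rate: float = 0.01
    n_samples: int = 1
    max_clip_fraction: float = 0.2
    indels: tuple[IndelSpec, ...] = ()
    snvs: tuple[SnvSpec, ...] = ()
    flank: int = 50
    variant_margin: int = 15
    seq_name: str = "simref"

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error rate must be in [0, 1)")
        if self.n_samples < 1:
            raise ValueError("need at least one sample")

    def sample_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_samples)]


# haplotype segments: ("M", hap_start, hap_end, ref_start) matched block,
# ("I", hap_start, hap_end, anchor_ref_pos, seq) inserted block
Segment = tuple


@dataclass
class SimulationResult:
    config: SimulationConfig
    reference: ReferenceSet
    targets: list[TargetRegion]
    truth: list[TruthVariant]
    alignments: dict[str, list[PartialAlignment]]
    haplotypes: dict[str, str]
    segments: dict[str, list[Segment]] = field(default_factory=dict)


def simulate_reference(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[ReferenceSet, list[TargetRegion]]:
    """Uniform-random reference with non-overlapping targets, each flanked
    by at least one read length of non-target sequence."""
    L = config.reference_length
    seq = _BASES[rng.integers(0, 4, size=L)].tobytes().decode()
    reference = ReferenceSet({config.seq_name: seq})

    lo, hi = config.target_length
    lengths = rng.integers(lo, hi + 1, size=config.n_targets)
    min_gap = 2 * config.flank
    required = int(lengths.sum()) + min_gap * (config.n_targets + 1)
    free = L - required
    if free < 0:
        raise ValueError(
            f"cannot fit {config.n_targets} targets of {lo}..{hi} nt in {L} nt"
        )
    cuts = np.sort(rng.integers(0, free + 1, size=config.n_targets))
    targets = []
    pos = min_gap
    prev_cut = 0
    for i, length in enumerate(lengths):
        pos += int(cuts[i]) - prev_cut
        prev_cut = int(cuts[i])
        targets.append(TargetRegion(config.seq_name, pos, pos + int(length), f"target{i + 1}"))
        pos += int(length) + min_gap
    return reference, targets


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def plant_variants(
    reference: ReferenceSet,
    targets: Sequence[TargetRegion],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[TruthVariant], dict[str, str], dict[str, list[Segment]]]:
    """Choose isolated loci, build the truth set and per-sample haplotypes.

    Planted variants are kept at least two read lengths apart and away
    from target edges so that recovery scoring is unambiguous and the
    boundary filter cannot touch them.
    """
    seq_name = config.seq_name
    ref_seq = reference[seq_name]
    n_variants = len(config.indels) + len(config.snvs)
    positions: list[int] = []
    min_sep = 2 * config.read_length
    attempts = 0
    while len(positions) < n_variants:
        attempts += 1
        if attempts > 2000 * max(1, n_variants):
            raise ValueError("could not place variants under the isolation constraint")
        t = targets[int(rng.integers(0, len(targets)))]
        lo = t.start + config.variant_margin
        hi = t.end - config.variant_margin - 10
        if hi <= lo:
            continue
        pos = int(rng.integers(lo, hi))
        if all(abs(pos - q) >= min_sep for q in positions):
            positions.append(pos)

    truth: list[TruthVariant] = []
    for spec, pos in zip(config.indels, positions[:len(config.indels)]):
        if spec.kind == "DEL":
            seq = ref_seq[pos:pos + spec.length]
        else:
            seq = _random_seq(rng, spec.length)
        truth.append(TruthVariant(seq_name, pos, spec.kind, spec.length, seq, spec.samples))
    for spec, pos in zip(config.snvs, positions[len(config.indels):]):
        ref_base = ref_seq[pos]
        if spec.alt is not None:
            alt = spec.alt
            if alt == ref_base:
                raise ValueError(f"requested alt equals reference base at {pos}")
        else:
            choices = [b for b in _BASE_STR if b != ref_base]
            alt = choices[int(rng.integers(0, 3))]
        truth.append(TruthVariant(seq_name, pos, "SNV", 1, alt, spec.samples))
    truth.sort(key=lambda v: v.pos)

    haplotypes: dict[str, str] = {}
    segments: dict[str, list[Segment]] = {}
    for i, sample in enumerate(config.sample_ids()):
        hap, segs = build_haplotype(ref_seq, [v for v in truth if i in v.samples])
        haplotypes[sample] = hap
        segments[sample] = segs
    return truth, haplotypes, segments


def build_haplotype(ref_seq: str, variants: Sequence[TruthVariant]) -> tuple[str, list[Segment]]:
    """Apply SNVs then indels (sorted by position) to the reference.

    Returns the haplotype string and its segment map (matched blocks and
    inserted blocks in haplotype coordinates).
    """
    mutated = bytearray(ref_seq.encode())
    for v in variants:
        if v.kind == "SNV":
            mutated[v.pos] = ord(v.sequence)
    parts: list[str] = []
    segs: list[Segment] = []
    h = r = 0
    for v in sorted((v for v in variants if v.kind != "SNV"), key=lambda v: v.pos):
        if v.kind == "DEL":
            block = mutated[r:v.pos].decode()
            if block:
                segs.append(("M", h, h + len(block), r))
                parts.append(block)
                h += len(block)
            r = v.pos + v.length
        else:  # INS anchored after base v.pos
            block = mutated[r:v.pos + 1].decode()
            segs.append(("M", h, h + len(block), r))
            parts.append(block)
            h += len(block)
            r = v.pos + 1
            segs.append(("I", h, h + v.length, v.pos, v.sequence))
            parts.append(v.sequence)
            h += v.length
    tail = mutated[r:].decode()
    if tail:
        segs.append(("M", h, h + len(tail), r))
        parts.append(tail)
    return "".join(parts), segs


def apply_truth_to_reference(ref_seq: str, variants: Sequence[TruthVariant], sample_index: int) -> str:
    """Independent reconstruction of one sample's haplotype (round-trip check)."""
    hap, _ = build_haplotype(ref_seq, [v for v in variants if sample_index in v.samples])
    return hap


def _ref_to_hap(segs: list[Segment], rpos: int) -> int:
    """Haplotype coordinate of a reference position lying in a matched block."""
    for seg in segs:
        if seg[0] != "M":
            continue
        _, h0, h1, r0 = seg
        if r0 <= rpos < r0 + (h1 - h0):
            return h0 + (rpos - r0)
    raise ValueError(f"reference position {rpos} not in a matched block")


@dataclass(frozen=True)
class SimRead:
    read_id: str
    hap_start: int
    strand: str
    seq: str


def sample_reads(
    sample: str,
    haplotype: str,
    segs: list[Segment],
    targets: Sequence[TargetRegion],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[SimRead]:
    """Uniform read starts over each target's padded span, Poisson counts
    at the rate giving the configured mean depth, uniform base errors,
    both strands equiprobable."""
    L = config.read_length
    reads: list[SimRead] = []
    counter = 0
    hap_len = len(haplotype)
    for t in targets:
        span_lo = max(0, t.start - config.flank)
        span_hi = t.end + config.flank
        hs = _ref_to_hap(segs, span_lo)
        he = _ref_to_hap(segs, span_hi - 1) + 1
        he = min(he, hap_len)
        n_starts = he - hs - L + 1
        if n_starts < 1:
            continue
        n = int(rng.poisson(config.mean_depth * n_starts / L))
        starts = rng.integers(hs, hs + n_starts, size=n)
        for h0 in starts:
            h0 = int(h0)
            arr = np.frombuffer(haplotype[h0:h0 + L].encode(), dtype=np.uint8).copy()
            if config.error_rate > 0:
                mask = rng.random(L) < config.error_rate
                n_err = int(mask.sum())
                if n_err:
                    shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
                    lut = np.full(256, 0, dtype=np.uint8)
                    for i, b in enumerate(_BASE_STR):
                        lut[ord(b)] = i
                    idx = (lut[arr[mask]] + shift) % 4
                    arr[mask] = _BASES[idx]
            strand = "-" if rng.random() < 0.5 else "+"
            counter += 1
            reads.append(SimRead(f"{sample}_r{counter:06d}", h0, strand, arr.tobytes().decode()))
    return reads


def _count_mismatches(read_span: str, ref_span: str) -> int:
    return sum(1 for a, b in zip(read_span, ref_span) if a != b)


def emulate_mapping(
    reads: Sequence[SimRead],
    segs: list[Segment],
    reference: ReferenceSet,
    config: SimulationConfig,
) -> list[PartialAlignment]:
    """Deterministic end-gapped placement of reads at their true coordinates.

    A read inside one matched block maps fully.  A read crossing an indel
    junction is anchored on the side keeping the clip shortest; the bases
    beyond the breakpoint become a soft clip.  Reads whose required clip
    would exceed the clip cap are emitted unclipped at their best ungapped
    placement, where the unanchored side simply accumulates mismatches
    (mimicking mapper rejection or absorption).
    """
    seq_name = config.seq_name
    ref_seq = reference[seq_name]
    ref_len = len(ref_seq)
    L = config.read_length
    max_clip = int(config.max_clip_fraction * L)
    h_starts = [seg[1] for seg in segs]
    out: list[PartialAlignment] = []

    for read in reads:
        h0 = read.hap_start
        h1 = h0 + len(read.seq)
        i = bisect_right(h_starts, h0) - 1
        overlapped = []
        j = i
        while j < len(segs) and segs[j][1] < h1:
            overlapped.append(segs[j])
            j += 1

        placement = _place_read(read, overlapped, h0, h1, max_clip)
        if placement is None:
            continue
        ref_start, left_clip, right_clip = placement
        span = len(read.seq) - left_clip - right_clip
        ref_end = ref_start + span
        if ref_start < 0 or ref_end > ref_len:
            continue  # would fall off the reference; drop (vanishingly rare)
        nm = _count_mismatches(
            read.seq[left_clip:len(read.seq) - right_clip],
            ref_seq[ref_start:ref_end],
        )
        out.append(PartialAlignment(
            read_id=read.read_id,
            seq_name=seq_name,
            start=ref_start,
            end=ref_end,
            strand=read.strand,
            read_seq=read.seq,
            left_clip=left_clip,
            right_clip=right_clip,
            nm=nm,
            mapq=60,
            is_unique=True,
        ))
    return out


def _place_read(
    read: SimRead, overlapped: list[Segment], h0: int, h1: int, max_clip: int
) -> tuple[int, int, int] | None:
    """Return (ref_start, left_clip, right_clip) for one read, or None."""
    m_segs = [s for s in overlapped if s[0] == "M"]
    i_segs = [s for s in overlapped if s[0] == "I"]
    if len(overlapped) == 1 and m_segs:
        _, sh0, _, sr0 = m_segs[0]
        return sr0 + (h0 - sh0), 0, 0

    if i_segs:
        if len(i_segs) > 1 or len(m_segs) > 2:
            return None  # reads never span two variants under isolation
        ins = i_segs[0]
        _, ih0, ih1, anchor = ins[0], ins[1], ins[2], ins[3]
        a = max(0, ih0 - h0)           # prefix bases matching reference
        b = max(0, h1 - ih1)           # suffix bases matching reference
        clip_right = len(read.seq) - a  # anchor the prefix
        clip_left = len(read.seq) - b   # anchor the suffix
        options = []
        if a >= 1:
            options.append((clip_right, "R"))
        if b >= 1:
            options.append((clip_left, "L"))
        if not options:
            return None
        clip, side = min(options)
        if clip <= max_clip:
            if side == "R":
                pre = m_segs[0]
                ref_start = pre[3] + (h0 - pre[1])
                return ref_start, 0, clip
            ref_suffix_start = anchor + 1
            return ref_suffix_start, clip, 0
        # unclipped fallback: anchor the longer matched side
        if a >= b:
            pre = m_segs[0]
            return pre[3] + (h0 - pre[1]), 0, 0
        return (anchor + 1) - (len(read.seq) - b), 0, 0

    if len(m_segs) == 2:  # deletion junction
        s1, s2 = m_segs
        a = s1[2] - h0
        b = h1 - s2[1]
        if a <= 0:
            return s2[3] + (h0 - s2[1]), 0, 0
        if b <= 0:
            return s1[3] + (h0 - s1[1]), 0, 0
        if min(a, b) <= max_clip:
            if a >= b:
                return s1[3] + (h0 - s1[1]), 0, b
            return s2[3], a, 0
        if a >= b:
            return s1[3] + (h0 - s1[1]), 0, 0
        return s2[3] - a, 0, 0
    return None


def run_simulation(config: SimulationConfig) -> SimulationResult:
    """End-to-end generation: reference, targets, truth, per-sample alignments."""
    rng = np.random.default_rng(config.seed)
    reference, targets = simulate_reference(config, rng)
    truth, haplotypes, segments = plant_variants(reference, targets, config, rng)
    alignments: dict[str, list[PartialAlignment]] = {}
    for sample in config.sample_ids():
        reads = sample_reads(sample, haplotypes[sample], segments[sample], targets, config, rng)
        alignments[sample] = emulate_mapping(reads, segments[sample], reference, config)
    return SimulationResult(config, reference, targets, truth, alignments, haplotypes, segments)


def write_truth(truth: Sequence[TruthVariant], path: str | Path) -> None:
    lines = ["seq\tpos_0based\ttype\tlength\tsequence\tsamples"]
    for v in truth:
        lines.append(
            f"{v.seq_name}\t{v.pos}\t{v.kind}\t{v.length}\t{v.sequence}\t"
            + ",".join(str(s) for s in v.samples)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_simulation(result: SimulationResult, out_dir: str | Path) -> dict[str, Path]:
    """Write FASTA/BED/SAM/truth/config; returns the paths keyed by role."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["reference"] = out / "reference.fasta"
    write_fasta(result.reference, paths["reference"])
    paths["targets"] = out / "targets.bed"
    write_bed(result.targets, paths["targets"])
    paths["truth"] = out / "truth.tsv"
    write_truth(result.truth, paths["truth"])
    cfg_lines = []
    for f in fields(result.config):
        cfg_lines.append(f"{f.name} = {getattr(result.config, f.name)!r}")
    (out / "config.txt").write_text("\n".join(cfg_lines) + "\n")
    paths["config"] = out / "config.txt"
    for sample, alns in result.alignments.items():
        p = out / f"{sample}.sam"
        write_sam(alns, result.reference, p)
        paths[f"sam:{sample}"] = p
    return paths


# --------------------------------------------------------------------------
# recovery scoring


@dataclass(frozen=True)
class RecoveryRow:
    variant: TruthVariant
    detected: bool
    position_error: int | None
    type_match: bool
    length_match: bool
    sequence_match: bool


@dataclass
class RecoveryReport:
    rows: list[RecoveryRow]
    false_positives: list[IndelCandidate]

    @property
    def n_recovered(self) -> int:
        return sum(1 for r in self.rows if r.detected and r.length_match)

    @property
    def n_detected(self) -> int:
        return sum(1 for r in self.rows if r.detected)


_KIND_TO_CALL = {"DEL": CallType.DELETION, "INS": CallType.INSERTION}


def score_recovery(
    candidates: Iterable[IndelCandidate],
    truth: Sequence[TruthVariant],
    tolerance: int = 2,
    sample_index: int | None = None,
) -> RecoveryReport:
    """Match PASS candidates against the planted indels.

    A truth variant is detected iff a PASS candidate of the same type lies
    within ``tolerance`` positions; sequence match is exact string
    equality.  PASS candidates matching no truth variant are reported as
    false positives.
    """
    passing = [c for c in candidates if c.is_pass and c.call.resolved]
    matched: set[int] = set()
    rows: list[RecoveryRow] = []
    for v in truth:
        if v.kind == "SNV":
            continue
        if sample_index is not None and sample_index not in v.samples:
            continue
        want = _KIND_TO_CALL[v.kind]
        best = None
        for i, c in enumerate(passing):
            if c.seq_name != v.seq_name or c.call.call_type is not want:
                continue
            dist = abs((c.var_pos if c.var_pos is not None else c.site.p) - v.pos)
            if dist <= tolerance and (best is None or dist < best[0]):
                best = (dist, i)
        if best is None:
            rows.append(RecoveryRow(v, False, None, False, False, False))
        else:
            dist, i = best
            matched.add(i)
            c = passing[i]
            rows.append(RecoveryRow(
                v, True, dist, True,
                c.call.length == v.length,
                c.call.sequence == v.sequence,
            ))
    fps = []
    for i, c in enumerate(passing):
        if i in matched:
            continue
        near_truth = any(
            v.kind != "SNV"
            and _KIND_TO_CALL[v.kind] is c.call.call_type
            and c.seq_name == v.seq_name
            and abs((c.var_pos or c.site.p) - v.pos) <= tolerance
            for v in truth
        )
        if not near_truth:
            fps.append(c)
    return RecoveryReport(rows, fps)
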