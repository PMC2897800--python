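"""Readers and writers for the standard formats the pipeline touches.

FASTA via Biopython, SAM and VCF input via pysam; BED and the flat TSV /
minimal VCF outputs are simple enough to handle directly. All coordinates
are converted to 0-based half-open on the way in and back to 1-based on
the way out.
"""
from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Iterator

import pysam
from Bio import SeqIO

from .models import (
    CallType,
    CdsInterval,
    IndelCandidate,
    KnownVariantSet,
    PartialAlignment,
    ReferenceSet,
    SNVCandidate,
    TargetRegion,
)

logger = logging.getLogger("parmap")

_NON_ACGTN = re.compile(r"[^ACGTN]")

# SAM CIGAR operation codes
_OP_M, _OP_I, _OP_D, _OP_S, _OP_H = 0, 1, 2, 4, 5


def read_reference(path: str | Path) -> ReferenceSet:
    """Load a FASTA file; lowercase is uppercased, non-ACGTN becomes N."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate sequence name {record.id!r} in {path}")
        seq = _NON_ACGTN.sub("N", str(record.seq).upper())
        sequences[record.id] = seq
    if not sequences:
        raise ValueError(f"no FASTA records in {path}")
    return ReferenceSet(sequences)


def read_alignments(
    path: str | Path,
    reference: ReferenceSet | None = None,
    unique_mapq: int = 1,
) -> Iterator[PartialAlignment]:
    """Stream primary alignments from a SAM file as PartialAlignment records.

    Soft clips at either end become the clip lengths; secondary,
    supplementary and unmapped records are skipped. NM is taken from the
    tag when present, otherwise recomputed against ``reference`` over the
    aligned span. Records with hard clips or a missing SEQ are skipped
    with a warning (the clipped bases are unavailable).
    """
    with pysam.AlignmentFile(str(path), "r") as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            cigar = rec.cigartuples
            if not cigar:
                continue
            if any(op == _OP_H for op, _ in cigar):
                logger.warning("%s: hard-clipped record skipped (bases unavailable)", rec.query_name)
                continue
            seq = rec.query_sequence
            left = cigar[0][1] if cigar[0][0] == _OP_S else 0
            right = cigar[-1][1] if cigar[-1][0] == _OP_S else 0
            if seq is None:
                if left or right:
                    logger.warning("%s: SEQ '*' with soft clip, record skipped", rec.query_name)
                    continue
                logger.warning("%s: SEQ '*', record skipped", rec.query_name)
                continue
            internal = any(op in (_OP_I, _OP_D) for op, _ in cigar)
            nm = None
            if rec.has_tag("NM"):
                nm = int(rec.get_tag("NM"))
            elif reference is not None and not internal:
                ref_span = reference.fetch(rec.reference_name, rec.reference_start, rec.reference_end)
                read_span = seq[left:len(seq) - right]
                nm = sum(1 for a, b in zip(read_span, ref_span) if a != b)
            if nm is None:
                logger.warning("%s: no NM tag and no reference; NM set to 0", rec.query_name)
                nm = 0
            yield PartialAlignment(
                read_id=rec.query_name,
                seq_name=rec.reference_name,
                start=rec.reference_start,
                end=rec.reference_end,
                strand="-" if rec.is_reverse else "+",
                read_seq=seq.upper(),
                left_clip=left,
                right_clip=right,
                nm=nm,
                mapq=rec.mapping_quality,
                is_unique=rec.mapping_quality >= unique_mapq,
                has_internal_indel=internal,
            )


def read_targets(path: str | Path, reference: ReferenceSet | None = None) -> list[TargetRegion]:
    """Parse a 3+ column BED (0-based half-open) into TargetRegion records."""
    targets: list[TargetRegion] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
        seq, start, end = fields[0], int(fields[1]), int(fields[2])
        label = fields[3] if len(fields) > 3 else ""
        if start >= end:
            raise ValueError(f"{path}:{lineno}: empty/inverted interval {start}..{end}")
        if reference is not None:
            if seq not in reference:
                raise ValueError(f"{path}:{lineno}: unknown sequence {seq!r}")
            if end > reference.length(seq):
                raise ValueError(f"{path}:{lineno}: interval exceeds sequence length")
        targets.append(TargetRegion(seq, start, end, label))
    return targets


def read_known_variants(path: str | Path) -> KnownVariantSet:
    """Load known polymorphic positions from a VCF (.vcf) or BED (.bed).

    VCF records spanning more than one base contribute every covered
    position; all positions are normalized to 0-based.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    positions: set[tuple[str, int]] = set()
    if suffix == ".vcf" or path.name.lower().endswith(".vcf.gz"):
        try:
            with pysam.VariantFile(str(path)) as vcf:
                for rec in vcf:
                    for pos in range(rec.start, rec.stop):
                        positions.add((rec.chrom, pos))
        except ValueError as exc:
            if "empty" in str(exc).lower() or path.stat().st_size == 0:
                return KnownVariantSet()
            raise
    elif suffix == ".bed":
        text = path.read_text()
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            seq, start, end = fields[0], int(fields[1]), int(fields[2])
            for pos in range(start, end):
                positions.add((seq, pos))
    else:
        raise ValueError(f"unsupported known-variant format: {path} (use .vcf or .bed)")
    return KnownVariantSet(positions)


def read_cds(path: str | Path) -> list[CdsInterval]:
    """Parse a 6-column TSV of CDS intervals: seq, start, end, strand, frame, gene."""
    out: list[CdsInterval] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 5:
            raise ValueError(f"{path}:{lineno}: expected >= 5 columns")
        gene = fields[5] if len(fields) > 5 else ""
        out.append(
            CdsInterval(fields[0], int(fields[1]), int(fields[2]), fields[3], int(fields[4]), gene)
        )
    return out


# --------------------------------------------------------------------------
# candidate output

INDEL_COLUMNS = [
    "sample", "seq", "pos_1based", "direction", "N_p", "N_pm1", "N_both", "r",
    "support", "gap_consensus", "call_type", "call_length", "call_sequence",
    "filters_failed",
]

SNV_COLUMNS = [
    "sample", "seq", "pos_1based", "ref", "alt", "depth", "alt_count",
    "alt_fraction", "consequence",
]


def _fmt_float(x: float) -> str:
    return f"{x:.6g}"


def _direction_label(cand: IndelCandidate) -> str:
    dirs = {d for _, d in cand.breakpoints}
    if len(dirs) > 1:
        return "both"
    return next(iter(dirs)).value


def _indel_sort_key(c: IndelCandidate):
    return (c.sample_id, c.seq_name, c.key_pos, _direction_label(c), c.call.call_type.value)


def write_candidates(
    candidates: Iterable[IndelCandidate],
    tsv_path: str | Path,
    vcf_path: str | Path | None = None,
    reference: ReferenceSet | None = None,
    pass_only: bool = False,
) -> None:
    """Write the indel candidate table (TSV) and a minimal VCF-like file.

    Output is sorted and floats are formatted stably, so reruns on
    identical input are byte-identical.
    """
    cands = sorted(candidates, key=_indel_sort_key)
    if pass_only:
        cands = [c for c in cands if c.is_pass]
    lines = ["\t".join(INDEL_COLUMNS)]
    for c in cands:
        lines.append("\t".join([
            c.sample_id,
            c.seq_name,
            str(c.key_pos + 1),
            _direction_label(c),
            str(c.site.n_p),
            str(c.site.n_pm1),
            str(c.site.n_both),
            _fmt_float(c.site.r),
            str(c.support),
            c.consensus.sequence or ".",
            c.call.call_type.value,
            str(c.call.length),
            c.call.sequence or ".",
            ",".join(sorted(c.filters_failed)) if c.filters_failed else "PASS",
        ]))
    Path(tsv_path).write_text("\n".join(lines) + "\n")

    if vcf_path is not None:
        _write_indel_vcf(cands, vcf_path, reference)


def _vcf_header(reference: ReferenceSet | None) -> list[str]:
    lines = ["##fileformat=VCFv4.2", "##source=parmap"]
    if reference is not None:
        for name in reference.names():
            lines.append(f"##contig=<ID={name},length={reference.length(name)}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    return lines


def _write_indel_vcf(
    cands: list[IndelCandidate],
    vcf_path: str | Path,
    reference: ReferenceSet | None,
) -> None:
    lines = _vcf_header(reference)
    for c in cands:
        if not c.call.resolved or c.var_pos is None:
            continue
        filt = "PASS" if c.is_pass else ";".join(sorted(c.filters_failed))
        info = f"TYPE={c.call.call_type.value};LEN={c.call.length};R={_fmt_float(c.site.r)};SUPPORT={c.support}"
        if c.call.call_type is CallType.DELETION:
            # anchor base before the deleted span, VCF style
            anchor = c.var_pos - 1
            if reference is not None and anchor >= 0:
                anchor_base = reference.base(c.seq_name, anchor) or "N"
                ref_allele = anchor_base + c.call.sequence
                alt_allele = anchor_base
            else:
                anchor_base, ref_allele, alt_allele = "N", "N" + c.call.sequence, "N"
            pos_1 = c.var_pos  # anchor position, 1-based == var_pos (0-based) since anchor = var_pos-1
        else:
            anchor = c.var_pos
            anchor_base = (reference.base(c.seq_name, anchor) or "N") if reference is not None else "N"
            ref_allele = anchor_base
            alt_allele = anchor_base + c.call.sequence
            pos_1 = c.var_pos + 1
        lines.append(
            f"{c.seq_name}\t{pos_1}\t.\t{ref_allele}\t{alt_allele}\t.\t{filt}\t{info}"
        )
    Path(vcf_path).write_text("\n".join(lines) + "\n")


def write_snvs(
    snvs: Iterable[SNVCandidate],
    tsv_path: str | Path,
    vcf_path: str | Path | None = None,
    reference: ReferenceSet | None = None,
) -> None:
    """Write the SNV candidate table and a minimal VCF-like file."""
    cands = sorted(snvs, key=lambda c: (c.sample_id, c.seq_name, c.pos, c.alt_base))
    lines = ["\t".join(SNV_COLUMNS)]
    for c in cands:
        lines.append("\t".join([
            c.sample_id, c.seq_name, str(c.pos + 1), c.ref_base, c.alt_base,
            str(c.depth), str(c.alt_count), _fmt_float(c.alt_fraction),
            c.consequence.value,
        ]))
    Path(tsv_path).write_text("\n".join(lines) + "\n")
    if vcf_path is not None:
        vlines = _vcf_header(reference)
        for c in cands:
            info = f"DEPTH={c.depth};ALTC={c.alt_count};SAMPLE={c.sample_id};CSQ={c.consequence.value}"
            vlines.append(f"{c.seq_name}\t{c.pos + 1}\t.\t{c.ref_base}\t{c.alt_base}\t.\tPASS\t{info}")
        Path(vcf_path).write_text("\n".join(vlines) + "\n")


def read_candidate_table(path: str | Path) -> list[dict[str, str]]:
    """Re-read a candidate TSV as a list of dicts keyed by column name."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        return []
    header = lines[0].split("\t")
    return [dict(zip(header, line.split("\t"))) for line in lines[1:]]


def write_sam(
    alignments: Iterable[PartialAlignment],
    reference: ReferenceSet,
    path: str | Path,
) -> None:
    """Write PartialAlignment records as a coordinate-sorted SAM file."""
    names = reference.names()
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": reference.length(n)} for n in names],
    })
    tid = {n: i for i, n in enumerate(names)}
    recs = sorted(alignments, key=lambda a: (tid[a.seq_name], a.start, a.read_id))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for a in recs:
            seg = pysam.AlignedSegment(header)
            seg.query_name = a.read_id
            seg.flag = 16 if a.strand == "-" else 0
            seg.reference_id = tid[a.seq_name]
            seg.reference_start = a.start
            seg.mapping_quality = a.mapq
            cigar = []
            if a.left_clip:
                cigar.append((_OP_S, a.left_clip))
            cigar.append((_OP_M, a.aligned_span))
            if a.right_clip:
                cigar.append((_OP_S, a.right_clip))
            seg.cigartuples = cigar
            seg.query_sequence = a.read_seq
            seg.query_qualities = None
            seg.set_tag("NM", a.nm, "i")
            out.write(seg)


def write_fasta(reference: ReferenceSet, path: str | Path, width: int = 60) -> None:
    """Write a ReferenceSet as wrapped FASTA (deterministic byte output)."""
    lines: list[str] = []
    for name in reference.names():
        lines.append(f">{name}")
        seq = reference[name]
        for i in range(0, len(seq), width):
            lines.append(seq[i:i + width])
    Path(path).write_text("\n".join(lines) + "\n")


def write_bed(targets: Iterable[TargetRegion], path: str | Path) -> None:
    lines = [f"{t.seq_name}\t{t.start}\t{t.end}\t{t.label}" for t in targets]
    Path(path).write_text("\n".join(lines) + "\n")
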