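"""Tunable parameters for read admission and indel evidence evaluation.

A flat ``key = value`` config file can override any field; CLI flags
override both (defaults < file < flags).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any


@dataclass(frozen=True)
class MappingParams:
    """Read-admission filters applied before any evidence is collected.

    unique_mapq: minimum MAPQ for an alignment to count as unique (together
        with the primary flag).
    max_mismatches: maximum NM over the aligned span.
    max_clip_fraction: maximum soft-clipped fraction of the read length.
    count_mapper_indels: include reads whose CIGAR already contains internal
        I/D operators in clip-site evidence (default: excluded — their indel
        is the mapper's call).
    """

    unique_mapq: int = 1
    max_mismatches: int = 2
    max_clip_fraction: float = 0.2
    count_mapper_indels: bool = False


@dataclass(frozen=True)
class CoreParams:
    """Consensus and classification knobs.

    consensus_agreement: minimum plurality fraction for a consensus base.
    min_consensus_support: minimum number of tails still extending for the
        consensus to continue (kept independent of the candidate support
        threshold: tails thin out linearly toward the clip cap, so demanding
        deep support at every offset would truncate most consensi below the
        classifiable length; the default keeps single-tail extensions, whose
        occasional errors the realignment identity threshold absorbs).
    classify_identity: minimum per-base identity of the winning hypothesis.
    min_classify_span: minimum number of compared bases for a hypothesis.
    min_classify_length: minimum consensus length to attempt classification.
    max_indel_length: largest indel size considered (< 10 nt by design).
    merge_tolerance: maximum distance between variant positions inferred
        from opposite-direction clip sites for them to be merged.
    mismatch_penalty: per-mismatch penalty in the realignment score
        (score = matches - penalty * mismatches).
    """

    consensus_agreement: float = 0.5
    min_consensus_support: int = 1
    classify_identity: float = 0.9
    min_classify_span: int = 4
    min_classify_length: int = 4
    max_indel_length: int = 9
    merge_tolerance: int = 9
    mismatch_penalty: float = 2.0


def load_flat_config(path: str | Path) -> dict[str, str]:
    """Parse a flat ``key = value`` file; '#' starts a comment."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def _coerce(value: str, typ: Any) -> Any:
    if typ is bool or typ == "bool":
        return value.lower() in ("1", "true", "yes", "on")
    if typ is int or typ == "int":
        return int(value)
    if typ is float or typ == "float":
        return float(value)
    return value


def update_params(params: Any, overrides: dict[str, Any]) -> Any:
    """Return a copy of a frozen params dataclass with matching keys replaced.

    Keys may use '-' or '_'; string values are coerced to the field type.
    Unknown keys are ignored so one flat file can feed several dataclasses.
    """
    fields = {f.name: f for f in dataclasses.fields(params)}
    changes = {}
    for key, value in overrides.items():
        name = key.replace("-", "_")
        if name not in fields or value is None:
            continue
        if isinstance(value, str):
            value = _coerce(value, fields[name].type)
        changes[name] = value
    return dataclasses.replace(params, **changes) if changes else params
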