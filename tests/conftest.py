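from __future__ import annotations

import numpy as np
import pytest

from parmap.models import ClipDirection, PartialAlignment, ReferenceSet
from parmap.simulate import IndelSpec, SimulationConfig, run_simulation


def make_aln(
    start: int,
    end: int,
    left: int = 0,
    right: int = 0,
    seq_name: str = "t",
    read_id: str | None = None,
    read_seq: str | None = None,
    **kwargs,
) -> PartialAlignment:
    """Build a PartialAlignment with a consistent read length."""
    if read_seq is None:
        read_seq = "A" * (left + (end - start) + right)
    if read_id is None:
        make_aln._n += 1
        read_id = f"read{make_aln._n}"
    kwargs.setdefault("mapq", 60)
    return PartialAlignment(
        read_id=read_id,
        seq_name=seq_name,
        start=start,
        end=end,
        strand="+",
        read_seq=read_seq,
        left_clip=left,
        right_clip=right,
        **kwargs,
    )


make_aln._n = 0


def jaccard_oracle(alignments, seq_name: str, p: int, direction: ClipDirection) -> float:
    """Independent brute force: materialize both read sets, take |∩|/|∪|."""
    neighbour = p + (1 if direction is ClipDirection.RIGHT else -1)
    set_p = {i for i, a in enumerate(alignments)
             if a.seq_name == seq_name and a.covers(p)}
    set_n = {i for i, a in enumerate(alignments)
             if a.seq_name == seq_name and a.covers(neighbour)}
    union = set_p | set_n
    if not union:
        return 1.0
    return len(set_p & set_n) / len(union)


def random_pileup(rng: np.random.Generator, seq_len: int = 60, n_reads: int | None = None):
    """Random aligned spans over a short sequence for oracle comparisons."""
    if n_reads is None:
        n_reads = int(rng.integers(0, 40))
    alns = []
    for _ in range(n_reads):
        start = int(rng.integers(0, seq_len - 1))
        end = int(rng.integers(start + 1, min(seq_len, start + 20) + 1))
        alns.append(make_aln(start, end))
    return alns


@pytest.fixture
def toy_reference() -> ReferenceSet:
    rng = np.random.default_rng(42)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=400))
    return ReferenceSet({"t": seq})


ERRORFREE_SPECS = (
    IndelSpec("DEL", 3),
    IndelSpec("DEL", 6),
    IndelSpec("INS", 5),
    IndelSpec("INS", 3),
)


@pytest.fixture(scope="session")
def errorfree_sim():
    """One sample, 100 kb, 20 targets, depth 40, no errors, the four
    planted indels (3/6 nt deletions, 5/3 nt insertions)."""
    config = SimulationConfig(
        seed=7, n_samples=1, error_rate=0.0, mean_depth=40.0, indels=ERRORFREE_SPECS,
    )
    return run_simulation(config)
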