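"""Target coverage summaries (breadth and mean depth)."""
from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .models import PartialAlignment, ReferenceSet, TargetRegion


def coverage_stats(
    alignments: Iterable[PartialAlignment],
    targets: Sequence[TargetRegion],
    reference: ReferenceSet,
) -> tuple[float, float]:
    """(breadth, mean depth) over target bases.

    Breadth = fraction of target bases covered by at least one aligned
    span; depth is averaged over all target bases, zeros included.
    Clipped bases do not cover.
    """
    if not targets:
        return 0.0, 0.0
    diff: dict[str, np.ndarray] = {}
    for name in reference.names():
        diff[name] = np.zeros(reference.length(name) + 1, dtype=np.int64)
    for a in alignments:
        diff[a.seq_name][a.start] += 1
        diff[a.seq_name][a.end] -= 1
    depth = {name: np.cumsum(d[:-1]) for name, d in diff.items()}
    total = covered = 0
    depth_sum = 0
    for t in targets:
        d = depth[t.seq_name][t.start:t.end]
        total += len(d)
        covered += int(np.count_nonzero(d))
        depth_sum += int(d.sum())
    return covered / total, depth_sum / total
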