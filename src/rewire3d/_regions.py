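"""Small interval helpers shared across pipeline stages.

Intervals are 0-based half-open ``(start, end)`` tuples in bp (or bins where
stated). Overlap queries go through :mod:`intervaltree`.
"""

from __future__ import annotations

import numpy as np
from intervaltree import IntervalTree


def merge_intervals(intervals, gap: int = 0):
    """Merge overlapping (and, for ``gap >= 0``, within-``gap``/abutting)
    sorted or unsorted intervals into a disjoint sorted list."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1] + gap:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def build_tree(intervals) -> IntervalTree:
    t = IntervalTree()
    for s, e in intervals:
        if e > s:
            t.addi(int(s), int(e))
    return t


def overlaps_any(queries, reference) -> np.ndarray:
    """Boolean array: does each query interval overlap (>=1 bp) any reference?"""
    tree = build_tree(reference)
    return np.array([bool(tree.overlap(int(s), int(e))) for s, e in queries])


def overlap_lengths(query, intervals) -> np.ndarray:
    """bp overlap of one query ``(s, e)`` with each interval in a list."""
    s, e = query
    out = np.zeros(len(intervals), dtype=int)
    for k, (a, b) in enumerate(intervals):
        out[k] = max(0, min(e, b) - max(s, a))
    return out
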