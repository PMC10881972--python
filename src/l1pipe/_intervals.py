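"""Interval arithmetic shared by the read filters and fragment counters.

Coordinates are 0-based half-open throughout. The central object is
:class:`GenomeIntervals`, a per-contig merged interval set supporting
vectorized "how many bases of [a, b) are covered" queries via prefix sums.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["merge_intervals", "GenomeIntervals"]


def merge_intervals(starts, ends) -> tuple[np.ndarray, np.ndarray]:
    """Merge possibly overlapping intervals into sorted disjoint ones."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="mergesort")
    s, e = starts[order], ends[order]
    out_s, out_e = [s[0]], [e[0]]
    for i in range(1, len(s)):
        if s[i] <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e[i])
        else:
            out_s.append(s[i])
            out_e.append(e[i])
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


class GenomeIntervals:
    """Merged interval set keyed by contig with O(log n) coverage queries."""

    def __init__(self, df: pd.DataFrame, start_col: str = "start", end_col: str = "end"):
        self._by_contig: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        if len(df):
            for contig, sub in df.groupby("contig", sort=False):
                s, e = merge_intervals(sub[start_col].to_numpy(), sub[end_col].to_numpy())
                lengths = e - s
                # prefix[i] = covered bases in intervals 0..i-1
                prefix = np.concatenate([[0], np.cumsum(lengths)])
                self._by_contig[str(contig)] = (s, e, prefix)

    def _covered_upto(self, contig: str, x: np.ndarray) -> np.ndarray:
        """Covered bases in (-inf, x) per query point."""
        entry = self._by_contig.get(contig)
        if entry is None:
            return np.zeros(len(x), dtype=np.int64)
        s, e, prefix = entry
        j = np.searchsorted(e, x, side="right")  # intervals fully left of x
        full = prefix[j]
        partial = np.zeros_like(full)
        inside = j < len(s)
        js = np.clip(j, 0, len(s) - 1)
        partial = np.where(inside, np.clip(x - s[js], 0, e[js] - s[js]), 0)
        return full + partial

    def overlap_bases(self, contig: str, starts, ends) -> np.ndarray:
        """Vectorized covered length of each query interval [start, end)."""
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        return self._covered_upto(contig, ends) - self._covered_upto(contig, starts)

    def overlap_bases_blocks(self, contig: str, blocks) -> int:
        """Covered length of a list of (start, end) blocks (one read)."""
        total = 0
        for s, e in blocks:
            total += int(self.overlap_bases(contig, [s], [e])[0])
        return total
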