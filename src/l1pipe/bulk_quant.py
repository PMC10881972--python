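"""Active-locus calling from paired-end bulk RNA-seq.

Transcriptionally active L1 loci are called from strand-aware fragment
counts on the 1-kb flanking windows: a locus is "expressed" when its
downstream window holds at least five times as many fragments as its
upstream window. Proper-pair mates are split by SAM flag (67 = read1 in a
proper pair, 131 = read2); under the default ``read1_sense`` protocol a
flag-67 read marks a forward-strand fragment and a flag-131 read a
reverse-strand fragment. Fragments, not mate reads, are counted: a
fragment contributes at most once per window.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._intervals import GenomeIntervals
from .sc_quant import FilterConfig, _table_overlap_frac, _window_trees

__all__ = ["FragmentCount", "split_mates", "count_window_fragments",
           "call_expressed", "run_bulk"]

FLAG_READ1_PROPER = 67
FLAG_READ2_PROPER = 131

PROTOCOLS = {
    "read1_sense": {FLAG_READ1_PROPER: "+", FLAG_READ2_PROPER: "-"},
    "read2_sense": {FLAG_READ1_PROPER: "-", FLAG_READ2_PROPER: "+"},
}


@dataclass
class FragmentCount:
    locus_id: str
    n_down: int
    n_up: int
    sample_id: str = ""


def split_mates(reads: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Partition records into flag-67 and flag-131 sets; tally the rest."""
    flags = reads["flag"].to_numpy()
    fwd = reads.loc[flags == FLAG_READ1_PROPER]
    rev = reads.loc[flags == FLAG_READ2_PROPER]
    ignored = int(len(reads) - len(fwd) - len(rev))
    return fwd, rev, ignored


def prefilter_bulk(reads: pd.DataFrame, exons: pd.DataFrame,
                   repeats: pd.DataFrame, exon_any_overlap: bool = True,
                   repeat_frac: float = 0.90) -> pd.DataFrame:
    """Bulk read filter: drop exon-touching reads and >=90%-repeat reads.

    The exon rule is any-overlap by default (stricter than the single-cell
    1% rule); set ``exon_any_overlap=False`` to use the 1% threshold.
    """
    if len(reads) == 0:
        return reads
    ef = _table_overlap_frac(reads, GenomeIntervals(exons))
    rf = _table_overlap_frac(reads, GenomeIntervals(repeats))
    exon_ok = (ef == 0.0) if exon_any_overlap else (ef < FilterConfig().exon_frac)
    return reads.loc[exon_ok & (rf < repeat_frac)]


def count_window_fragments(mates: pd.DataFrame, windows: pd.DataFrame,
                           protocol: str = "read1_sense",
                           min_overlap_bp: int = 1) -> pd.DataFrame:
    """Count fragments per window, strand-aware under the named protocol.

    ``mates`` holds flag-67/131 records (other flags are ignored here); the
    fragment strand is inferred from the mate identity and must equal the
    window strand. Deduplication is by query name per window.
    """
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}; "
                         f"choose from {sorted(PROTOCOLS)}")
    strand_of = PROTOCOLS[protocol]
    trees = _window_trees(windows)
    seen: dict[tuple, set] = {}
    flags = mates["flag"].to_numpy()
    contigs = mates["contig"].to_numpy()
    starts = mates["start"].to_numpy()
    ends = mates["end"].to_numpy()
    qnames = mates["qname"].to_numpy()
    for i in range(len(mates)):
        frag_strand = strand_of.get(int(flags[i]))
        if frag_strand is None:
            continue
        tree = trees.get(str(contigs[i]))
        if tree is None:
            continue
        for iv in tree.overlap(starts[i], ends[i]):
            locus_id, layer, wstrand = iv.data
            if wstrand != frag_strand:
                continue
            if min(ends[i], iv.end) - max(starts[i], iv.begin) < min_overlap_bp:
                continue
            seen.setdefault((locus_id, layer), set()).add(qnames[i])
    rows = []
    for locus_id in dict.fromkeys(windows["locus_id"]):
        n_down = len(seen.get((locus_id, "downstream"), ()))
        n_up = len(seen.get((locus_id, "upstream"), ()))
        rows.append((locus_id, n_down, n_up))
    return pd.DataFrame(rows, columns=["locus_id", "n_down", "n_up"])


def call_expressed(counts: pd.DataFrame, ratio: float = 5.0) -> pd.DataFrame:
    """Expressed iff n_down >= ratio * max(n_up, 1).

    The floor at 1 keeps the rule defined when no upstream fragments exist
    and prevents single-fragment false positives (n_down must reach
    ``ratio`` even at n_up = 0).
    """
    out = counts.copy()
    out["expressed"] = out["n_down"] >= ratio * np.maximum(out["n_up"], 1)
    return out


def run_bulk(reads: pd.DataFrame, windows: pd.DataFrame, exons: pd.DataFrame,
             repeats: pd.DataFrame, protocol: str = "read1_sense",
             ratio: float = 5.0) -> pd.DataFrame:
    """Full bulk path: prefilter, split mates, count fragments, call loci."""
    filtered = prefilter_bulk(reads, exons, repeats)
    fwd, rev, _ignored = split_mates(filtered)
    mates = pd.concat([fwd, rev], ignore_index=True)
    counts = count_window_fragments(mates, windows, protocol=protocol)
    return call_expressed(counts, ratio=ratio)
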