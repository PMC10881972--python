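"""Windowed UMI counting of L1 read-through in 3' single-cell RNA-seq.

Converts barcoded alignments into per-cell deduplicated UMI counts on the
1-kb downstream and upstream windows of each catalogued full-length L1,
after a four-rule read filter:

1. exon overlap (reads mapping >= 1% of their aligned bases to exons are
   excluded — gene-derived transcripts);
2. repeat overlap (>= 90% to repeats excluded — ambiguous repetitive
   alignments);
3. window overlap (>= 60% of aligned bases inside a window required);
4. poly-A artifact (A fraction >= 60% or T fraction >= 60% excluded —
   mispriming on the element's polyadenine stretch).

Only uniquely aligned reads on the same strand as the window are counted;
a read meeting the 60% rule for two different windows is discarded as
ambiguous. All overlap fractions are fractions of the read's aligned bases.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from intervaltree import IntervalTree

from ._intervals import GenomeIntervals

__all__ = [
    "FilterConfig",
    "AlignedRead",
    "FilterReport",
    "UmiCountMatrix",
    "build_windows",
    "overlap_fraction",
    "filter_reads",
    "dedup_count",
    "count_genes",
]


@dataclass
class FilterConfig:
    exon_frac: float = 0.01
    repeat_frac: float = 0.90
    window_frac: float = 0.60
    at_frac: float = 0.60
    max_mismatches: int = 2
    at_mode: str = "either"  # 'either': A>=t or T>=t; 'combined': A+T>=t

    def validate(self) -> None:
        for name in ("exon_frac", "repeat_frac", "window_frac", "at_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if self.at_mode not in ("either", "combined"):
            raise ValueError(f"unknown at_mode {self.at_mode!r}")


@dataclass
class AlignedRead:
    """A single alignment record with explicit aligned blocks."""

    barcode: str
    umi: int | str
    contig: str
    blocks: list  # sorted, non-overlapping (start, end)
    strand: str
    frac_a: float = 0.0
    frac_t: float = 0.0
    n_alignments: int = 1
    n_mismatches: int = 0

    @property
    def aligned_bases(self) -> int:
        return sum(e - s for s, e in self.blocks)


@dataclass
class FilterReport:
    """Reads removed per rule, recorded in application order."""

    n_input: int = 0
    removed: dict = field(default_factory=dict)
    n_kept: int = 0
    flagged_windows: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {"n_input": self.n_input, "removed": dict(self.removed),
                "n_kept": self.n_kept, "flagged_windows": list(self.flagged_windows)}


class UmiCountMatrix:
    """Features x cell-barcodes deduplicated UMI counts for one layer."""

    def __init__(self, X: sp.spmatrix, features: list[str], barcodes: list[str],
                 layer: str):
        self.X = sp.csr_matrix(X, dtype=np.int64)
        self.features = list(features)
        self.barcodes = list(barcodes)
        self.layer = layer
        if self.X.shape != (len(self.features), len(self.barcodes)):
            raise ValueError("matrix shape does not match feature/barcode lists")
        if len(self.X.data) and self.X.data.min() < 0:
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_long(cls, df: pd.DataFrame, features, barcodes, layer: str,
                  feature_col: str = "feature", count_col: str = "count"):
        fi = {f: i for i, f in enumerate(features)}
        bi = {b: i for i, b in enumerate(barcodes)}
        if len(df):
            rows = df[feature_col].map(fi).to_numpy()
            cols = df["barcode"].map(bi).to_numpy()
            X = sp.coo_matrix((df[count_col].to_numpy(), (rows, cols)),
                              shape=(len(fi), len(bi)))
        else:
            X = sp.coo_matrix((len(fi), len(bi)), dtype=np.int64)
        return cls(X.tocsr(), list(features), list(barcodes), layer)

    def to_df(self) -> pd.DataFrame:
        return pd.DataFrame(self.X.toarray(), index=self.features,
                            columns=self.barcodes)

    def total_per_feature(self) -> pd.Series:
        return pd.Series(np.asarray(self.X.sum(axis=1)).ravel(),
                         index=self.features, name="total")

    def total_per_cell(self) -> pd.Series:
        return pd.Series(np.asarray(self.X.sum(axis=0)).ravel(),
                         index=self.barcodes, name="total")

    def save_mtx(self, prefix: str) -> None:
        import scipy.io as sio
        sio.mmwrite(f"{prefix}.mtx", self.X.tocoo())
        pd.Series(self.features).to_csv(f"{prefix}.features.tsv", sep="\t",
                                        header=False, index=False)
        pd.Series(self.barcodes).to_csv(f"{prefix}.barcodes.tsv", sep="\t",
                                        header=False, index=False)

    @classmethod
    def load_mtx(cls, prefix: str, layer: str):
        import scipy.io as sio
        X = sp.csr_matrix(sio.mmread(f"{prefix}.mtx"))
        features = pd.read_csv(f"{prefix}.features.tsv", sep="\t",
                               header=None)[0].tolist()
        barcodes = pd.read_csv(f"{prefix}.barcodes.tsv", sep="\t",
                               header=None)[0].tolist()
        return cls(X, features, barcodes, layer)


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

def build_windows(catalog: pd.DataFrame, window_bp: int = 1000,
                  contig_lengths: dict | None = None) -> pd.DataFrame:
    """1-kb windows flanking each locus, strand-aware, clipped at contig edges.

    Returns a long table with one row per (locus, layer): the ``downstream``
    window sits 3' of the locus relative to its strand, ``upstream`` 5'.
    """
    rows = []
    for L in catalog.itertuples(index=False):
        if contig_lengths is not None and L.contig not in contig_lengths:
            raise KeyError(f"unknown contig {L.contig!r}")
        clen = contig_lengths.get(L.contig) if contig_lengths else None
        left = (L.start - window_bp, L.start)
        right = (L.end, L.end + window_bp)
        down, up = (right, left) if L.strand == "+" else (left, right)
        for layer, (ws, we) in (("downstream", down), ("upstream", up)):
            cs, ce = max(0, ws), we if clen is None else min(we, clen)
            rows.append((L.locus_id, L.contig, int(cs), int(ce), L.strand, layer,
                         (ce - cs) != window_bp))
    return pd.DataFrame(rows, columns=["locus_id", "contig", "start", "end",
                                       "strand", "layer", "clipped"])


def overlap_fraction(read: AlignedRead, intervals: GenomeIntervals) -> float:
    """Fraction of the read's aligned bases covered by the interval set."""
    total = read.aligned_bases
    if total == 0:
        raise ValueError("read has no aligned blocks")
    cov = intervals.overlap_bases_blocks(read.contig, read.blocks)
    return cov / total


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def _table_overlap_frac(reads: pd.DataFrame, intervals: GenomeIntervals) -> np.ndarray:
    """Vectorized per-read overlap fraction; honours multi-block rows."""
    frac = np.zeros(len(reads))
    has_blocks = "blocks" in reads.columns
    for contig, idx in reads.groupby("contig", sort=False,
                                     observed=True).indices.items():
        sub = reads.iloc[idx]
        cov = intervals.overlap_bases(str(contig), sub["start"].to_numpy(),
                                      sub["end"].to_numpy()).astype(float)
        lengths = (sub["end"] - sub["start"]).to_numpy(dtype=float)
        if has_blocks:
            bl = sub["blocks"]
            multi = bl.notna().to_numpy()
            for j in np.flatnonzero(multi):
                blocks = bl.iloc[j]
                cov[j] = intervals.overlap_bases_blocks(str(contig), blocks)
                lengths[j] = sum(e - s for s, e in blocks)
        frac[idx] = cov / lengths
    return frac


def _window_trees(windows: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for contig, sub in windows.groupby("contig", sort=False):
        t = IntervalTree()
        for w in sub.itertuples(index=False):
            if w.end > w.start:
                t.addi(w.start, w.end, (w.locus_id, w.layer, w.strand))
        trees[str(contig)] = t
    return trees


def filter_reads(reads: pd.DataFrame, exons: pd.DataFrame, repeats: pd.DataFrame,
                 windows: pd.DataFrame, cfg: FilterConfig | None = None
                 ) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the four read filters plus uniqueness/strand/ambiguity rules.

    Each rule is a pure per-read predicate, so the kept set is independent of
    application order; the report tallies removals in the order exon, repeat,
    window, poly-A, multimapper, mismatches, strand, ambiguous.

    Returns the kept reads with ``locus_id`` and ``layer`` assignment columns.
    """
    cfg = cfg or FilterConfig()
    cfg.validate()
    report = FilterReport(n_input=len(reads))
    order = ["exon", "repeat", "window", "polyA", "multimap", "mismatch",
             "strand", "ambiguous"]
    report.removed = {k: 0 for k in order}
    if len(reads) == 0:
        report.n_kept = 0
        kept = reads.copy()
        kept["locus_id"] = pd.Series(dtype=str)
        kept["layer"] = pd.Series(dtype=str)
        return kept, report

    exon_ix = GenomeIntervals(exons)
    repeat_ix = GenomeIntervals(repeats)
    window_ix = GenomeIntervals(windows)

    exon_frac = _table_overlap_frac(reads, exon_ix)
    repeat_frac = _table_overlap_frac(reads, repeat_ix)
    window_cov = _table_overlap_frac(reads, window_ix)

    pass_exon = exon_frac < cfg.exon_frac
    pass_repeat = repeat_frac < cfg.repeat_frac
    if cfg.at_mode == "either":
        is_polya = (reads["frac_a"].to_numpy() >= cfg.at_frac) | \
                   (reads["frac_t"].to_numpy() >= cfg.at_frac)
    else:
        is_polya = (reads["frac_a"] + reads["frac_t"]).to_numpy() >= cfg.at_frac
    pass_unique = reads["n_alignments"].to_numpy() == 1
    pass_mm = reads["n_mismatches"].to_numpy() <= cfg.max_mismatches

    # exact window assignment for reads with any window coverage
    trees = _window_trees(windows)
    n = len(reads)
    best_locus = np.full(n, "", dtype=object)
    best_layer = np.full(n, "", dtype=object)
    pass_window = np.zeros(n, dtype=bool)   # >=60% with some window, any strand
    pass_strand = np.zeros(n, dtype=bool)   # the qualifying window matches strand
    ambiguous = np.zeros(n, dtype=bool)
    has_blocks = "blocks" in reads.columns
    cand_idx = np.flatnonzero(window_cov > 0)
    contigs_arr = reads["contig"].to_numpy()
    starts = reads["start"].to_numpy()
    ends = reads["end"].to_numpy()
    strands = reads["strand"].to_numpy()
    blocks_col = reads["blocks"].to_numpy() if has_blocks else None
    for i in cand_idx:
        tree = trees.get(contigs_arr[i])
        if tree is None:
            continue
        blocks = None
        if blocks_col is not None and blocks_col[i] is not None and \
                not (isinstance(blocks_col[i], float) and np.isnan(blocks_col[i])):
            blocks = list(blocks_col[i])
        if blocks is None:
            blocks = [(starts[i], ends[i])]
        total = sum(e - s for s, e in blocks)
        hits = {}
        for s, e in blocks:
            for iv in tree.overlap(s, e):
                key = iv.data
                ov = sum(min(e2, iv.end) - max(s2, iv.begin)
                         for s2, e2 in blocks
                         if min(e2, iv.end) > max(s2, iv.begin))
                hits[key] = ov
        qual = [(k, v) for k, v in hits.items() if v / total >= cfg.window_frac]
        if not qual:
            continue
        pass_window[i] = True
        same = [k for k, _ in qual if k[2] == strands[i]]
        if not same:
            continue
        pass_strand[i] = True
        loci = {k[0] for k in same}
        if len(loci) > 1:
            ambiguous[i] = True
            continue
        # a read can touch both layers of one locus only if windows abut;
        # take the layer with the larger overlap
        best = max(((k, v) for k, v in qual if k[2] == strands[i]),
                   key=lambda kv: kv[1])
        best_locus[i] = best[0][0]
        best_layer[i] = best[0][1]

    keep = (pass_exon & pass_repeat & pass_window & ~is_polya & pass_unique &
            pass_mm & pass_strand & ~ambiguous)

    # removals tallied in application order over surviving reads
    alive = np.ones(n, dtype=bool)
    for name, pred in (("exon", pass_exon), ("repeat", pass_repeat),
                       ("window", pass_window), ("polyA", ~is_polya),
                       ("multimap", pass_unique), ("mismatch", pass_mm),
                       ("strand", pass_strand), ("ambiguous", ~ambiguous)):
        removed = alive & ~pred
        report.removed[name] = int(removed.sum())
        alive &= pred
    report.n_kept = int(keep.sum())

    # windows overlapping another catalogued repeat are flagged, not dropped
    wcov = window_ix  # noqa: F841  (windows themselves excluded from repeat set)
    for w in windows.itertuples(index=False):
        ov = repeat_ix.overlap_bases(w.contig, [w.start], [w.end])[0]
        if ov > 0:
            report.flagged_windows.append((w.locus_id, w.layer))

    kept = reads.loc[keep].copy()
    kept["locus_id"] = best_locus[keep]
    kept["layer"] = best_layer[keep]
    return kept, report


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

def dedup_count(kept: pd.DataFrame, windows: pd.DataFrame, cells: pd.DataFrame
                ) -> tuple[dict[str, UmiCountMatrix], int]:
    """Collapse (barcode, UMI, locus, layer) to one count each.

    Reads whose barcode is absent from the cell table are dropped; the number
    dropped is returned alongside the ``downstream``/``upstream`` matrices.
    Features cover every catalog locus (zero rows retained).
    """
    barcodes = cells["barcode"].tolist()
    features = list(dict.fromkeys(windows["locus_id"]))
    known = kept["barcode"].isin(set(barcodes))
    n_dropped = int((~known).sum())
    kept = kept.loc[known]
    out = {}
    for layer in ("downstream", "upstream"):
        sub = kept.loc[kept["layer"] == layer]
        uniq = sub.drop_duplicates(["barcode", "umi", "locus_id"])
        counts = (uniq.groupby(["locus_id", "barcode"], sort=False, observed=True)
                  .size().rename("count").reset_index())
        out[layer] = UmiCountMatrix.from_long(
            counts, features, barcodes, layer, feature_col="locus_id")
    return out, n_dropped


def count_genes(reads: pd.DataFrame, genes: pd.DataFrame, cells: pd.DataFrame
                ) -> UmiCountMatrix:
    """Assign unfiltered reads to genes (unique, same strand), dedup, count.

    A read is assigned when it overlaps exactly one gene on its own strand
    and aligns uniquely (NH = 1); reads overlapping two same-strand genes are
    ambiguous and dropped. Assumes gene bodies on one strand do not overlap
    each other (true of the synthetic annotation; violations raise).
    """
    barcodes = cells["barcode"].tolist()
    features = genes["gene_id"].tolist()
    n = len(reads)
    assign = np.full(n, "", dtype=object)
    for (contig, strand), gsub in genes.groupby(["contig", "strand"], sort=False):
        gsub = gsub.sort_values("start")
        gs = gsub["start"].to_numpy()
        ge = gsub["end"].to_numpy()
        if len(gs) > 1 and (gs[1:] < ge[:-1]).any():
            raise ValueError("overlapping same-strand genes are not supported")
        gid = gsub["gene_id"].to_numpy()
        m = ((reads["contig"] == contig) & (reads["strand"] == strand)).to_numpy()
        if not m.any():
            continue
        rs = reads["start"].to_numpy()[m]
        re_ = reads["end"].to_numpy()[m]
        i = np.searchsorted(gs, rs, side="right") - 1
        hit_a = (i >= 0) & (rs < ge[np.clip(i, 0, len(ge) - 1)])
        j = i + 1
        hit_b = (j < len(gs)) & (re_ > gs[np.clip(j, 0, len(gs) - 1)])
        n_hits = hit_a.astype(int) + hit_b.astype(int)
        chosen = np.where(hit_a, np.clip(i, 0, len(gid) - 1),
                          np.clip(j, 0, len(gid) - 1))
        ok = n_hits == 1
        local = np.full(m.sum(), "", dtype=object)
        local[ok] = gid[chosen[ok]]
        assign[m] = local
    unique = reads["n_alignments"].to_numpy() == 1
    assigned = (assign != "") & unique
    sub = reads.loc[assigned, ["barcode", "umi"]].copy()
    sub["gene_id"] = assign[assigned]
    sub = sub[sub["barcode"].isin(set(barcodes))]
    uniq = sub.drop_duplicates(["barcode", "umi", "gene_id"])
    counts = (uniq.groupby(["gene_id", "barcode"], sort=False, observed=True)
              .size().rename("count").reset_index())
    return UmiCountMatrix.from_long(counts, features, barcodes, "gene",
                                    feature_col="gene_id")
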