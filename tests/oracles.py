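"""Independent brute-force oracles used to validate the pipeline.

Everything here works per base / per set-element with no interval
arithmetic, no searchsorted tricks and no statsmodels — deliberately naive
so it cannot share bugs with the implementation under test.
"""
from __future__ import annotations

import itertools

import numpy as np


def positions(blocks) -> set[int]:
    out = set()
    for s, e in blocks:
        out.update(range(int(s), int(e)))
    return out


def brute_overlap_fraction(blocks, intervals) -> float:
    """Per-base overlap fraction of read blocks with a list of intervals."""
    read = positions(blocks)
    cover = positions(intervals)
    return len(read & cover) / len(read)


def brute_filter_and_assign(reads, exons, repeats, windows, cfg):
    """Re-implement the read filter with per-base sets.

    ``reads`` is the tabular read format; annotation frames hold
    contig/start/end(/strand, locus_id, layer). Returns dict read_id ->
    (locus_id, layer) for kept reads.
    """
    ex_by = {}
    for r in exons.itertuples(index=False):
        ex_by.setdefault(r.contig, set()).update(range(r.start, r.end))
    rep_by = {}
    for r in repeats.itertuples(index=False):
        rep_by.setdefault(r.contig, set()).update(range(r.start, r.end))
    win_list = [(w, set(range(w.start, w.end)))
                for w in windows.itertuples(index=False)]

    kept = {}
    for r in reads.itertuples(index=False):
        blocks = getattr(r, "blocks", None)
        if blocks is None or (isinstance(blocks, float) and np.isnan(blocks)):
            blocks = [(r.start, r.end)]
        pos = positions(blocks)
        n = len(pos)
        if len(ex_by.get(r.contig, set()) & pos) / n >= cfg.exon_frac:
            continue
        if len(rep_by.get(r.contig, set()) & pos) / n >= cfg.repeat_frac:
            continue
        if cfg.at_mode == "either":
            if r.frac_a >= cfg.at_frac or r.frac_t >= cfg.at_frac:
                continue
        else:
            if r.frac_a + r.frac_t >= cfg.at_frac:
                continue
        if r.n_alignments != 1 or r.n_mismatches > cfg.max_mismatches:
            continue
        hits = []
        for w, wpos in win_list:
            if w.contig != r.contig:
                continue
            ov = len(pos & wpos)
            if ov / n >= cfg.window_frac:
                hits.append((w.locus_id, w.layer, w.strand, ov))
        if not hits:
            continue
        same = [h for h in hits if h[2] == r.strand]
        if not same:
            continue
        if len({h[0] for h in same}) > 1:
            continue
        best = max(same, key=lambda h: h[3])
        kept[r.read_id] = (best[0], best[1])
    return kept


def brute_umi_counts(assigned, layer):
    """Set-cardinality dedup: {(barcode, umi)} per (locus, barcode).

    ``assigned`` is an iterable of (barcode, umi, locus_id, layer) tuples.
    """
    triples = {(b, u, l) for b, u, l, lay in assigned if lay == layer}
    counts = {}
    for b, u, l in triples:
        counts[(l, b)] = counts.get((l, b), 0) + 1
    return counts


def brute_gene_counts(reads, genes):
    """Per-base unique same-strand gene assignment then set dedup."""
    triples = set()
    gene_list = list(genes.itertuples(index=False))
    for r in reads.itertuples(index=False):
        if r.n_alignments != 1:
            continue
        pos = positions([(r.start, r.end)])
        hits = [g.gene_id for g in gene_list
                if g.contig == r.contig and g.strand == r.strand
                and pos & set(range(g.start, g.end))]
        if len(hits) == 1:
            triples.add((r.barcode, r.umi, hits[0]))
    counts = {}
    for b, u, g in triples:
        counts[(g, b)] = counts.get((g, b), 0) + 1
    return counts


def brute_bulk_counts(mates, windows, strand_of_flag):
    """Per-base strand-aware fragment counting, dedup by query name."""
    seen = {}
    win_list = [(w, set(range(w.start, w.end)))
                for w in windows.itertuples(index=False)]
    for r in mates.itertuples(index=False):
        fs = strand_of_flag.get(r.flag)
        if fs is None:
            continue
        pos = positions([(r.start, r.end)])
        for w, wpos in win_list:
            if w.contig != r.contig or w.strand != fs:
                continue
            if pos & wpos:
                seen.setdefault((w.locus_id, w.layer), set()).add(r.qname)
    return {k: len(v) for k, v in seen.items()}


def brute_auc(expr_ranks_desc, set_members, k):
    """Recovery-curve integration: walk ranks 1..k, accumulate set hits.

    ``expr_ranks_desc`` is the list of gene names ordered best-first.
    """
    m = len([g for g in set_members if g in expr_ranks_desc])
    hits = 0
    area = 0
    for r in range(1, k + 1):
        if expr_ranks_desc[r - 1] in set_members:
            hits += 1
        area += hits
    denom = sum(min(r, m) for r in range(1, k + 1)) if m else 1
    return area / denom if m else 0.0


def wilcoxon_exact_two_sided(d) -> float:
    """Exact signed-rank two-sided p by enumerating all 2^n sign patterns."""
    d = np.asarray([x for x in d if x != 0], dtype=float)
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    # mid-ranks for ties
    absd = np.abs(d)
    for v in np.unique(absd):
        m = absd == v
        ranks[m] = ranks[m].mean()
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.array(ws)
    p_le = np.mean(ws <= w_obs)
    p_ge = np.mean(ws >= w_obs)
    return min(1.0, 2.0 * min(p_le, p_ge))


def bh_closed_form(p):
    """q_(i) = min_{j >= i} p_(j) * n / j, mapped back to input order."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(n)
    running = np.inf
    for i in range(n - 1, -1, -1):
        running = min(running, p[order[i]] * n / (i + 1))
        q_sorted[i] = min(1.0, running)
    q = np.empty(n)
    q[order] = q_sorted
    return q


def pearson_closed_form(x, y):
    """r from the definitional formula; p from the t transform."""
    from scipy.stats import t as tdist

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    xc, yc = x - x.mean(), y - y.mean()
    r = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
    tt = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * tdist.sf(abs(tt), n - 2)
    return r, p
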