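"""Locus-level evaluation of single-cell L1 expression.

Normalizes UMI counts, restricts the analysis universe to the most highly
expressed loci, labels tumor/normal and cell-type enrichment by threefold
rules on per-sample per-cell-type means, tests L1-host-gene association two
ways (sample-level Pearson correlation and single-cell logistic regression
on median-matched cells), and selects candidate autonomously active loci:
tumor-sample-high loci with no positive host association.

Rationale: reads in an L1 downstream window may come from the element's own
promoter or from transcription of a host gene whose intron contains the
element. A locus whose window signal tracks its host is likely ingenuine,
so host-associated loci are excluded from the candidate set.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, logit_lrt
from .sc_quant import UmiCountMatrix

__all__ = [
    "normalize",
    "combined_cell_totals",
    "top_fraction_filter",
    "GroupMeans",
    "group_means",
    "fold_change_labels",
    "host_correlation",
    "median_match_subsample",
    "host_logistic",
    "host_association_logistic",
    "select_candidates",
]


def combined_cell_totals(matrices: list[UmiCountMatrix]) -> pd.Series:
    """Per-cell total UMIs summed over the given layers (gene + L1 windows)."""
    total = None
    for m in matrices:
        t = m.total_per_cell()
        total = t if total is None else total.add(t, fill_value=0)
    return total.astype(np.int64)


def normalize(counts: UmiCountMatrix, cell_totals: pd.Series,
              scale: float = 10_000.0) -> pd.DataFrame:
    """ln(1 + scale * count / cell_total), the standard log-normalization.

    ``cell_totals`` is the cell-level size factor over the combined gene+L1
    matrix. Cells with zero total are dropped with a warning. Zeros map to
    zero and within-cell ranks are preserved.
    """
    totals = cell_totals.reindex(counts.barcodes).fillna(0)
    zero = totals.index[totals.to_numpy() == 0]
    if len(zero):
        warnings.warn(f"dropping {len(zero)} cells with zero total UMIs")
    keep = totals.to_numpy() > 0
    X = counts.X.toarray()[:, keep].astype(float)
    X = np.log1p(scale * X / totals.to_numpy()[keep])
    return pd.DataFrame(X, index=counts.features,
                        columns=[b for b, k in zip(counts.barcodes, keep) if k])


def top_fraction_filter(totals: pd.Series, fraction: float = 0.05
                        ) -> tuple[list[str], int]:
    """Top-``fraction`` of detected loci by total UMI count.

    Detected means total >= 1. The cutoff is the ceil(fraction * n_detected)-th
    largest total; ties at the cutoff are all retained. Returns the retained
    locus list (descending by total) and the realized minimum total.
    """
    detected = totals[totals >= 1].sort_values(ascending=False, kind="mergesort")
    if len(detected) == 0:
        return [], 0
    k = int(np.ceil(fraction * len(detected)))
    k = max(1, min(k, len(detected)))
    cutoff = detected.iloc[k - 1]
    kept = detected[detected >= cutoff]
    return kept.index.tolist(), int(kept.min())


@dataclass
class GroupMeans:
    """Mean normalized expression per (sample, cell type), plus group sizes."""

    means: pd.DataFrame  # features x MultiIndex(sample_id, cell_type)
    n_cells: pd.Series  # per (sample_id, cell_type)


def group_means(norm: pd.DataFrame, cells: pd.DataFrame) -> GroupMeans:
    """Arithmetic mean (zeros included) over each sample's cells of each type.

    Empty (sample, cell type) combinations simply do not appear as columns;
    they are never imputed as zero.
    """
    meta = cells.set_index("barcode")[["sample_id", "cell_type"]]
    meta = meta.reindex(norm.columns)
    if meta.isna().any().any():
        missing = meta.index[meta.isna().any(axis=1)][:5].tolist()
        raise ValueError(f"cells without sample/cell-type labels: {missing}...")
    key = pd.MultiIndex.from_frame(meta)
    means = norm.T.groupby(key).mean().T
    n = meta.groupby(["sample_id", "cell_type"]).size()
    means.columns = pd.MultiIndex.from_tuples(means.columns,
                                              names=["sample_id", "cell_type"])
    return GroupMeans(means, n)


def _sample_means(gm: GroupMeans) -> pd.DataFrame:
    """Per-sample mean of that sample's cell-type means (features x samples)."""
    return gm.means.T.groupby(level="sample_id").mean().T


def fold_change_labels(gm: GroupMeans, cells: pd.DataFrame, fold: float = 3.0,
                       eps: float = 1e-9, cancer_type: str = "cancer",
                       zero_denominator_high: bool = False) -> pd.DataFrame:
    """Threefold enrichment labels per locus.

    ``tumor_high``: mean over tumor-sample means >= fold x mean over
    normal-sample means (denominator floored at ``eps``); ``normal_high``
    symmetric. ``celltype_high``: within tumor samples, a cell type whose
    mean is >= fold x the mean of every other cell type. A ratio with zero
    denominator and positive numerator is flagged (``*_only`` columns) and
    only labelled high when ``zero_denominator_high`` is set.
    """
    groups = cells.drop_duplicates("sample_id").set_index("sample_id")["group_class"]
    sm = _sample_means(gm)
    tumor_samples = [s for s in sm.columns if groups.get(s) == "tumor"]
    normal_samples = [s for s in sm.columns if groups.get(s) == "normal"]
    if not normal_samples:
        raise ValueError("no normal samples: enrichment labels undefined")
    t_mean = sm[tumor_samples].mean(axis=1)
    n_mean = sm[normal_samples].mean(axis=1)

    rel = 1.0 - 1e-9  # "at least fold" is inclusive up to rounding

    def _high(num, den):
        ratio = num / np.maximum(den, eps)
        zero_den = (den <= 0) & (num > 0)
        high = (ratio >= fold * rel) & (num > 0)
        if not zero_denominator_high:
            high &= ~zero_den
        return high, ratio, zero_den

    tumor_high, fold_tn, tumor_only = _high(t_mean, n_mean)
    normal_high, fold_nt, normal_only = _high(n_mean, t_mean)

    # cell-type enrichment within tumor samples
    tm = gm.means.loc[:, gm.means.columns.get_level_values("sample_id").isin(tumor_samples)]
    ct_means = tm.T.groupby(level="cell_type").mean().T
    celltype_high = pd.Series("", index=gm.means.index, dtype=object)
    fold_ct = pd.Series(np.nan, index=gm.means.index)
    for ct in ct_means.columns:
        others = [c for c in ct_means.columns if c != ct]
        if not others:
            continue
        ok = np.ones(len(ct_means), dtype=bool)
        worst = np.full(len(ct_means), np.inf)
        for o in others:
            r = ct_means[ct] / np.maximum(ct_means[o], eps)
            zero_den = (ct_means[o] <= 0) & (ct_means[ct] > 0)
            this_ok = (r >= fold * rel) & (ct_means[ct] > 0)
            if not zero_denominator_high:
                this_ok &= ~zero_den
            ok &= this_ok.to_numpy()
            worst = np.minimum(worst, r.to_numpy())
        celltype_high[ok] = ct
        fold_ct[ok] = worst[ok]

    out = pd.DataFrame({
        "tumor_high": tumor_high, "normal_high": normal_high,
        "tumor_only": tumor_only, "normal_only": normal_only,
        "fold_tumor_normal": fold_tn, "fold_normal_tumor": fold_nt,
        "celltype_high": celltype_high, "fold_celltype": fold_ct,
    })
    out.index.name = "locus_id"
    assert not (out["tumor_high"] & out["normal_high"]).any()
    return out


def host_correlation(l1_means: pd.DataFrame, gene_means: pd.DataFrame,
                     pairs: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between each L1 and its host over group means.

    Both inputs are features x (sample, cell type) mean matrices; ``pairs``
    maps ``locus_id`` to ``host_gene_id``. Pairs with fewer than three
    common groups or a constant vector are flagged and excluded from the
    BH family.
    """
    cols = l1_means.columns.intersection(gene_means.columns)
    rows = []
    for p in pairs.itertuples(index=False):
        r = pv = np.nan
        flag = ""
        if p.locus_id not in l1_means.index or p.host_gene_id not in gene_means.index:
            flag = "missing"
        else:
            x = l1_means.loc[p.locus_id, cols].to_numpy(dtype=float)
            y = gene_means.loc[p.host_gene_id, cols].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(y))
            x, y = x[ok], y[ok]
            if len(x) < 3:
                flag = "insufficient"
            elif np.ptp(x) == 0 or np.ptp(y) == 0:
                flag = "constant"
            else:
                res = stats.pearsonr(x, y)
                r, pv = float(res.statistic), float(res.pvalue)
        rows.append((p.locus_id, p.host_gene_id,
                     bool(getattr(p, "host_same_strand", False)), r, pv, flag))
    out = pd.DataFrame(rows, columns=["locus_id", "host_gene_id", "same_strand",
                                      "pearson_r", "p_corr", "flag"])
    out["q_corr"] = bh_adjust(out["p_corr"])
    out["positive_significant"] = (out["pearson_r"] > 0) & (out["q_corr"] < 0.05)
    return out


def median_match_subsample(l1_pos_totals: pd.Series, l1_neg_totals: pd.Series,
                           seed: int = 0, max_neg: int | None = None) -> pd.Index:
    """Median-matched subsample of L1-negative cells by total UMI count.

    Negatives are sorted by total; the anchor is the negative whose total is
    closest to the positives' median, and ``m`` cells are taken from each
    side of the anchor, m = min(cells below, cells above) (capped at
    ``max_neg`` per side). This removes the cell-size bias that makes large
    cells more likely to be L1-positive.
    """
    if len(l1_pos_totals) == 0 or len(l1_neg_totals) == 0:
        raise ValueError("both positive and negative sets must be non-empty")
    med = float(np.median(l1_pos_totals.to_numpy()))
    neg = l1_neg_totals.sort_values(kind="mergesort")
    dist = np.abs(neg.to_numpy(dtype=float) - med)
    anchor = int(np.argmin(dist))  # first closest on ties: deterministic
    m = min(anchor, len(neg) - anchor - 1)
    if max_neg is not None:
        m = min(m, max_neg)
    if m == 0 and len(neg) > 1:
        raise ValueError("all negative cells lie on one side of the anchor; "
                         "median matching impossible")
    return neg.index[anchor - m: anchor + m + 1]


def host_logistic(l1_flags: np.ndarray, host_expr: np.ndarray,
                  sample_ids: np.ndarray) -> tuple[float, float, str]:
    """One logistic model: L1-positive ~ host expression + sample indicators.

    Returns (coefficient, LRT p, flag); complete separation is flagged with
    an undefined (NaN) p, never 0.
    """
    dummies = pd.get_dummies(pd.Series(sample_ids), drop_first=True, dtype=float)
    return logit_lrt(l1_flags, host_expr, dummies)


def host_association_logistic(counts_down: UmiCountMatrix,
                              gene_norm: pd.DataFrame, cells: pd.DataFrame,
                              pairs: pd.DataFrame, cell_totals: pd.Series,
                              min_cells: int = 5, seed: int = 0) -> pd.DataFrame:
    """Per (locus, cell type) host-association logistic regression.

    Cells of each type are split into L1+ (>= 1 downstream UMI) and L1-,
    the negatives median-matched on total UMIs, and the model fitted on the
    union. BH-FDR is applied across all fitted models.
    """
    raw = counts_down.to_df()
    rows = []
    barcodes = [b for b in gene_norm.columns]
    meta = cells.set_index("barcode").loc[barcodes]
    for p in pairs.itertuples(index=False):
        if p.locus_id not in raw.index or p.host_gene_id not in gene_norm.index:
            continue
        flags_all = (raw.loc[p.locus_id].reindex(barcodes).fillna(0) >= 1)
        for ct, ct_bcs in meta.groupby("cell_type").groups.items():
            ct_bcs = pd.Index(ct_bcs)
            pos = ct_bcs[flags_all[ct_bcs]]
            neg = ct_bcs[~flags_all[ct_bcs]]
            if len(pos) < min_cells or len(neg) < min_cells:
                rows.append((p.locus_id, p.host_gene_id, ct, np.nan, np.nan,
                             "insufficient"))
                continue
            try:
                matched = median_match_subsample(cell_totals[pos],
                                                 cell_totals[neg], seed=seed)
            except ValueError:
                rows.append((p.locus_id, p.host_gene_id, ct, np.nan, np.nan,
                             "unmatchable"))
                continue
            use = pos.append(matched)
            coef, pv, flag = host_logistic(
                flags_all[use].to_numpy(float),
                gene_norm.loc[p.host_gene_id, use].to_numpy(float),
                meta.loc[use, "sample_id"].to_numpy())
            rows.append((p.locus_id, p.host_gene_id, ct, coef, pv, flag))
    out = pd.DataFrame(rows, columns=["locus_id", "host_gene_id", "cell_type",
                                      "logit_coef", "p_logit", "flag"])
    out["q_logit"] = bh_adjust(out["p_logit"])
    out["positive_significant"] = (out["logit_coef"] > 0) & (out["q_logit"] < 0.05)
    return out


def select_candidates(labels: pd.DataFrame, corr: pd.DataFrame,
                      logit: pd.DataFrame) -> list[str]:
    """Tumor-sample-high loci without positive host association in either test.

    Intergenic loci (absent from the association tables) pass the
    association condition trivially. The returned list is ordered as in
    ``labels``.
    """
    assoc_pos = set(corr.loc[corr["positive_significant"], "locus_id"])
    assoc_pos |= set(logit.loc[logit["positive_significant"], "locus_id"])
    return [lid for lid in labels.index
            if labels.loc[lid, "tumor_high"] and lid not in assoc_pos]
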