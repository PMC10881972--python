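"""Pre- vs post-chemotherapy comparison of L1 expression in cancer cells.

Three views of the same question, all restricted to cancer cells of paired
patient samples: (1) per-locus Pearson correlation of mean expression
between the pre and post sample of each patient (high correlation = stable
patient-specific expression); (2) a paired Wilcoxon signed-rank test on
sample means for a systematic shift; (3) a single-cell logistic model of
phase membership on per-cell normalized locus expression with patient
indicators absorbing inter-patient differences.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, logit_lrt

__all__ = ["paired_sample_table", "paired_correlation", "paired_wilcoxon",
           "chemo_logistic", "run_chemo"]


def paired_sample_table(norm: pd.DataFrame, cells: pd.DataFrame, loci: list[str],
                        cancer_type: str = "cancer") -> pd.DataFrame:
    """Per-locus mean normalized expression in cancer cells, pre and post.

    Returns a long table: patient_id, phase ('pre'/'post'), one column per
    locus. Every patient must contribute exactly one pre and one post
    sample.
    """
    meta = cells.set_index("barcode")
    meta = meta.loc[meta.index.intersection(norm.columns)]
    mask = (meta["cell_type"] == cancer_type) & meta["group"].isin(
        ["tumor_pre", "tumor_post"])
    meta = meta.loc[mask]
    rows = []
    for (patient, group), bcs in meta.groupby(["patient_id", "group"]).groups.items():
        phase = "pre" if group == "tumor_pre" else "post"
        means = norm.loc[loci, list(bcs)].mean(axis=1)
        rows.append([patient, phase] + means.tolist())
    table = pd.DataFrame(rows, columns=["patient_id", "phase"] + list(loci))
    counts = table.groupby("patient_id")["phase"].nunique()
    if (counts != 2).any():
        bad = counts.index[counts != 2].tolist()
        raise ValueError(f"patients without a complete pre/post pair: {bad}")
    return table.sort_values(["patient_id", "phase"],
                             ascending=[True, False]).reset_index(drop=True)


def _pre_post(table: pd.DataFrame, locus: str) -> tuple[np.ndarray, np.ndarray]:
    wide = table.pivot(index="patient_id", columns="phase", values=locus)
    return wide["pre"].to_numpy(float), wide["post"].to_numpy(float)


def paired_correlation(table: pd.DataFrame, loci: list[str]) -> pd.DataFrame:
    """Pearson r between pre and post means per locus; BH over the panel."""
    rows = []
    for locus in loci:
        pre, post = _pre_post(table, locus)
        ok = ~(np.isnan(pre) | np.isnan(post))
        pre, post = pre[ok], post[ok]
        r = pv = np.nan
        flag = ""
        if len(pre) < 3:
            flag = "insufficient"
        elif np.ptp(pre) == 0 or np.ptp(post) == 0:
            flag = "constant"
        else:
            res = stats.pearsonr(pre, post)
            r, pv = float(res.statistic), float(res.pvalue)
        rows.append((locus, r, pv, flag))
    out = pd.DataFrame(rows, columns=["locus_id", "pearson_r", "p", "flag"])
    out["q"] = bh_adjust(out["p"])
    return out


def paired_wilcoxon(table: pd.DataFrame, loci: list[str]) -> pd.DataFrame:
    """Two-sided Wilcoxon signed-rank test on paired sample means.

    Zero differences are dropped (Wilcoxon convention); the exact null
    distribution is used for small samples (scipy's default). All-zero
    differences leave p undefined, flagged.
    """
    rows = []
    for locus in loci:
        pre, post = _pre_post(table, locus)
        ok = ~(np.isnan(pre) | np.isnan(post))
        d = post[ok] - pre[ok]
        d = d[d != 0]
        pv = np.nan
        flag = ""
        if len(d) == 0:
            flag = "all_zero"
        elif len(d) < 2:
            flag = "insufficient"
        else:
            pv = float(stats.wilcoxon(d, alternative="two-sided",
                                      method="exact" if len(d) <= 25 else "auto").pvalue)
        rows.append((locus, pv, len(d), flag))
    return pd.DataFrame(rows, columns=["locus_id", "wilcoxon_p", "n_informative",
                                       "flag"])


def chemo_logistic(norm: pd.DataFrame, cells: pd.DataFrame, loci: list[str],
                   cancer_type: str = "cancer") -> pd.DataFrame:
    """Phase ~ per-cell locus expression + patient indicators, LRT per locus."""
    meta = cells.set_index("barcode")
    meta = meta.loc[meta.index.intersection(norm.columns)]
    meta = meta.loc[(meta["cell_type"] == cancer_type) &
                    meta["group"].isin(["tumor_pre", "tumor_post"])]
    y = (meta["group"] == "tumor_post").to_numpy(float)
    dummies = pd.get_dummies(meta["patient_id"], drop_first=True, dtype=float)
    rows = []
    for locus in loci:
        x = norm.loc[locus, meta.index].to_numpy(float)
        coef, pv, flag = logit_lrt(y, x, dummies)
        rows.append((locus, coef, pv, flag))
    return pd.DataFrame(rows, columns=["locus_id", "logit_coef", "logit_p", "flag"])


def run_chemo(norm: pd.DataFrame, cells: pd.DataFrame, loci: list[str],
              cancer_type: str = "cancer") -> pd.DataFrame:
    """All three pre/post analyses, merged into one per-locus table."""
    table = paired_sample_table(norm, cells, loci, cancer_type=cancer_type)
    corr = paired_correlation(table, loci)
    wil = paired_wilcoxon(table, loci)
    logit = chemo_logistic(norm, cells, loci, cancer_type=cancer_type)
    out = corr.merge(wil[["locus_id", "wilcoxon_p", "n_informative"]],
                     on="locus_id")
    out = out.merge(logit[["locus_id", "logit_coef", "logit_p"]], on="locus_id")
    out["wilcoxon_q"] = bh_adjust(out["wilcoxon_p"])
    out["logit_q"] = bh_adjust(out["logit_p"])
    return out
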