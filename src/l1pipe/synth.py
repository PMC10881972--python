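"""Synthetic-data generator with known ground truth.

Emulates the data-generating structure that the LINE-1 (L1) read-through
quantification pipeline assumes for 3' single-cell RNA-seq and paired-end
bulk RNA-seq:

* a catalog of full-length L1 loci, a fraction of them intronic within
  "host" genes whose transcription can spill into the L1 1-kb downstream
  window and thereby mimic autonomous L1 expression;
* autonomous L1 transcription read-through of at most ~1 kb past the
  element's weak polyadenylation site, captured as 3'-biased reads inside
  the downstream window;
* poly-A mispriming artifact reads (>=60% A or T base composition);
* per-cell UMI-budget variation (lognormal), PCR duplicates, a tumor/normal
  cohort of paired pre/post-chemotherapy samples plus healthy controls,
  and cancer/epithelial, fibroblast and immune cell types.

Every locus carries a truth class so downstream detection can be scored:

``autonomous_tumor``
    transcribes from its own promoter, predominantly in tumor cancer cells.
``autonomous_ubiquitous``
    transcribes in all samples and cell types.
``host_driven_decoy``
    silent itself; its window signal is entirely host-gene spill-over.
``polyA_decoy``
    silent; its window reads are A/T-rich mispriming artifacts.
``silent``
    background noise only.

Reads are emitted directly as alignment records (no sequence-level
aligner); the mismatch count is a stored field. UMIs are stored as integer
codes internally and expanded to 10-mers when SAM is written.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "SimConfig",
    "Annotation",
    "TruthLabels",
    "generate_annotation",
    "simulate_cells",
    "simulate_reads_sc",
    "simulate_reads_bulk",
    "write_sam_sc",
    "read_sam_sc",
    "write_sam_bulk",
    "write_bed",
    "encode_umi",
    "decode_umi",
]

LOCUS_CLASSES = (
    "autonomous_tumor",
    "autonomous_ubiquitous",
    "host_driven_decoy",
    "polyA_decoy",
    "silent",
)

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """All knobs of the generator; defaults define the study conditions."""

    seed: int = 0
    # genome geometry
    n_contigs: int = 2
    contig_length_bp: int = 2_500_000
    n_loci: int = 200
    locus_length: int = 6000
    window_bp: int = 1000
    frac_intragenic: float = 0.485
    class_counts: dict = field(
        default_factory=lambda: {
            "autonomous_tumor": 20,
            "host_driven_decoy": 40,
            "polyA_decoy": 10,
        }
    )
    splice_decoys: bool = False
    # cohort
    n_tumor_pairs: int = 11
    n_normal_samples: int = 5
    cells_per_sample: int = 300
    celltype_proportions: dict = field(
        default_factory=lambda: {"cancer": 0.5, "fibroblast": 0.25, "immune": 0.25}
    )
    umi_budget_logmean: float = 5.0
    umi_budget_logsd: float = 0.4
    # gene expression programme
    n_background_genes: int = 30
    gene_expr_rates: dict | None = None  # gene_id -> weight override
    decoy_host_weight: float = 3.0
    decoy_tumor_bias: float = 20.0
    background_weight: float = 2.0
    # L1 biology
    l1_activity: dict | None = None  # class -> {(group_class, cell_type): rate}
    readthrough_decay_bp: float = 400.0
    host_spanning_rate: float = 0.02
    polyA_artifact_rate: float = 0.05
    polyA_locus_rate: float = 0.05
    # library artefacts
    pcr_duplicate_rate: float = 0.15
    multi_align_rate: float = 0.02
    read_length: int = 98
    umi_length: int = 10
    barcode_length: int = 16
    # bulk
    bulk_down_autonomous: float = 30.0
    bulk_up_autonomous: float = 3.0
    bulk_decoy_rate: float = 15.0
    bulk_background_rate: float = 0.3
    bulk_fragment_length: int = 250
    bulk_noise_pairs: int = 200

    def validate(self) -> None:
        fracs = {
            "frac_intragenic": self.frac_intragenic,
            "host_spanning_rate": self.host_spanning_rate,
            "polyA_artifact_rate": self.polyA_artifact_rate,
            "pcr_duplicate_rate": self.pcr_duplicate_rate,
            "multi_align_rate": self.multi_align_rate,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        total = sum(self.celltype_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"celltype_proportions must sum to 1, got {total}")
        for k in self.class_counts:
            if k not in LOCUS_CLASSES:
                raise ValueError(f"unknown locus class {k!r}")
        if sum(self.class_counts.values()) > self.n_loci:
            raise ValueError("class_counts exceed n_loci")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        if d["l1_activity"] is not None:
            d["l1_activity"] = {
                cls: {f"{g}|{t}": r for (g, t), r in m.items()}
                for cls, m in d["l1_activity"].items()
            }
        return json.dumps(d, indent=2, sort_keys=True)

    def activity_map(self) -> dict:
        """Per-class autonomous rates (UMI per average-size cell)."""
        if self.l1_activity is not None:
            return self.l1_activity
        return {
            "autonomous_tumor": {
                ("tumor", "cancer"): 0.09,
                ("normal", "epithelial"): 0.008,
            },
            "autonomous_ubiquitous": {("*", "*"): 0.05},
        }

    @property
    def mean_budget(self) -> float:
        return float(np.exp(self.umi_budget_logmean + self.umi_budget_logsd**2 / 2))


@dataclass
class Annotation:
    """BED-compatible annotation tables produced by :func:`generate_annotation`."""

    catalog: pd.DataFrame  # contig,start,end,locus_id,score,strand + flag columns
    genes: pd.DataFrame  # contig,start,end,gene_id,score,strand
    exons: pd.DataFrame
    repeats: pd.DataFrame
    gene_weights: pd.DataFrame  # gene_id, weight_tumor, weight_normal
    locus_classes: pd.DataFrame  # locus_id, truth_class, intragenic, host cols
    contig_lengths: dict


@dataclass
class TruthLabels:
    """Ground truth: one class per locus, per-cell autonomous-expression flags."""

    locus_classes: pd.DataFrame
    cell_flags: pd.DataFrame  # columns: barcode, locus_id (autonomous UMIs >= 1)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def generate_annotation(config: SimConfig) -> Annotation:
    """Lay out L1 loci, host/background genes, exons and repeats.

    Loci are placed on fixed-width slots (one locus per slot) so that 1-kb
    windows never collide; `host_driven_decoy` loci are always intronic with
    a same-strand host, other loci are intronic with a probability chosen so
    the overall intragenic fraction matches ``frac_intragenic``.
    """
    config.validate()
    contig_lengths = {
        f"chr{i + 1}": config.contig_length_bp for i in range(config.n_contigs)
    }
    empty = lambda cols: pd.DataFrame(columns=cols)  # noqa: E731
    bedcols = ["contig", "start", "end"]
    if config.n_loci == 0:
        cat = empty(bedcols + ["locus_id", "score", "strand", "polyA_extended",
                               "retro_competent", "orf2_intact", "host_gene_id",
                               "host_same_strand"])
        return Annotation(cat, empty(bedcols + ["gene_id", "score", "strand"]),
                          empty(bedcols + ["gene_id", "score", "strand"]),
                          empty(bedcols + ["name", "score", "strand"]),
                          empty(["gene_id", "weight_tumor", "weight_normal"]),
                          empty(["locus_id", "truth_class", "intragenic",
                                 "host_gene_id", "host_same_strand", "decoy_bias"]),
                          contig_lengths)

    rng = np.random.default_rng(config.seed)
    contigs = list(contig_lengths)
    # distribute loci round-robin over contigs
    per_contig = [config.n_loci // config.n_contigs] * config.n_contigs
    for i in range(config.n_loci % config.n_contigs):
        per_contig[i] += 1
    for n_i in per_contig:
        if n_i and config.contig_length_bp // n_i < 20_000:
            raise ValueError(
                "contig too short: need contig_length_bp >= 20 kb per locus "
                f"({n_i} loci on a {config.contig_length_bp} bp contig)"
            )

    # truth classes, shuffled over locus indices
    classes = []
    for cls, n in config.class_counts.items():
        classes += [cls] * n
    classes += ["silent"] * (config.n_loci - len(classes))
    classes = np.array(classes)[rng.permutation(config.n_loci)]

    # host-driven decoys are always intronic (same-strand host); autonomous
    # loci are always intergenic so their truth class is unambiguous — a
    # host-contaminated autonomous locus would rightly be rejected by the
    # host-association rule, which no single truth label could express.
    n_decoy = int(np.sum(classes == "host_driven_decoy"))
    n_auto = int(np.sum(np.char.startswith(classes.astype(str), "autonomous")))
    n_other = config.n_loci - n_decoy - n_auto
    p_other = 0.0
    if n_other:
        p_other = min(1.0, max(0.0, (config.frac_intragenic * config.n_loci - n_decoy) / n_other))

    rows, genes, exons, repeats, weights, truth = [], [], [], [], [], []
    decoy_seen = 0
    li = 0
    for ci, contig in enumerate(contigs):
        n_i = per_contig[ci]
        if n_i == 0:
            continue
        slot = config.contig_length_bp // n_i
        for s_i in range(n_i):
            slot_start = s_i * slot
            lo = slot_start + 7000
            hi = slot_start + slot - config.locus_length - 7000
            start = int(rng.integers(lo, max(lo + 1, hi)))
            end = start + config.locus_length
            strand = "+" if rng.random() < 0.5 else "-"
            cls = classes[li]
            locus_id = f"FL-L1-{li + 1:04d}"
            if cls == "host_driven_decoy":
                intragenic = True
                decoy_bias = "tumor" if decoy_seen % 2 == 0 else "uniform"
                decoy_seen += 1
            elif cls.startswith("autonomous"):
                intragenic = False
                decoy_bias = ""
            else:
                intragenic = bool(rng.random() < p_other)
                decoy_bias = ""
            host_id, host_same = "", None
            if intragenic:
                host_id = f"G{li + 1:04d}"
                if cls == "host_driven_decoy":
                    host_strand = strand
                else:
                    host_strand = strand if rng.random() < 0.5 else ("-" if strand == "+" else "+")
                host_same = host_strand == strand
                gs, ge = start - 3000, end + 3000
                genes.append((contig, gs, ge, host_id, 0, host_strand))
                exons.append((contig, gs, gs + 300, host_id, 0, host_strand))
                exons.append((contig, ge - 300, ge, host_id, 0, host_strand))
                if config.splice_decoys and cls == "silent" and li % 7 == 0:
                    # splice decoy: host exon inside the downstream window
                    ws = end if strand == "+" else start - config.window_bp
                    exons.append((contig, ws + 400, ws + 600, host_id, 0, host_strand))
                if cls == "host_driven_decoy":
                    wt = config.decoy_host_weight
                    wn = wt / config.decoy_tumor_bias if decoy_bias == "tumor" else wt
                else:
                    wt = wn = float(rng.lognormal(np.log(0.9), 0.5))
                weights.append((host_id, wt, wn))
            rows.append((contig, start, end, locus_id, 0, strand,
                         cls == "polyA_decoy", False, False, host_id, host_same))
            repeats.append((contig, start, end, f"L1:{locus_id}", 0, strand))
            # one unrelated repeat per slot exercises the repeat filter
            repeats.append((contig, slot_start + 3000, slot_start + 3500,
                            f"AluY:{li}", 0, "+"))
            truth.append((locus_id, cls, intragenic, host_id, host_same, decoy_bias))
            li += 1

    # flag a couple of autonomous loci as retrotransposition competent
    cat = pd.DataFrame(rows, columns=[
        "contig", "start", "end", "locus_id", "score", "strand", "polyA_extended",
        "retro_competent", "orf2_intact", "host_gene_id", "host_same_strand"])
    auto_idx = cat.index[[c.startswith("autonomous") for c in classes]]
    cat.loc[auto_idx[:2], "retro_competent"] = True
    cat.loc[auto_idx[:3], "orf2_intact"] = True

    # background genes in the free head of the first slots
    bg = 0
    for ci, contig in enumerate(contigs):
        n_i = per_contig[ci]
        if n_i == 0:
            continue
        slot = config.contig_length_bp // n_i
        for s_i in range(n_i):
            if bg >= config.n_background_genes:
                break
            gid = f"BG{bg + 1:04d}"
            gs = s_i * slot + 500
            strand = "+" if (bg % 2 == 0) else "-"
            genes.append((contig, gs, gs + 2000, gid, 0, strand))
            exons.append((contig, gs, gs + 300, gid, 0, strand))
            exons.append((contig, gs + 1700, gs + 2000, gid, 0, strand))
            w = float(rng.lognormal(np.log(0.9), 0.5))
            weights.append((gid, w, w))
            bg += 1

    genes_df = pd.DataFrame(genes, columns=bedcols + ["gene_id", "score", "strand"])
    exons_df = pd.DataFrame(exons, columns=bedcols + ["gene_id", "score", "strand"])
    repeats_df = pd.DataFrame(repeats, columns=bedcols + ["name", "score", "strand"])
    weights_df = pd.DataFrame(weights, columns=["gene_id", "weight_tumor", "weight_normal"])
    truth_df = pd.DataFrame(truth, columns=[
        "locus_id", "truth_class", "intragenic", "host_gene_id",
        "host_same_strand", "decoy_bias"])
    if config.gene_expr_rates:
        for gid, w in config.gene_expr_rates.items():
            weights_df.loc[weights_df.gene_id == gid, ["weight_tumor", "weight_normal"]] = w
    for df in (genes_df, exons_df, repeats_df):
        df.sort_values(["contig", "start"], inplace=True, kind="mergesort")
        df.reset_index(drop=True, inplace=True)
    cat = cat.sort_values(["contig", "start"], kind="mergesort").reset_index(drop=True)
    return Annotation(cat, genes_df, exons_df, repeats_df, weights_df, truth_df,
                      contig_lengths)


# ---------------------------------------------------------------------------
# cells
# ---------------------------------------------------------------------------

def _barcodes(n: int, length: int) -> np.ndarray:
    idx = np.arange(n)
    digits = (idx[:, None] // 4 ** np.arange(length)) % 4
    return np.array(["".join(_BASES[d]) for d in digits])


def simulate_cells(config: SimConfig) -> pd.DataFrame:
    """One row per cell: barcode, sample/patient ids, group, cell type, budget.

    Tumor patients contribute a pre-chemotherapy (``_p``) and a
    post-chemotherapy interval (``_i``) sample each; the epithelial-lineage
    cell-type slot is labelled ``cancer`` in tumor samples and ``epithelial``
    in normals.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    samples = []
    for p in range(config.n_tumor_pairs):
        pid = f"EOC{p + 1:02d}"
        samples.append((f"{pid}_p", pid, "tumor_pre", "tumor"))
        samples.append((f"{pid}_i", pid, "tumor_post", "tumor"))
    for s in range(config.n_normal_samples):
        samples.append((f"N{s + 1:02d}", f"N{s + 1:02d}", "normal", "normal"))

    types = list(config.celltype_proportions)
    props = np.array([config.celltype_proportions[t] for t in types])
    rows = []
    for sample_id, patient_id, group, group_class in samples:
        ct = rng.choice(types, size=config.cells_per_sample, p=props)
        if group_class == "normal":
            ct = np.where(ct == "cancer", "epithelial", ct)
        budget = np.maximum(
            1, np.round(rng.lognormal(config.umi_budget_logmean,
                                      config.umi_budget_logsd,
                                      config.cells_per_sample))).astype(np.int64)
        for t, b in zip(ct, budget):
            rows.append((sample_id, patient_id, group, group_class, t, int(b)))
    df = pd.DataFrame(rows, columns=["sample_id", "patient_id", "group",
                                     "group_class", "cell_type", "umi_budget"])
    df.insert(0, "barcode", _barcodes(len(df), config.barcode_length))
    return df


# ---------------------------------------------------------------------------
# single-cell reads
# ---------------------------------------------------------------------------

def encode_umi(codes: np.ndarray, length: int = 10) -> list[str]:
    digits = (np.asarray(codes)[:, None] // 4 ** np.arange(length)) % 4
    return ["".join(_BASES[d]) for d in digits]


def decode_umi(umis) -> np.ndarray:
    lut = {b: i for i, b in enumerate("ACGT")}
    return np.array([sum(lut[c] * 4 ** i for i, c in enumerate(u)) for u in umis],
                    dtype=np.int64)


def _window_coords(start, end, strand, window_bp):
    if strand == "+":
        return end, end + window_bp
    return start - window_bp, start


def simulate_reads_sc(annotation: Annotation, cells: pd.DataFrame,
                      config: SimConfig) -> tuple[pd.DataFrame, TruthLabels]:
    """Draw per-cell molecules and emit them as single-block aligned reads.

    Sources: (a) gene 3'-end reads, with host-gene molecules spilling into
    their resident L1's downstream window at ``host_spanning_rate``;
    (b) autonomous L1 read-through inside the downstream window; (c) poly-A
    artifact reads at flagged loci; (d) uniform intergenic background.
    PCR duplicates repeat the full record under a fresh read id.
    """
    rng = np.random.default_rng(config.seed + 2)
    n_cells = len(cells)
    read_len = config.read_length
    contigs = list(annotation.contig_lengths)
    truth_rows = []

    budget = cells["umi_budget"].to_numpy(dtype=float)
    is_tumor = (cells["group_class"] == "tumor").to_numpy()
    size_factor = budget / config.mean_budget

    gw = annotation.gene_weights
    genes = annotation.genes.set_index("gene_id")
    cat = annotation.catalog.set_index("locus_id")
    truth_cls = annotation.locus_classes.set_index("locus_id")

    # compact accumulators; expanded into a DataFrame once at the end
    contig_codes = {c: i for i, c in enumerate(contigs)}
    sources = ["gene", "spill", "bg", "l1", "polyA"]
    src_code = {s: i for i, s in enumerate(sources)}
    features: list[str] = [""]  # feature_truth category 0 = none
    feat_code: dict[str, int] = {"": 0}
    acc: list[tuple] = []  # (contig_code, start, plus_strand, cell_idx, src, feat)

    def _feat(name: str) -> int:
        if name not in feat_code:
            feat_code[name] = len(features)
            features.append(name)
        return feat_code[name]

    def emit(ccode, starts, plus, cell_idx, src, feat):
        acc.append((np.broadcast_to(np.int8(ccode), starts.shape).copy()
                    if np.isscalar(ccode) else ccode,
                    starts.astype(np.int64), plus, cell_idx.astype(np.int32),
                    np.broadcast_to(np.int8(src), starts.shape).copy()
                    if np.isscalar(src) else src,
                    np.broadcast_to(np.int32(feat), starts.shape).copy()
                    if np.isscalar(feat) else feat))

    # --- gene + background molecules (one Poisson matrix) -----------------
    if len(gw):
        w_t = gw["weight_tumor"].to_numpy(float)
        w_n = gw["weight_normal"].to_numpy(float)
        W_t = w_t.sum() + config.background_weight
        W_n = w_n.sum() + config.background_weight
        w_row = np.where(is_tumor[:, None], w_t[None, :], w_n[None, :])
        W_row = np.where(is_tumor, W_t, W_n)
        rates = budget[:, None] * w_row / W_row[:, None]
        counts = rng.poisson(rates)  # cells x genes
        cell_idx, gene_idx = np.nonzero(counts)
        reps = counts[cell_idx, gene_idx]
        cell_idx = np.repeat(cell_idx, reps)
        gene_idx = np.repeat(gene_idx, reps)
        n_mol = len(gene_idx)
        # per-gene lookup arrays
        gsub = genes.loc[gw["gene_id"]]
        g_start = gsub["start"].to_numpy(np.int64)
        g_end = gsub["end"].to_numpy(np.int64)
        g_plus = (gsub["strand"] == "+").to_numpy()
        g_contig = np.array([contig_codes[c] for c in gsub["contig"]], dtype=np.int8)
        host_locus = np.full(len(gsub), -1)
        win_s = np.zeros(len(gsub), dtype=np.int64)
        hosted = truth_cls[truth_cls["host_gene_id"] != ""]
        gpos = {g: i for i, g in enumerate(gw["gene_id"])}
        for lid, row in hosted.iterrows():
            gi = gpos.get(row["host_gene_id"])
            if gi is None:
                continue
            L = cat.loc[lid]
            ws, _we = _window_coords(L["start"], L["end"], L["strand"],
                                     config.window_bp)
            host_locus[gi] = _feat(lid)
            win_s[gi] = ws
        # 3'-end position (constant 302-bp sampling width given >=98-bp reads)
        off = rng.integers(0, 400 - read_len, n_mol)
        pos = np.where(g_plus[gene_idx], g_end[gene_idx] - 400 + off,
                       g_start[gene_idx] + off)
        spill = (host_locus[gene_idx] >= 0) & \
            (rng.random(n_mol) < config.host_spanning_rate)
        if spill.any():
            w_off = rng.integers(0, config.window_bp - read_len, int(spill.sum()))
            pos[spill] = win_s[gene_idx[spill]] + w_off
        feat = np.where(spill, host_locus[gene_idx],
                        np.array([_feat(g) for g in gw["gene_id"]],
                                 dtype=np.int32)[gene_idx]).astype(np.int32)
        src = np.where(spill, src_code["spill"], src_code["gene"]).astype(np.int8)
        emit(g_contig[gene_idx], pos, g_plus[gene_idx], cell_idx, src, feat)
    else:
        W_t = W_n = config.background_weight

    # background molecules: uniform over the genome
    rate_bg = np.where(is_tumor, budget * config.background_weight / W_t,
                       budget * config.background_weight / W_n)
    counts = rng.poisson(rate_bg)
    total = int(counts.sum())
    if total:
        cell_idx = np.repeat(np.arange(n_cells), counts)
        which = rng.integers(0, len(contigs), total).astype(np.int8)
        lens = np.array([annotation.contig_lengths[c] for c in contigs])
        pos = rng.integers(0, lens[which] - read_len)
        plus = rng.random(total) < 0.5
        emit(which, pos, plus, cell_idx, np.int8(src_code["bg"]), np.int32(0))

    # --- autonomous L1 molecules ----------------------------------------
    activity = config.activity_map()
    group_class = cells["group_class"].to_numpy()
    cell_type = cells["cell_type"].to_numpy()
    for lid, row in truth_cls.iterrows():
        cls = row["truth_class"]
        rates_map = activity.get(cls)
        if not rates_map:
            continue
        rate = np.zeros(n_cells)
        for (g, t), r in rates_map.items():
            m = np.ones(n_cells, dtype=bool)
            if g != "*":
                m &= group_class == g
            if t != "*":
                m &= cell_type == t
            rate[m] = r
        rate = rate * size_factor
        counts = rng.poisson(rate)
        total = int(counts.sum())
        if total == 0:
            continue
        cell_idx = np.repeat(np.arange(n_cells), counts)
        expressing = np.flatnonzero(counts)
        truth_rows += [(cells["barcode"].iat[i], lid) for i in expressing]
        L = cat.loc[lid]
        ws, we = _window_coords(L["start"], L["end"], L["strand"], config.window_bp)
        d = rng.exponential(config.readthrough_decay_bp, total)
        offset = np.clip(np.round(d).astype(np.int64) - 20, -39,
                         config.window_bp - read_len)
        if L["strand"] == "+":
            pos = ws + offset
        else:
            pos = we - read_len - offset
        emit(np.int8(contig_codes[L["contig"]]), pos, np.full(total, L["strand"] == "+"),
             cell_idx, np.int8(src_code["l1"]), np.int32(_feat(lid)))

    # --- poly-A artifact molecules at flagged loci -----------------------
    for lid, L in cat[cat["polyA_extended"]].iterrows():
        counts = rng.poisson(config.polyA_locus_rate * size_factor)
        total = int(counts.sum())
        if total == 0:
            continue
        cell_idx = np.repeat(np.arange(n_cells), counts)
        ws, we = _window_coords(L["start"], L["end"], L["strand"], config.window_bp)
        pos = rng.integers(ws, we - read_len, total)
        emit(np.int8(contig_codes[L["contig"]]), pos, np.full(total, L["strand"] == "+"),
             cell_idx, np.int8(src_code["polyA"]), np.int32(_feat(lid)))

    if acc:
        ccode = np.concatenate([a[0] for a in acc])
        start = np.concatenate([a[1] for a in acc])
        plus = np.concatenate([a[2] for a in acc])
        cell_idx = np.concatenate([a[3] for a in acc])
        src = np.concatenate([a[4] for a in acc])
        feat = np.concatenate([a[5] for a in acc])
    else:
        ccode = np.array([], dtype=np.int8)
        start = np.array([], dtype=np.int64)
        plus = np.array([], dtype=bool)
        cell_idx = np.array([], dtype=np.int32)
        src = np.array([], dtype=np.int8)
        feat = np.array([], dtype=np.int32)
    n = len(start)
    reads = pd.DataFrame({
        "contig": pd.Categorical.from_codes(ccode, categories=contigs),
        "start": start,
        "end": start + read_len,
        "strand": pd.Categorical.from_codes((~plus).astype(np.int8),
                                            categories=["+", "-"]),
        "barcode": pd.Categorical.from_codes(cell_idx,
                                             categories=cells["barcode"]),
        "source": pd.Categorical.from_codes(src, categories=sources),
        "feature_truth": pd.Categorical.from_codes(feat, categories=features),
    })
    reads["umi"] = rng.integers(0, 4 ** config.umi_length, n)

    # base composition; window-derived reads may become A/T-rich artifacts
    frac_a = np.clip(rng.normal(0.25, 0.05, n), 0.02, 0.45)
    frac_t = np.clip(rng.normal(0.25, 0.05, n), 0.02, 0.45)
    window_src = reads["source"].isin(["spill", "l1"]).to_numpy() if n else \
        np.array([], dtype=bool)
    art = np.zeros(n, dtype=bool)
    if n:
        art = (window_src & (rng.random(n) < config.polyA_artifact_rate)) | \
            (reads["source"] == "polyA").to_numpy()
    rich = 0.60 + 0.30 * rng.random(n)
    plus = (reads["strand"] == "+").to_numpy() if n else np.array([], dtype=bool)
    frac_a = np.where(art & plus, rich, frac_a)
    frac_t = np.where(art & ~plus, rich, frac_t)
    frac_t = np.where(art & plus, np.minimum(frac_t, 1 - frac_a), frac_t)
    frac_a = np.where(art & ~plus, np.minimum(frac_a, 1 - frac_t), frac_a)
    reads["frac_a"] = np.round(frac_a, 4)
    reads["frac_t"] = np.round(frac_t, 4)
    reads["n_alignments"] = np.where(rng.random(n) < config.multi_align_rate, 2, 1)
    reads["n_mismatches"] = rng.integers(0, 3, n)

    # PCR duplicates: re-emit the same molecule record
    dup = rng.random(n) < config.pcr_duplicate_rate
    if dup.any():
        reads = pd.concat([reads, reads[dup]], ignore_index=True)
    reads = reads.sort_values(["contig", "start"],
                              kind="mergesort").reset_index(drop=True)
    reads["read_id"] = np.arange(len(reads))

    cell_flags = pd.DataFrame(sorted(set(truth_rows)), columns=["barcode", "locus_id"])
    return reads, TruthLabels(annotation.locus_classes.copy(), cell_flags)


# ---------------------------------------------------------------------------
# bulk fragments
# ---------------------------------------------------------------------------

def simulate_reads_bulk(annotation: Annotation,
                        config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired-end fragments over the L1 windows, plus exonic noise pairs.

    Autonomous loci receive ~``bulk_down_autonomous``:``bulk_up_autonomous``
    downstream:upstream fragments (10:1 by default); host-driven decoys are
    balanced. The strand-informative mate carries SAM flag 67 (read1,
    + fragments) or 131 (read2, - fragments); the other mate gets 147/83.
    Returns the read table and the per-locus drawn fragment-count truth.
    """
    rng = np.random.default_rng(config.seed + 3)
    rows, truth = [], []
    frag_len = config.bulk_fragment_length
    read_len = config.read_length
    qid = 0

    def add_pair(contig, fs, strand):
        nonlocal qid
        fe = fs + frag_len
        if strand == "+":
            # read1 forward (67), read2 reverse (147)
            rows.append((f"frag{qid:07d}", 67, contig, fs, fs + read_len, "+"))
            rows.append((f"frag{qid:07d}", 147, contig, fe - read_len, fe, "-"))
        else:
            rows.append((f"frag{qid:07d}", 83, contig, fe - read_len, fe, "-"))
            rows.append((f"frag{qid:07d}", 131, contig, fs, fs + read_len, "+"))
        qid += 1

    for _, L in annotation.catalog.iterrows():
        cls = annotation.locus_classes.set_index("locus_id").loc[
            L["locus_id"], "truth_class"]
        ws_d, we_d = _window_coords(L["start"], L["end"], L["strand"], config.window_bp)
        ws_u, we_u = _window_coords(L["start"], L["end"],
                                    "-" if L["strand"] == "+" else "+", config.window_bp)
        if cls.startswith("autonomous"):
            lam_d, lam_u = config.bulk_down_autonomous, config.bulk_up_autonomous
        elif cls == "host_driven_decoy":
            lam_d = lam_u = config.bulk_decoy_rate
        else:
            lam_d = lam_u = config.bulk_background_rate
        n_d = int(rng.poisson(lam_d))
        n_u = int(rng.poisson(lam_u))
        for n, (ws, we) in ((n_d, (ws_d, we_d)), (n_u, (ws_u, we_u))):
            for _ in range(n):
                fs = int(rng.integers(ws, we - frag_len))
                add_pair(L["contig"], fs, L["strand"])
        truth.append((L["locus_id"], n_d, n_u))

    # exonic noise pairs (removed by the bulk exon filter) and stray flags
    ex = annotation.exons
    for _ in range(config.bulk_noise_pairs):
        if len(ex) == 0:
            break
        e = ex.iloc[int(rng.integers(0, len(ex)))]
        fs = int(rng.integers(e["start"], max(e["start"] + 1, e["end"] - frag_len)))
        add_pair(e["contig"], fs, str(e["strand"]))
    for _ in range(10):  # non-proper records, ignored and tallied downstream
        contig = list(annotation.contig_lengths)[0]
        fs = int(rng.integers(0, annotation.contig_lengths[contig] - read_len))
        rows.append((f"stray{qid:07d}", 0, contig, fs, fs + read_len, "+"))
        qid += 1

    reads = pd.DataFrame(rows, columns=["qname", "flag", "contig", "start", "end",
                                        "strand"])
    reads = reads.sort_values(["contig", "start", "qname"],
                              kind="mergesort").reset_index(drop=True)
    truth_df = pd.DataFrame(truth, columns=["locus_id", "sim_down", "sim_up"])
    return reads, truth_df


# ---------------------------------------------------------------------------
# writers / readers
# ---------------------------------------------------------------------------

def _sam_header(contig_lengths: dict) -> dict:
    return {"HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": int(l)} for c, l in contig_lengths.items()]}


def write_sam_sc(reads: pd.DataFrame, contig_lengths: dict, path: str,
                 umi_length: int = 10) -> None:
    """Write single-cell reads as plain SAM with CB/UB/NH/nM (+fa/ft) tags."""
    header = pysam.AlignmentHeader.from_dict(_sam_header(contig_lengths))
    tid = {c: i for i, c in enumerate(contig_lengths)}
    umis = encode_umi(reads["umi"].to_numpy(), umi_length)
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for i, row in enumerate(reads.itertuples(index=False)):
            a = pysam.AlignedSegment(header)
            a.query_name = f"r{row.read_id:08d}"
            a.flag = 16 if row.strand == "-" else 0
            a.reference_id = tid[row.contig]
            a.reference_start = int(row.start)
            a.mapping_quality = 255
            a.cigartuples = [(0, int(row.end - row.start))]
            a.set_tags([("CB", row.barcode), ("UB", umis[i]),
                        ("NH", int(row.n_alignments), "i"),
                        ("nM", int(row.n_mismatches), "i"),
                        ("fa", float(row.frac_a), "f"),
                        ("ft", float(row.frac_t), "f")])
            out.write(a)


def read_sam_sc(path: str, cb_tag: str = "CB", ub_tag: str = "UB") -> pd.DataFrame:
    """Load a (coordinate-sorted) SAM/BAM into the tabular read format.

    Multi-block (spliced) alignments keep their block list in a ``blocks``
    column; A/T fractions come from fa/ft tags or the sequence itself.
    """
    rows = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as f:
        for a in f:
            if a.is_unmapped:
                continue
            blocks = a.get_blocks()
            if a.has_tag("fa"):
                fa, ft = float(a.get_tag("fa")), float(a.get_tag("ft"))
            elif a.query_sequence:
                seq = a.query_sequence.upper()
                fa = seq.count("A") / len(seq)
                ft = seq.count("T") / len(seq)
            else:
                fa = ft = 0.0
            rows.append((a.query_name,
                         a.get_tag(cb_tag) if a.has_tag(cb_tag) else "",
                         a.get_tag(ub_tag) if a.has_tag(ub_tag) else "",
                         a.reference_name, blocks[0][0], blocks[-1][1],
                         "-" if a.is_reverse else "+", fa, ft,
                         int(a.get_tag("NH")) if a.has_tag("NH") else 1,
                         int(a.get_tag("nM")) if a.has_tag("nM") else 0,
                         blocks if len(blocks) > 1 else None))
    df = pd.DataFrame(rows, columns=["read_id", "barcode", "umi", "contig", "start",
                                     "end", "strand", "frac_a", "frac_t",
                                     "n_alignments", "n_mismatches", "blocks"])
    if len(df) and df["umi"].astype(str).str.len().max() > 0:
        try:
            df["umi"] = decode_umi(df["umi"].astype(str))
        except KeyError:
            pass  # non-ACGT UMIs stay as strings
    return df


def write_sam_bulk(reads: pd.DataFrame, contig_lengths: dict, path: str) -> None:
    header = pysam.AlignmentHeader.from_dict(_sam_header(contig_lengths))
    tid = {c: i for i, c in enumerate(contig_lengths)}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for row in reads.itertuples(index=False):
            a = pysam.AlignedSegment(header)
            a.query_name = row.qname
            a.flag = int(row.flag)
            a.reference_id = tid[row.contig]
            a.reference_start = int(row.start)
            a.mapping_quality = 255
            a.cigartuples = [(0, int(row.end - row.start))]
            out.write(a)


def write_bed(df: pd.DataFrame, path: str, name_col: str = "name") -> None:
    """Write the first six BED columns (0-based half-open, as stored)."""
    cols = ["contig", "start", "end", name_col, "score", "strand"]
    df[cols].to_csv(path, sep="\t", header=False, index=False)
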