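"""Window construction, overlap fractions, the four-rule filter, counting."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from l1pipe._intervals import GenomeIntervals
from l1pipe import sc_quant
from l1pipe.sc_quant import (AlignedRead, FilterConfig, UmiCountMatrix,
                             build_windows, count_genes, dedup_count,
                             filter_reads, overlap_fraction)

import oracles


def _catalog(rows):
    return pd.DataFrame(rows, columns=["contig", "start", "end", "locus_id",
                                       "score", "strand"])


def _reads(rows, extra_cols=()):
    cols = ["read_id", "barcode", "umi", "contig", "start", "end", "strand",
            "frac_a", "frac_t", "n_alignments", "n_mismatches"]
    df = pd.DataFrame(rows, columns=cols)
    return df


def _win_df(rows):
    return pd.DataFrame(rows, columns=["locus_id", "contig", "start", "end",
                                       "strand", "layer", "clipped"])


EX0 = pd.DataFrame(columns=["contig", "start", "end"])


class TestBuildWindows:
    @pytest.mark.parametrize("strand,down,up", [
        ("+", (11000, 12000), (4000, 5000)),
        ("-", (4000, 5000), (11000, 12000)),
    ])
    def test_strand_convention(self, strand, down, up):
        cat = _catalog([("chr1", 5000, 11000, "L1", 0, strand)])
        w = build_windows(cat).set_index("layer")
        assert (w.loc["downstream", "start"], w.loc["downstream", "end"]) == down
        assert (w.loc["upstream", "start"], w.loc["upstream", "end"]) == up
        assert not w["clipped"].any()

    def test_clipping_at_contig_edges(self):
        cat = _catalog([("chr1", 300, 6300, "L1", 0, "+")])
        w = build_windows(cat, contig_lengths={"chr1": 6800}).set_index("layer")
        assert (w.loc["upstream", "start"], w.loc["upstream", "end"]) == (0, 300)
        assert w.loc["upstream", "clipped"]
        assert (w.loc["downstream", "start"], w.loc["downstream", "end"]) == (6300, 6800)
        assert w.loc["downstream", "clipped"]

    def test_unknown_contig_raises(self):
        cat = _catalog([("chrX", 5000, 11000, "L1", 0, "+")])
        with pytest.raises(KeyError, match="chrX"):
            build_windows(cat, contig_lengths={"chr1": 100000})


class TestOverlapFraction:
    def iv(self, rows):
        return GenomeIntervals(pd.DataFrame(rows, columns=["contig", "start", "end"]))

    def test_fully_inside(self):
        r = AlignedRead("b", 1, "c", [(100, 198)], "+")
        assert overlap_fraction(r, self.iv([("c", 0, 1000)])) == 1.0

    def test_partial_arithmetic(self):
        r = AlignedRead("b", 1, "c", [(0, 98)], "+")
        assert overlap_fraction(r, self.iv([("c", 68, 500)])) == pytest.approx(30 / 98)

    def test_empty_blocks_is_domain_error(self):
        with pytest.raises(ValueError):
            overlap_fraction(AlignedRead("b", 1, "c", [], "+"), self.iv([]))

    def test_spliced_reads_match_per_base_oracle(self):
        rng = np.random.default_rng(42)
        iv_rows = [("c", int(s), int(s) + int(l))
                   for s, l in zip(rng.integers(0, 5000, 40),
                                   rng.integers(10, 300, 40))]
        index = self.iv(iv_rows)
        for _ in range(300):
            s1 = int(rng.integers(0, 4800))
            l1 = int(rng.integers(5, 80))
            gap = int(rng.integers(1, 200))
            l2 = int(rng.integers(5, 80))
            blocks = [(s1, s1 + l1), (s1 + l1 + gap, s1 + l1 + gap + l2)]
            r = AlignedRead("b", 1, "c", blocks, "+")
            got = overlap_fraction(r, index)
            exp = oracles.brute_overlap_fraction(blocks, [(a, b) for _, a, b in iv_rows])
            assert got == pytest.approx(exp, abs=1e-12)


class TestFilterRules:
    """Each rule boundary, on a one-window setup."""

    windows = _win_df([("L1", "c", 1000, 2000, "+", "downstream", False),
                       ("L1", "c", 7000, 8000, "+", "upstream", False)])

    def run_one(self, read_row, exons=EX0, repeats=EX0, cfg=None):
        reads = _reads([read_row])
        kept, report = filter_reads(reads, exons, repeats, self.windows, cfg)
        return kept, report

    def test_clean_window_read_is_kept(self):
        kept, _ = self.run_one((0, "b", 1, "c", 1100, 1198, "+", .25, .25, 1, 0))
        assert len(kept) == 1 and kept.iloc[0]["locus_id"] == "L1"
        assert kept.iloc[0]["layer"] == "downstream"

    @pytest.mark.parametrize("fa,ft,removed", [
        (0.61, 0.2, True),   # A-rich
        (0.60, 0.2, True),   # boundary inclusive: "60 percent or higher"
        (0.2, 0.61, True),   # T-rich
        (0.59, 0.39, False),
    ])
    def test_polya_boundary(self, fa, ft, removed):
        kept, rep = self.run_one((0, "b", 1, "c", 1100, 1198, "+", fa, ft, 1, 0))
        assert (len(kept) == 0) == removed
        if removed:
            assert rep.removed["polyA"] == 1

    def test_combined_at_mode(self):
        cfg = FilterConfig(at_mode="combined")
        kept, _ = self.run_one((0, "b", 1, "c", 1100, 1198, "+", .35, .30, 1, 0),
                               cfg=cfg)
        assert len(kept) == 0  # 0.65 >= 0.60 combined

    def test_exon_one_percent_boundary_inclusive(self):
        # 100-bp read, exactly 1 exonic base -> fraction 0.01 -> excluded
        exons = pd.DataFrame([("c", 1150, 1151)], columns=["contig", "start", "end"])
        kept, rep = self.run_one((0, "b", 1, "c", 1100, 1200, "+", .2, .2, 1, 0),
                                 exons=exons)
        assert len(kept) == 0 and rep.removed["exon"] == 1

    def test_repeat_ninety_percent_boundary(self):
        repeats = pd.DataFrame([("c", 1100, 1190)], columns=["contig", "start", "end"])
        # 100-bp read, 90 repeat bases -> 0.90 -> excluded
        kept, rep = self.run_one((0, "b", 1, "c", 1100, 1200, "+", .2, .2, 1, 0),
                                 repeats=repeats)
        assert len(kept) == 0 and rep.removed["repeat"] == 1
        # 89 bases -> kept
        repeats = pd.DataFrame([("c", 1100, 1189)], columns=["contig", "start", "end"])
        kept, _ = self.run_one((0, "b", 1, "c", 1100, 1200, "+", .2, .2, 1, 0),
                               repeats=repeats)
        assert len(kept) == 1

    def test_window_sixty_percent_boundary(self):
        # 100-bp read with 60 bases in window -> kept; 59 -> removed
        kept, _ = self.run_one((0, "b", 1, "c", 1940, 2040, "+", .2, .2, 1, 0))
        assert len(kept) == 1
        kept, rep = self.run_one((0, "b", 1, "c", 1941, 2041, "+", .2, .2, 1, 0))
        assert len(kept) == 0 and rep.removed["window"] == 1

    def test_strand_and_uniqueness_rules(self):
        kept, rep = self.run_one((0, "b", 1, "c", 1100, 1198, "-", .2, .2, 1, 0))
        assert len(kept) == 0 and rep.removed["strand"] == 1
        kept, rep = self.run_one((0, "b", 1, "c", 1100, 1198, "+", .2, .2, 2, 0))
        assert len(kept) == 0 and rep.removed["multimap"] == 1
        kept, rep = self.run_one((0, "b", 1, "c", 1100, 1198, "+", .2, .2, 1, 3))
        assert len(kept) == 0 and rep.removed["mismatch"] == 1

    def test_ambiguous_two_loci_dropped(self):
        windows = _win_df([
            ("A", "c", 1000, 2000, "+", "downstream", False),
            ("B", "c", 1900, 2900, "+", "downstream", False)])
        # 100-bp read with 60 bases in A and 100-40=... spans both at >=60%?
        # place read [1840,1940): 60 bases in A's window... also 40 in B
        reads = _reads([(0, "b", 1, "c", 1840, 1940, "+", .2, .2, 1, 0)])
        kept, rep = filter_reads(reads, EX0, EX0, windows)
        assert len(kept) == 1  # only A reaches 60%
        # read [1900,2000) overlaps A 100% and B 100% -> ambiguous
        reads = _reads([(1, "b", 1, "c", 1900, 2000, "+", .2, .2, 1, 0)])
        kept, rep = filter_reads(reads, EX0, EX0, windows)
        assert len(kept) == 0 and rep.removed["ambiguous"] == 1

    def test_empty_input(self):
        kept, rep = filter_reads(_reads([]), EX0, EX0, self.windows)
        assert len(kept) == 0 and rep.n_input == 0
        assert all(v == 0 for v in rep.removed.values())

    def test_kept_set_is_permutation_invariant(self):
        """Every kept read passes each pure predicate of the oracle."""
        rng = np.random.default_rng(0)
        rows = []
        for i in range(400):
            start = int(rng.integers(900, 2100))
            rows.append((i, "b", i, "c", start, start + 98,
                         "+" if rng.random() < 0.7 else "-",
                         float(rng.random() * 0.8), float(rng.random() * 0.3),
                         1 if rng.random() < 0.9 else 2,
                         int(rng.integers(0, 4))))
        reads = _reads(rows)
        exons = pd.DataFrame([("c", 950, 1010)], columns=["contig", "start", "end"])
        reps = pd.DataFrame([("c", 0, 1000)], columns=["contig", "start", "end"])
        kept, _ = filter_reads(reads, exons, reps, self.windows)
        expected = oracles.brute_filter_and_assign(reads, exons, reps,
                                                   self.windows, FilterConfig())
        assert set(kept["read_id"]) == set(expected)


class TestCounting:
    windows = _win_df([("L1", "c", 1000, 2000, "+", "downstream", False),
                       ("L1", "c", 7000, 8000, "+", "upstream", False)])
    cells = pd.DataFrame({"barcode": ["AA", "CC"]})

    def kept(self, rows):
        df = _reads(rows)
        df["locus_id"] = "L1"
        df["layer"] = "downstream"
        return df

    def test_duplicate_umi_collapses(self):
        k = self.kept([(0, "AA", 5, "c", 1100, 1198, "+", .2, .2, 1, 0),
                       (1, "AA", 5, "c", 1150, 1248, "+", .2, .2, 1, 0)])
        layers, _ = dedup_count(k, self.windows, self.cells)
        assert layers["downstream"].to_df().loc["L1", "AA"] == 1

    def test_same_umi_two_cells_counts_twice(self):
        k = self.kept([(0, "AA", 5, "c", 1100, 1198, "+", .2, .2, 1, 0),
                       (1, "CC", 5, "c", 1100, 1198, "+", .2, .2, 1, 0)])
        layers, _ = dedup_count(k, self.windows, self.cells)
        df = layers["downstream"].to_df()
        assert df.loc["L1", "AA"] == 1 and df.loc["L1", "CC"] == 1

    def test_unknown_barcode_dropped_and_logged(self):
        k = self.kept([(0, "TT", 5, "c", 1100, 1198, "+", .2, .2, 1, 0)])
        layers, dropped = dedup_count(k, self.windows, self.cells)
        assert dropped == 1 and layers["downstream"].X.sum() == 0

    def test_recounting_counted_output_is_identity(self):
        """Dedup is idempotent: unique triples count once however repeated."""
        k = self.kept([(i, "AA", u, "c", 1100, 1198, "+", .2, .2, 1, 0)
                       for i, u in enumerate([1, 1, 2, 3, 3, 3])])
        layers, _ = dedup_count(k, self.windows, self.cells)
        once = layers["downstream"].to_df()
        again, _ = dedup_count(k.drop_duplicates(["barcode", "umi", "locus_id"]),
                               self.windows, self.cells)
        assert once.equals(again["downstream"].to_df())
        assert once.loc["L1", "AA"] == 3


class TestAgainstGeneratorTruth:
    def test_polya_removals_match_configured_rate(self):
        from conftest import small_sim_config
        from l1pipe import synth
        cfg = small_sim_config(seed=21, polyA_artifact_rate=0.2,
                               cells_per_sample=60, pcr_duplicate_rate=0.0)
        ann = synth.generate_annotation(cfg)
        cells = synth.simulate_cells(cfg)
        reads, _ = synth.simulate_reads_sc(ann, cells, cfg)
        win_reads = reads[reads["source"].isin(["spill", "l1"])]
        n = len(win_reads)
        removed = ((win_reads["frac_a"] >= 0.6) | (win_reads["frac_t"] >= 0.6)).sum()
        sd = np.sqrt(n * 0.2 * 0.8)
        assert abs(removed - 0.2 * n) < 3 * sd

    def test_counts_match_set_oracle_on_simulated_reads(self, small_dataset):
        reads = small_dataset["reads"].head(10_000)
        ann = small_dataset["annotation"]
        windows = small_dataset["windows"]
        kept, _ = filter_reads(reads, ann.exons, ann.repeats, windows)
        layers, _ = dedup_count(kept, windows, small_dataset["cells"])
        assigned = list(zip(kept["barcode"], kept["umi"], kept["locus_id"],
                            kept["layer"]))
        for layer in ("downstream", "upstream"):
            expected = oracles.brute_umi_counts(assigned, layer)
            got = layers[layer].to_df()
            assert int(got.to_numpy().sum()) == sum(expected.values())
            for (locus, bc), v in expected.items():
                assert got.loc[locus, bc] == v

    def test_upstream_sparse_relative_to_downstream(self, small_study):
        down = small_study["layers"]["downstream"].X.sum()
        up = small_study["layers"]["upstream"].X.sum()
        assert up < 0.05 * down

    def test_gene_counts_match_brute_force(self, small_dataset):
        reads = small_dataset["reads"].head(3000)
        genes = small_dataset["annotation"].genes
        cells = small_dataset["cells"]
        got = count_genes(reads, genes, cells).to_df()
        expected = oracles.brute_gene_counts(reads, genes)
        assert int(got.to_numpy().sum()) == sum(expected.values())
        for (g, b), v in expected.items():
            assert got.loc[g, b] == v

    def test_opposite_strand_gene_not_counted(self):
        genes = pd.DataFrame([("c", 0, 2000, "G1", 0, "+"),
                              ("c", 0, 2000, "G2", 0, "-")],
                             columns=["contig", "start", "end", "gene_id",
                                      "score", "strand"])
        reads = _reads([(0, "AA", 1, "c", 100, 198, "+", .2, .2, 1, 0)])
        cells = pd.DataFrame({"barcode": ["AA"]})
        df = count_genes(reads, genes, cells).to_df()
        assert df.loc["G1", "AA"] == 1 and df.loc["G2", "AA"] == 0
        assert (df.loc["G2"] == 0).all()  # zero row retained


@settings(max_examples=30, deadline=None)
@given(st.lists(st.tuples(st.integers(0, 500), st.integers(1, 100)),
                min_size=1, max_size=6))
def test_overlap_fraction_bounds(blocks_raw):
    blocks, cursor = [], 0
    for off, ln in blocks_raw:
        s = cursor + off
        blocks.append((s, s + ln))
        cursor = s + ln + 1
    iv = GenomeIntervals(pd.DataFrame([("c", 50, 400)],
                                      columns=["contig", "start", "end"]))
    r = AlignedRead("b", 1, "c", blocks, "+")
    f = overlap_fraction(r, iv)
    assert 0.0 <= f <= 1.0
    assert f == pytest.approx(
        oracles.brute_overlap_fraction(blocks, [(50, 400)]), abs=1e-12)
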