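import pytest

import l1pipe
from l1pipe import sc_quant, synth


def small_sim_config(seed=11, **kw):
    base = dict(
        seed=seed,
        n_loci=40,
        class_counts={"autonomous_tumor": 6, "host_driven_decoy": 8,
                      "polyA_decoy": 2},
        n_tumor_pairs=4,
        n_normal_samples=3,
        cells_per_sample=80,
        n_background_genes=10,
        # stronger rates than the full-size default: with only 3 x 40
        # epithelial cells the threefold rule needs non-zero normal means,
        # and the tumor:normal contrast must survive background dilution
        l1_activity={"autonomous_tumor": {("tumor", "cancer"): 0.25,
                                          ("normal", "epithelial"): 0.03}},
    )
    base.update(kw)
    return synth.SimConfig(**base)


@pytest.fixture(scope="session")
def sim_config():
    return small_sim_config()


@pytest.fixture(scope="session")
def small_dataset(sim_config):
    """One small simulated cohort shared across read-level tests."""
    ann = synth.generate_annotation(sim_config)
    cells = synth.simulate_cells(sim_config)
    reads, truth = synth.simulate_reads_sc(ann, cells, sim_config)
    windows = sc_quant.build_windows(ann.catalog, sim_config.window_bp,
                                     ann.contig_lengths)
    return {"config": sim_config, "annotation": ann, "cells": cells,
            "reads": reads, "truth": truth, "windows": windows}


@pytest.fixture(scope="session")
def small_study(sim_config):
    """Full in-memory analysis of the small cohort (full detected universe)."""
    return l1pipe.run_sc_study(sim_config, top_fraction=1.0)
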