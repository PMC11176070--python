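import numpy as np
import pandas as pd
import pytest

from scmosaic import (ConfigError, CreSimConfig, ExprSimConfig, MsvEvent,
                      NOSimConfig, SimConfig, simulate_cre_haplotype_counts,
                      simulate_expression, simulate_no_matrix,
                      simulate_strand_cells)

GENOME = [("chr1", 20_000_000), ("chr2", 20_000_000)]


def test_config_validation():
    with pytest.raises(ConfigError):
        SimConfig(genome=GENOME, bin_width=0)
    with pytest.raises(ConfigError):
        SimConfig(genome=GENOME, background_noise=0.6)
    with pytest.raises(ConfigError):
        SimConfig(genome=GENOME,
                  msv_events=[("del", "chr9", 0, 1_000_000, "H1", 0.5)])
    with pytest.raises(ConfigError):
        SimConfig(genome=GENOME,
                  msv_events=[("del", "chr1", 0, 30_000_000, "H1", 0.5)])
    # overlapping same-haplotype events are rejected; different haplotypes OK
    ev = [("del", "chr1", 0, 2_000_000, "H1", 0.3),
          ("dup", "chr1", 1_000_000, 3_000_000, "H1", 0.3)]
    with pytest.raises(ConfigError):
        SimConfig(genome=GENOME, msv_events=ev)
    ev[1] = ("dup", "chr1", 1_000_000, 3_000_000, "H2", 0.3)
    SimConfig(genome=GENOME, msv_events=ev)
    with pytest.raises(ConfigError):
        MsvEvent("delinv", "chr1", 0, 10, "H1", 0.5)
    with pytest.raises(ConfigError):
        MsvEvent("del", "chr1", 0, 10, "H3", 0.5)


def test_strand_sim_determinism():
    cfg = SimConfig(genome=GENOME, n_cells=5, seed=11)
    m1, t1 = simulate_strand_cells(cfg)
    m2, t2 = simulate_strand_cells(cfg)
    assert (m1.W == m2.W).all() and (m1.C == m2.C).all()
    assert t1.sce_positions == t2.sce_positions


def test_strand_sim_read_depth_and_states():
    cfg = SimConfig(genome=GENOME, n_cells=30, reads_per_cell=20_000.0, seed=1)
    m, truth = simulate_strand_cells(cfg)
    # mean total reads per cell ~ reads_per_cell (Poisson)
    assert abs(m.total.sum() / 30 - 20_000) < 500
    # every (cell, chromosome) has a ground state from the 4 true states
    assert set(truth.ground_states.values()) <= {"WW", "WC", "CW", "CC"}
    assert len(truth.ground_states) == 30 * 2


def test_del_cf_half_carriers_and_depth():
    # one del at CF 0.5 over 100 cells: half the cells carry it and their
    # binned depth inside the interval is about half the outside depth
    cfg = SimConfig(genome=GENOME, n_cells=100, reads_per_cell=40_000.0,
                    sce_rate=0.0,
                    msv_events=[("del", "chr1", 5_000_000, 15_000_000,
                                 "H1", 0.5)],
                    seed=3)
    m, truth = simulate_strand_cells(cfg)
    carriers = truth.msv_carriers["msv_0"]
    assert abs(len(carriers) - 50) <= 1
    inside = m.chrom_mask("chr1") & (m.bins["start"] >= 5_000_000).to_numpy() \
        & (m.bins["end"] <= 15_000_000).to_numpy()
    outside = ~inside
    idx = [i for i, c in enumerate(m.cells) if c in set(carriers)]
    tot = m.total
    # bins all have equal width here, so mean depth ratio ~ copy ratio 1/2
    ratio = (tot[idx][:, inside].mean() / tot[idx][:, outside].mean())
    assert abs(ratio - 0.5) < 0.05


def test_sce_rate_mean_four():
    cfg = SimConfig(genome=GENOME, n_cells=300, sce_rate=4.0, seed=5)
    _, truth = simulate_strand_cells(cfg)
    mean_sces = np.mean([len(v) for v in truth.sce_positions.values()])
    assert abs(mean_sces - 4.0) <= 0.4  # within 10% of the configured rate


def test_sce_hotspot_weighting():
    hs = ("chr1", 2_000_000, 3_000_000)
    cfg = SimConfig(genome=GENOME, n_cells=200, sce_rate=2.0,
                    sce_hotspots=[(hs, 1e9)], seed=6)
    _, truth = simulate_strand_cells(cfg)
    pos = [p for v in truth.sce_positions.values() for p in v]
    in_hs = [1 for (c, bp, _) in pos
             if c == "chr1" and 2_000_000 <= bp < 3_000_000]
    assert len(in_hs) / len(pos) > 0.99


def test_planted_cf_within_binomial_ci():
    # planted carrier frequency consistent with the configured CF (99% CI)
    cfg = SimConfig(genome=GENOME, n_cells=400, sce_rate=0.0,
                    msv_events=[("dup", "chr2", 1_000_000, 4_000_000,
                                 "H2", 0.25)], seed=7)
    _, truth = simulate_strand_cells(cfg)
    k = len(truth.msv_carriers["msv_0"])
    se = np.sqrt(0.25 * 0.75 / 400)
    assert abs(k / 400 - 0.25) <= max(2.58 * se, 1 / 400)


def test_no_sim_effect_zero_warns_and_is_flat():
    with pytest.warns(UserWarning):
        m, truth = simulate_no_matrix(NOSimConfig(
            n_classes=2, n_cells=80, n_genes=100, signature_size=10,
            effect=0.0, seed=2))
    lab = pd.Series(truth.celltype_labels)
    a = m.counts[lab == "class_0"].mean()
    b = m.counts[lab == "class_1"].mean()
    # no planted effect: the signed between-class difference averages to zero
    assert abs((a - b).mean()) < 1.0


def test_no_sim_signature_blocks_disjoint():
    m, truth = simulate_no_matrix(NOSimConfig(seed=3))
    sigs = list(truth.signature_genes.values())
    flat = [g for s in sigs for g in s]
    assert len(flat) == len(set(flat)) == 8 * 40
    assert truth.signature_effect == 1.0


def test_no_sim_rejects_impossible():
    with pytest.raises(ConfigError):
        simulate_no_matrix(NOSimConfig(n_classes=1))
    with pytest.raises(ConfigError):
        simulate_no_matrix(NOSimConfig(n_genes=10, signature_size=40))


def test_cre_sim_carrier_ratio():
    cfg = CreSimConfig(n_cells=200, n_cres=150, carrier_fraction=0.5,
                       planted_windows=[("chrX", 500_000, 800_000, "H1", 0.5)],
                       seed=4)
    counts, cres, truth = simulate_cre_haplotype_counts(cfg)
    lab = pd.Series(truth.clone_labels)
    in_w = cres[(cres["start"] < 800_000) & (cres["end"] > 500_000)]["cre_id"]
    h1 = counts.xs("H1", axis=1, level="haplotype")[list(in_w)].sum(axis=1)
    h2 = counts.xs("H2", axis=1, level="haplotype")[list(in_w)].sum(axis=1)
    ratio = (h1 / h2)
    carrier_ratio = ratio[lab == "carrier"].mean()
    wt_ratio = ratio[lab == "wt"].mean()
    assert 0.35 < carrier_ratio / wt_ratio < 0.65


def test_cre_sim_rejects_empty_window():
    with pytest.raises(ConfigError):
        simulate_cre_haplotype_counts(CreSimConfig(
            planted_windows=[("chr9", 0, 1000, "H1", 0.5)]))


def test_expr_sim_dosage_one_is_flat():
    cfg = ExprSimConfig(n_cells=400, n_genes=100,
                        clones=[("c", ("chr17", 0, 500_000), 1.0, 0.5)],
                        seed=5)
    m, truth = simulate_expression(cfg)
    lab = pd.Series(truth.clone_labels)
    region = m.gene_meta[m.gene_meta["start"] < 500_000].index
    a = m.counts.loc[(lab == "c").values, region].mean().mean()
    b = m.counts.loc[(lab == "normal").values, region].mean().mean()
    assert abs(a / b - 1.0) < 0.1


def test_expr_sim_dosage_half_scales_region():
    cfg = ExprSimConfig(n_cells=600, n_genes=100,
                        clones=[("c", ("chr17", 0, 500_000), 0.5, 0.5)],
                        seed=6)
    m, truth = simulate_expression(cfg)
    lab = pd.Series(truth.clone_labels)
    region = m.gene_meta[m.gene_meta["start"] < 500_000].index
    outside = m.gene_meta[m.gene_meta["start"] >= 500_000].index
    a = m.counts.loc[(lab == "c").values, region].mean().mean()
    b = m.counts.loc[(lab == "normal").values, region].mean().mean()
    assert 0.4 < a / b < 0.6
    a2 = m.counts.loc[(lab == "c").values, outside].mean().mean()
    b2 = m.counts.loc[(lab == "normal").values, outside].mean().mean()
    assert 0.9 < a2 / b2 < 1.1


def test_expr_sim_rejects_fractions_beyond_one():
    with pytest.raises(ConfigError):
        simulate_expression(ExprSimConfig(
            clones=[("a", ("chr17", 0, 100), 0.5, 0.6),
                    ("b", ("chr17", 200, 300), 0.5, 0.6)]))
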