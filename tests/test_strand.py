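import numpy as np
import pandas as pd
import pytest

from scmosaic import (MosaicCall, SimConfig, StrandCountMatrix,
                      call_strand_states, classify_singleton_subclonal,
                      detect_sces, genotype_footprints, simulate_strand_cells)
from scmosaic.strand import _footprints, genotype_cell


def _matrix_from_fractions(wfracs, reads_per_bin=40, chrom="chr1"):
    n = len(wfracs)
    bins = pd.DataFrame({"chrom": chrom, "start": np.arange(n) * 100_000,
                         "end": (np.arange(n) + 1) * 100_000})
    w = np.round(np.array(wfracs) * reads_per_bin).astype(float)[None, :]
    c = reads_per_bin - w
    return StrandCountMatrix(bins=bins, cells=["cellA"], W=w, C=c)


def test_single_state_chromosome_one_segment():
    m = _matrix_from_fractions([1.0] * 20)
    segs = call_strand_states(m)
    assert len(segs) == 1 and segs[0].state == "WW"
    assert segs[0].start == 0 and segs[0].end == 2_000_000


def test_wc_state_called():
    m = _matrix_from_fractions([0.5] * 20)
    segs = call_strand_states(m)
    assert len(segs) == 1 and segs[0].state == "WC"


def test_clean_changepoint_two_segments():
    m = _matrix_from_fractions([1.0] * 10 + [0.5] * 10)
    segs = call_strand_states(m)
    assert [s.state for s in segs] == ["WW", "WC"]
    assert segs[0].end == segs[1].start == 1_000_000


def test_min_bins_merges_short_segment():
    # a 1-bin blip cannot form its own segment at min_bins=3
    m = _matrix_from_fractions([1.0] * 9 + [0.5] + [1.0] * 10)
    segs = call_strand_states(m, min_bins=3)
    assert all(s.n_bins >= 3 for s in segs)


def test_low_coverage_unknown():
    m = _matrix_from_fractions([1.0] * 10, reads_per_bin=1)
    segs = call_strand_states(m, min_reads_per_chrom=20)
    assert len(segs) == 1 and segs[0].state == "unknown"


def test_detect_sces_single_flip_and_ci():
    m = _matrix_from_fractions([1.0] * 10 + [0.5] * 10)
    res = detect_sces(call_strand_states(m))
    assert len(res.calls) == 1
    call = res.calls[0]
    assert (call.ci_start, call.ci_end) == (999_999, 1_000_001)
    assert call.flipped in {"W->C", "C->W"}


def test_detect_sces_ww_cc_jump_is_msv_candidate():
    m = _matrix_from_fractions([1.0] * 10 + [0.0] * 10)
    res = detect_sces(call_strand_states(m))
    assert len(res.calls) == 0
    assert len(res.msv_candidates) == 1


def test_detect_sces_two_changepoints_reviewed():
    m = _matrix_from_fractions([1.0] * 8 + [0.5] * 8 + [1.0] * 8)
    res = detect_sces(call_strand_states(m))
    assert res.review == [("cellA", "chr1", 2)]


def test_footprints_reference_and_del():
    fp = _footprints("WC")
    assert fp[("ref", "-")] == (1.0, 1.0)
    assert fp[("del", "W-homolog")] == (0.0, 1.0)
    assert fp[("del", "C-homolog")] == (1.0, 0.0)
    fp_ww = _footprints("WW")
    assert fp_ww[("ref", "-")] == (2.0, 0.0)
    # inv in a WW ground moves one copy from W to C
    assert fp_ww[("inv", "ambiguous")] == (1.0, 1.0)


def test_genotype_cell_calls_del_and_ref():
    # WC ground, per-copy 100: ref expects (100, 100)
    cls, hap, post = genotype_cell(100, 100, 100.0, "WC")
    assert cls == "ref"
    cls, hap, post = genotype_cell(2, 100, 100.0, "WC")
    assert cls == "del" and hap == "W-homolog"
    assert post[("del", "W-homolog")] > 0.99


def test_genotype_cell_tie_prefers_reference():
    # zero depth: all hypotheses equally bad -> conservative ref call
    cls, _, _ = genotype_cell(0, 0, 0.0, "WC")
    assert cls == "ref"


def test_classify_singleton_subclonal_and_cf_percent():
    calls = [
        MosaicCall("e1", "del", "chr1", 0, 10, "ambiguous",
                   ["c1"], 43),
        MosaicCall("e2", "dup", "chr1", 0, 10, "ambiguous",
                   [f"c{i}" for i in range(19)], 84),
        MosaicCall("e3", "inv", "chr1", 0, 10, "ambiguous", [], 10),
    ]
    with pytest.warns(UserWarning):
        out = classify_singleton_subclonal(calls)
    assert [c.event_id for c in out] == ["e1", "e2"]
    assert out[0].status == "singleton" and out[0].cf_percent == 2.3
    assert out[1].status == "subclonal" and out[1].cf_percent == 22.6


def test_genotype_footprints_recovers_planted_del():
    cfg = SimConfig(genome=[("chr1", 20_000_000), ("chr2", 20_000_000)],
                    n_cells=60, reads_per_cell=40_000.0, sce_rate=0.0,
                    msv_events=[("del", "chr1", 5_000_000, 15_000_000,
                                 "H1", 0.3)], seed=13)
    m, truth = simulate_strand_cells(cfg)
    segs = call_strand_states(m)
    calls = genotype_footprints(
        m, segs, [{"chrom": "chr1", "start": 5_000_000, "end": 15_000_000,
                   "id": "cand"}])
    assert len(calls) == 1
    call = calls[0]
    assert call.svclass == "del"
    true_carriers = set(truth.msv_carriers["msv_0"])
    assert set(call.carriers) == true_carriers
    assert abs(call.cell_fraction - len(true_carriers) / 60) < 1e-9


def test_matrix_roundtrip(tmp_path):
    cfg = SimConfig(genome=[("chr1", 3_000_000)], n_cells=3,
                    reads_per_cell=1000.0, seed=1)
    m, _ = simulate_strand_cells(cfg)
    m.write_tsv(tmp_path / "w.tsv.gz", tmp_path / "c.tsv.gz")
    m2 = StrandCountMatrix.read_tsv(tmp_path / "w.tsv.gz", tmp_path / "c.tsv.gz")
    assert (m2.W == m.W).all() and (m2.C == m.C).all()
    pd.testing.assert_frame_equal(m2.bins, m.bins)
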