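import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scmosaic import (ExpressionMatrix, ExprSimConfig, assign_clones,
                      clone_cell_fraction, clone_celltype_fisher,
                      clone_cooccurrence, fit_two_component,
                      flag_bimodal_regions, normalize_expression,
                      region_mixture_test, simulate_expression)


@pytest.fixture(scope="module")
def planted_cna():
    cfg = ExprSimConfig(n_cells=800, n_genes=500,
                        clones=[("loss", ("chr17", 0, 1_200_000), 0.5, 0.4)],
                        seed=21)
    m, truth = simulate_expression(cfg)
    return m, truth


def test_normalize_expression_formula():
    counts = pd.DataFrame({"g1": [10], "g2": [90]}, index=["c"])
    norm = normalize_expression(ExpressionMatrix(counts=counts))
    cpm1 = 10 / 100 * 1e6
    assert norm.loc["c", "g1"] == pytest.approx(np.log2(cpm1 / 10 + 1))


def test_normalize_rejects_empty_cells():
    counts = pd.DataFrame({"g1": [0], "g2": [0]}, index=["c"])
    with pytest.raises(ValueError):
        normalize_expression(ExpressionMatrix(counts=counts))


def test_em_loglik_monotone_and_converged():
    rng = np.random.default_rng(0)
    x = np.concatenate([rng.normal(-1, 0.5, 300), rng.normal(1, 0.5, 200)])
    fit = fit_two_component(x, seed=1)
    trace = np.asarray(fit.ll_trace)
    assert (np.diff(trace) >= -1e-8).all()
    assert fit.converged
    assert fit.means[0] < fit.means[1]
    assert fit.means[0] == pytest.approx(-1, abs=0.15)
    assert fit.means[1] == pytest.approx(1, abs=0.15)
    assert fit.weight == pytest.approx(0.6, abs=0.05)


def test_em_pooled_variance_shared():
    rng = np.random.default_rng(1)
    x = np.concatenate([rng.normal(-1, 0.5, 200), rng.normal(1, 0.5, 200)])
    fit = fit_two_component(x, seed=0, variance_mode="pooled")
    assert fit.variances[0] == pytest.approx(fit.variances[1])
    free = fit_two_component(x, seed=0, variance_mode="free")
    # free mode may differ per component but both stay positive
    assert (np.asarray(free.variances) > 0).all()


def test_em_pooled_posterior_monotone_in_score():
    rng = np.random.default_rng(2)
    x = np.concatenate([rng.normal(-1, 0.7, 300), rng.normal(1, 0.4, 300)])
    fit = fit_two_component(x, seed=0, variance_mode="pooled")
    grid = np.linspace(x.min(), x.max(), 200)
    post_low = fit.responsibilities(grid)
    # with a shared variance, P(lower component | score) decreases in score
    assert (np.diff(post_low) <= 1e-9).all()


def test_region_skipped_below_min_genes(planted_cna):
    m, _ = planted_cna
    norm = normalize_expression(m)
    genes = list(m.counts.columns[:4])
    fit = region_mixture_test(norm, genes, region_id="tiny", counts=m.counts)
    assert fit.skipped is not None
    assert np.isnan(fit.lrt_p)
    with pytest.raises(ValueError):
        assign_clones(fit, dosage=0.5)


def test_unexpressed_genes_do_not_count(planted_cna):
    m, _ = planted_cna
    counts = m.counts.copy()
    ghost = [f"ghost_{i}" for i in range(3)]
    for g in ghost:
        counts[g] = 0
    m2 = ExpressionMatrix(counts=counts)
    norm = normalize_expression(m2)
    genes = list(m.counts.columns[:2]) + ghost  # 2 expressed + 3 silent
    fit = region_mixture_test(norm, genes, region_id="r", counts=counts)
    assert fit.n_expressed == 2
    assert fit.skipped is not None


def test_planted_clone_recovered(planted_cna):
    m, truth = planted_cna
    norm = normalize_expression(m)
    region = m.gene_meta[m.gene_meta["start"] < 1_200_000].index.tolist()
    fit = region_mixture_test(norm, region, region_id="loss",
                              counts=m.counts, seed=0)
    flag_bimodal_regions([fit])
    assert fit.bimodal
    assert fit.bic2 < fit.bic1
    a = assign_clones(fit, dosage=0.5)
    lab = pd.Series(truth.clone_labels)
    assigned = a[a["assignment"] != "unassigned"]
    pred = np.where(assigned["assignment"] == "CNA", "loss", "normal")
    acc = (pred == lab.loc[assigned.index].to_numpy()).mean()
    assert acc >= 0.9
    assert abs(clone_cell_fraction(a) - 0.4) <= 0.07


def test_flag_bimodal_gaussian_null_not_flagged():
    # under the model's own assumption (Gaussian scores) the LRT is
    # calibrated and a unimodal region is not flagged
    rng = np.random.default_rng(7)
    norm = pd.DataFrame(rng.normal(5, 1, size=(500, 30)),
                        index=[f"c{i}" for i in range(500)],
                        columns=[f"g{i}" for i in range(30)])
    fit = region_mixture_test(norm, list(norm.columns), region_id="null",
                              seed=1)
    flag_bimodal_regions([fit])
    assert not fit.bimodal
    assert fit.lrt_p > 0.01
    assert fit.bic1 < fit.bic2


def test_clone_celltype_fisher():
    in_clone = pd.Series([True] * 20 + [False] * 80)
    types = pd.Series(["HSC"] * 25 + ["MPP"] * 75)
    out = clone_celltype_fisher(in_clone, types)
    row = out.set_index("cell_type").loc["HSC"]
    table = [[20, 0], [5, 75]]
    odds, p = stats.fisher_exact(table)
    assert row["p"] == pytest.approx(p)
    assert bool(row["enriched"])


def test_clone_cooccurrence_counts():
    assignments = pd.DataFrame(
        {"r1": ["CNA", "CNA", "normal", "unassigned"],
         "r2": ["CNA", "normal", "normal", "CNA"]}, index=list("wxyz"))
    out = clone_cooccurrence(assignments)
    both = out[(out["region_a"] == "r1") & (out["region_b"] == "r2")].iloc[0]
    # z is unassigned in r1 and excluded from the pair
    assert both["n_both_assigned"] == 3
    # of the 2 r1-CNA cells, 1 is also r2-CNA
    assert both["p_b_given_a"] == pytest.approx(0.5)
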