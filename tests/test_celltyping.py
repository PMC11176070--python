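import numpy as np
import pandas as pd
import pytest

from scmosaic import (NOMatrix, NOSimConfig, loocv_auc, normalize_no,
                      select_features_stage1, select_features_stage2,
                      simulate_no_matrix, train_classifier, vip_scores)
from scmosaic.celltyping import (_fit_pls, _one_hot, classifier_from_dict,
                                 classifier_to_dict, differential_gene_activity,
                                 infer_gene_activity)


@pytest.fixture(scope="module")
def easy_ref():
    """Small, strongly separated reference (effect 2.0)."""
    m, truth = simulate_no_matrix(NOSimConfig(
        n_classes=5, n_cells=150, n_genes=300, signature_size=15,
        effect=2.0, seed=7))
    return m, truth, pd.Series(truth.celltype_labels)


def test_nomatrix_rejects_negative():
    with pytest.raises(ValueError):
        NOMatrix(counts=pd.DataFrame({"g": [-1]}, index=["c"]))


def test_normalize_no_train_params_reused():
    counts = pd.DataFrame(np.arange(12, dtype=float).reshape(3, 4),
                          index=list("abc"), columns=list("wxyz"))
    z = normalize_no(NOMatrix(counts=counts))
    # training normalization: zero mean, unit sd per gene
    assert np.allclose(z.values.mean(axis=0), 0, atol=1e-12)
    assert np.allclose(z.values.std(axis=0, ddof=1), 1)
    # applying stored params to new cells must not recompute statistics
    z2 = normalize_no(NOMatrix(counts=counts.iloc[:1]),
                      params=(z.gene_mean, z.gene_sd))
    assert np.allclose(z2.values.to_numpy(), z.values.iloc[:1].to_numpy())


def test_one_hot_columns_sorted():
    oh = _one_hot(pd.Series(["b", "a", "b"]))
    assert list(oh.columns) == ["a", "b"]
    assert (oh.sum(axis=1) == 1).all()


def test_vip_mean_square_is_one():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(50, 30))
    Y = rng.normal(size=(50, 3))
    vip = vip_scores(_fit_pls(X, Y, 2))
    # the standard VIP normalization: mean of squared VIPs equals 1
    assert np.isclose((vip ** 2).mean(), 1.0, atol=1e-8)
    assert (vip >= 0).all()


def test_stage1_null_calibration():
    # labels independent of X: the 90th-percentile threshold retains ~10%
    rng = np.random.default_rng(1)
    counts = pd.DataFrame(rng.poisson(20, size=(60, 200)).astype(float),
                          index=[f"c{i}" for i in range(60)],
                          columns=[f"g{i}" for i in range(200)])
    labels = pd.Series(rng.choice(["a", "b", "c"], 60), index=counts.index)
    z = normalize_no(NOMatrix(counts=counts))
    sel = select_features_stage1(z, labels, n_perm=20, seed=1)
    frac = len(sel.selected_genes) / 200
    assert 0.03 < frac < 0.2


def test_two_stage_recovers_planted_signature(easy_ref):
    m, truth, labels = easy_ref
    z = normalize_no(m)
    s1 = select_features_stage1(z, labels, n_perm=10, seed=2)
    per_class, signature = select_features_stage2(z, labels,
                                                  s1.selected_genes,
                                                  n_perm=10, seed=2)
    planted = {g for genes in truth.signature_genes.values() for g in genes}
    recovered = len(planted & set(signature)) / len(planted)
    assert recovered >= 0.8
    # everything selected at this effect size is a true signature gene
    assert set(signature) <= planted
    assert set(signature) <= set(s1.selected_genes)
    assert set(per_class) == set(labels.unique())


def test_classifier_accuracy_and_probabilities(easy_ref):
    m, truth, labels = easy_ref
    planted = [g for genes in truth.signature_genes.values() for g in genes]
    clf = train_classifier(m, labels, planted)
    post = clf.classify(m)
    acc = (post["assigned"] == labels.loc[post.index]).mean()
    assert acc >= 0.95
    proba = post[clf.classes].to_numpy()
    assert np.allclose(proba.sum(axis=1), 1)
    assert (proba >= 0).all()


def test_classifier_json_roundtrip(easy_ref):
    m, truth, labels = easy_ref
    planted = [g for genes in truth.signature_genes.values() for g in genes]
    clf = train_classifier(m, labels, planted)
    clf2 = classifier_from_dict(classifier_to_dict(clf))
    a = clf.decision_scores(m).to_numpy()
    b = clf2.decision_scores(m).to_numpy()
    assert np.allclose(a, b, atol=1e-12)


def test_loocv_auc_high_on_separable(easy_ref):
    m, truth, labels = easy_ref
    planted = [g for genes in truth.signature_genes.values() for g in genes]
    auc = loocv_auc(m, labels, planted)
    assert auc.mean() > 0.95


def test_infer_gene_activity_is_negated_z():
    z = pd.DataFrame([[1.0, -2.0]], columns=["a", "b"])
    act = infer_gene_activity(z)
    assert (act.to_numpy() == -z.to_numpy()).all()


def test_diffno_masked_region_flagged(easy_ref):
    m, truth, labels = easy_ref
    rng = np.random.default_rng(3)
    genotype = pd.Series(rng.choice(["mutant", "wt"], len(labels)),
                         index=labels.index)
    gene_meta = pd.DataFrame({
        "chrom": "chr1",
        "start": np.arange(len(m.genes)) * 10_000,
        "end": (np.arange(len(m.genes)) + 1) * 10_000}, index=m.genes)
    m2 = NOMatrix(counts=m.counts, gene_meta=gene_meta)
    res = differential_gene_activity(m2, genotype, celltype=labels,
                                     masked_region=("chr1", 0, 50_000),
                                     n_perm=20, seed=3)
    masked = res[res["masked"]]
    assert len(masked) == 5
    assert masked["q"].isna().all()
    # null genotype: essentially nothing significant outside the mask
    assert res["significant"].fillna(False).mean() < 0.2
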