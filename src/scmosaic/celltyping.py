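"""Nucleosome-occupancy (NO) cell typing and differential gene activity.

MNase-protected fragment density over gene bodies is inversely related to
chromatin accessibility, so cell types leave characteristic NO signatures.
This module normalizes per-cell gene-body fragment counts (reads-per-million,
log2, per-gene Z-score), selects signature genes by a two-stage partial
least squares discriminant analysis (PLS-DA) with permutation-calibrated
variance-importance-in-projection (VIP) thresholds, trains a PLS-DA
classifier, scores it by leave-one-out cross-validation, converts NO
Z-scores to inferred gene activity (activity = -Z), and tests differential
gene activity between genotype groups with the predicted cell type regressed
out as a confounder.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests


@dataclass
class NOMatrix:
    """Cells x genes NO fragment counts with optional labels and gene metadata."""

    counts: pd.DataFrame
    labels: pd.Series | None = None
    gene_meta: pd.DataFrame | None = None   # index gene, columns chrom/start/end

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.labels is not None and not self.labels.index.equals(self.counts.index):
            raise ValueError("labels index must match cells")

    @property
    def cells(self):
        return list(self.counts.index)

    @property
    def genes(self):
        return list(self.counts.columns)

    @property
    def library_size(self) -> pd.Series:
        return self.counts.sum(axis=1)


@dataclass
class NormalizedNOMatrix:
    """Standardized log2-RPM values with the normalization parameters used.

    ``gene_mean``/``gene_sd`` are the training statistics; applying them to
    new cells (rather than recomputing) keeps train/test hygiene.
    """

    values: pd.DataFrame
    gene_mean: pd.Series
    gene_sd: pd.Series


def normalize_no(m: NOMatrix, params: tuple[pd.Series, pd.Series] | None = None,
                 pseudocount: float = 1.0) -> NormalizedNOMatrix:
    """standardize(log2(RPM + pseudocount)) per gene.

    With ``params=(mean, sd)`` the given statistics are applied (prediction
    path); otherwise they are computed from ``m`` (training path). Genes with
    zero variance standardize to all-zero columns.
    """
    lib = m.counts.sum(axis=1).astype(float)
    if (lib == 0).any():
        raise ValueError("cells with zero library size cannot be normalized")
    rpm = m.counts.div(lib, axis=0) * 1e6
    logv = np.log2(rpm + pseudocount)
    if params is None:
        mean = logv.mean(axis=0)
        sd = logv.std(axis=0, ddof=1).fillna(0.0)
    else:
        mean, sd = params
        logv = logv[mean.index]
    safe_sd = sd.replace(0.0, np.inf)   # constant genes -> zeros, not NaN
    z = (logv - mean) / safe_sd
    return NormalizedNOMatrix(values=z, gene_mean=mean, gene_sd=sd)


def _one_hot(labels: pd.Series) -> pd.DataFrame:
    return pd.get_dummies(labels).astype(float)


def _fit_pls(X: np.ndarray, Y: np.ndarray, n_components: int) -> PLSRegression:
    n_components = max(1, min(n_components, X.shape[1], X.shape[0] - 1))
    pls = PLSRegression(n_components=n_components, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls.fit(X, Y)
    return pls


def vip_scores(pls: PLSRegression) -> np.ndarray:
    """Standard PLS VIP: per-feature weighted sum of squared, normalized
    loading weights, weighted by the Y-variance each component explains."""
    T = pls.x_scores_
    W = pls.x_weights_
    Q = pls.y_loadings_
    ssy = (T ** 2).sum(axis=0) * (Q ** 2).sum(axis=0)
    wn = (W / np.maximum(np.linalg.norm(W, axis=0), 1e-12)) ** 2
    p = W.shape[0]
    return np.sqrt(p * (wn @ ssy) / max(ssy.sum(), 1e-12))


@dataclass
class FeatureSelection:
    scores: pd.DataFrame          # gene, vip, selected, stage, class
    threshold: float
    null_vips: np.ndarray

    @property
    def selected_genes(self) -> list[str]:
        return list(self.scores.loc[self.scores["selected"], "gene"])


def _permuted_null(X: np.ndarray, Y: np.ndarray, n_components: int,
                   n_perm: int, rng) -> np.ndarray:
    """Pool VIPs from label-permuted refits into one null distribution."""
    pool = []
    for _ in range(n_perm):
        Yp = Y[rng.permutation(len(Y))]
        pool.append(vip_scores(_fit_pls(X, Yp, n_components)))
    return np.concatenate(pool)


def select_features_stage1(X: NormalizedNOMatrix, labels: pd.Series,
                           n_perm: int = 20, seed: int = 0,
                           quantile: float = 0.90,
                           n_components: int | None = None) -> FeatureSelection:
    """Multi-class VIP selection: keep genes above the 90th null percentile.

    The null distribution pools VIPs over ``n_perm`` label-permuted refits
    of the same PLS-DA. Zero-variance genes never pass (VIP 0).
    """
    if n_perm < 1:
        raise ValueError("null distribution requires permutations (n_perm >= 1)")
    rng = np.random.default_rng(seed)
    lab = labels.loc[X.values.index]
    Y = _one_hot(lab).to_numpy()
    variable = X.values.std(axis=0) > 0
    genes = X.values.columns[variable]
    Xv = X.values.loc[:, genes].to_numpy()
    k = n_components or min(Y.shape[1] - 1, 10)
    vip = vip_scores(_fit_pls(Xv, Y, k))
    null = _permuted_null(Xv, Y, k, n_perm, rng)
    thr = float(np.quantile(null, quantile))
    scores = pd.DataFrame({"gene": genes, "vip": vip,
                           "selected": vip > thr, "stage": 1, "class": "-"})
    return FeatureSelection(scores, thr, null)


def select_features_stage2(X: NormalizedNOMatrix, labels: pd.Series,
                           stage1_genes: list[str], n_perm: int = 20,
                           seed: int = 0, quantile: float = 0.95,
                           n_components: int = 2) -> tuple[dict, list[str]]:
    """Per-class one-vs-rest VIP selection on the stage-1 gene set.

    For each class, a binary PLS-DA against class membership; genes above the
    95th null percentile are that class's markers. Returns the per-class
    FeatureSelection dict and the union signature list (in stage-1 order).
    """
    rng = np.random.default_rng(seed)
    lab = labels.loc[X.values.index]
    classes = sorted(lab.unique())
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    Xv = X.values.loc[:, stage1_genes].to_numpy()
    per_class = {}
    union: set[str] = set()
    for cls in classes:
        y = (lab == cls).to_numpy(float)[:, None]
        if y.sum() == 0:
            raise ValueError(f"class {cls!r} absent from labels")
        vip = vip_scores(_fit_pls(Xv, y, n_components))
        null = _permuted_null(Xv, y, n_components, n_perm, rng)
        thr = float(np.quantile(null, quantile))
        sel = vip > thr
        per_class[cls] = FeatureSelection(
            pd.DataFrame({"gene": stage1_genes, "vip": vip, "selected": sel,
                          "stage": 2, "class": cls}), thr, null)
        union |= {g for g, s in zip(stage1_genes, sel) if s}
    signature = [g for g in stage1_genes if g in union]
    return per_class, signature


@dataclass
class CellTypeClassifier:
    """PLS-DA classifier over a fixed signature gene set.

    Stores the training normalization parameters; prediction never uses
    test-set statistics.
    """

    signature: list[str]
    classes: list[str]
    pls: PLSRegression
    gene_mean: pd.Series
    gene_sd: pd.Series
    pseudocount: float = 1.0

    def _features(self, m: NOMatrix) -> np.ndarray:
        z = normalize_no(NOMatrix(counts=m.counts[self.signature]),
                         params=(self.gene_mean, self.gene_sd),
                         pseudocount=self.pseudocount)
        return z.values.to_numpy()

    def decision_scores(self, m: NOMatrix) -> pd.DataFrame:
        s = self.pls.predict(self._features(m))
        return pd.DataFrame(s, index=m.counts.index, columns=self.classes)

    def predict_proba(self, m: NOMatrix) -> pd.DataFrame:
        s = self.decision_scores(m).to_numpy()
        e = np.exp(s - s.max(axis=1, keepdims=True))
        return pd.DataFrame(e / e.sum(axis=1, keepdims=True),
                            index=m.counts.index, columns=self.classes)

    def classify(self, m: NOMatrix) -> pd.DataFrame:
        """CellTypePosterior table: per-class probability, argmax, margin."""
        proba = self.predict_proba(m)
        arr = proba.to_numpy()
        order = np.sort(arr, axis=1)
        ties = np.isclose(order[:, -1], order[:, -2])
        if ties.any():
            warnings.warn(f"{ties.sum()} cells with tied class scores; "
                          "assigned by class order", stacklevel=2)
        out = proba.copy()
        out["assigned"] = proba.idxmax(axis=1)
        out["margin"] = order[:, -1] - order[:, -2]
        return out


def train_classifier(m: NOMatrix, labels: pd.Series, signature: list[str],
                     n_components: int | None = None,
                     pseudocount: float = 1.0) -> CellTypeClassifier:
    """Fit a PLS-DA classifier on the signature genes.

    Latent components default to min(n_classes - 1, 10).
    """
    lab = labels.loc[m.counts.index]
    classes = sorted(lab.unique())
    z = normalize_no(NOMatrix(counts=m.counts[signature]), pseudocount=pseudocount)
    Y = _one_hot(lab)[classes].to_numpy()
    k = n_components or min(len(classes) - 1, 10)
    pls = _fit_pls(z.values.to_numpy(), Y, k)
    return CellTypeClassifier(signature=list(signature), classes=classes,
                              pls=pls, gene_mean=z.gene_mean, gene_sd=z.gene_sd,
                              pseudocount=pseudocount)


@dataclass
class _LinearPredictor:
    """Affine stand-in for a fitted PLS regressor (prediction only).

    PLS-DA prediction is linear in the features, so the coefficient matrix
    and intercept are all a trained classifier needs at inference time;
    storing them (instead of the full fit) keeps classifier files as plain
    JSON.
    """

    coef: np.ndarray        # (classes, genes)
    intercept: np.ndarray   # (classes,)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return X @ self.coef.T + self.intercept


def classifier_to_dict(clf: CellTypeClassifier) -> dict:
    """JSON-serializable representation of a trained classifier."""
    return {
        "signature": list(clf.signature),
        "classes": list(clf.classes),
        "gene_mean": clf.gene_mean.reindex(clf.signature).tolist(),
        "gene_sd": clf.gene_sd.reindex(clf.signature).tolist(),
        "pseudocount": clf.pseudocount,
        "coef": np.asarray(clf.pls.coef_).tolist(),
        "intercept": np.asarray(clf.pls.intercept_).tolist(),
    }


def classifier_from_dict(data: dict) -> CellTypeClassifier:
    """Rebuild a prediction-capable classifier from its JSON form."""
    signature = list(data["signature"])
    pls = _LinearPredictor(coef=np.asarray(data["coef"], dtype=float),
                           intercept=np.asarray(data["intercept"], dtype=float))
    return CellTypeClassifier(
        signature=signature, classes=list(data["classes"]), pls=pls,
        gene_mean=pd.Series(data["gene_mean"], index=signature),
        gene_sd=pd.Series(data["gene_sd"], index=signature),
        pseudocount=float(data.get("pseudocount", 1.0)))


def loocv_auc(m: NOMatrix, labels: pd.Series, signature: list[str],
              n_components: int | None = None) -> pd.Series:
    """Leave-one-out per-class one-vs-rest AUC.

    Each fold refits the classifier (and its normalization parameters) on
    the remaining cells; the signature gene set stays fixed across folds.
    Classes with a single cell get a missing AUC.
    """
    cells = list(m.counts.index)
    lab = labels.loc[cells]
    classes = sorted(lab.unique())
    scores = np.zeros((len(cells), len(classes)))
    for i, cell in enumerate(cells):
        rest = [c for c in cells if c != cell]
        clf = train_classifier(NOMatrix(counts=m.counts.loc[rest]),
                               lab.loc[rest], signature, n_components)
        proba = clf.predict_proba(NOMatrix(counts=m.counts.loc[[cell]]))
        scores[i] = proba.reindex(columns=classes).to_numpy()[0]
    out = {}
    for j, cls in enumerate(classes):
        y = (lab == cls).to_numpy()
        ok = 2 <= y.sum() <= len(y) - 1
        out[cls] = roc_auc_score(y, scores[:, j]) if ok else np.nan
    return pd.Series(out, name="auc")


def infer_gene_activity(z: pd.DataFrame | NormalizedNOMatrix) -> pd.DataFrame:
    """Gene activity inferred from NO: the Z-score multiplied by -1."""
    values = z.values if isinstance(z, NormalizedNOMatrix) else z
    return -values


def differential_gene_activity(m: NOMatrix, genotype: pd.Series,
                               celltype: pd.Series | None = None,
                               masked_region: tuple | None = None,
                               n_perm: int = 100, seed: int = 0,
                               fdr: float = 0.10) -> pd.DataFrame:
    """Differential NO between genotype groups, confounder-aware.

    Cell-type effects are regressed out gene-wise (per-type centering of the
    normalized NO values); the genotype contrast on the residuals is scored
    by a binary PLS-DA VIP per gene, with gene-level p-values from a pooled
    label-permutation null and BH correction. Direction is reported on the
    activity scale (activity = -Z), so higher NO in mutants means activity
    down. Genes overlapping ``masked_region`` (chrom, start, end) are flagged
    and excluded from testing.
    """
    geno = genotype.loc[m.counts.index]
    groups = sorted(geno.unique())
    if len(groups) != 2:
        raise ValueError("genotype must have exactly two groups")
    if min((geno == g).sum() for g in groups) < 3:
        raise ValueError("insufficient cells: each genotype group needs >= 3")
    rng = np.random.default_rng(seed)

    masked = pd.Series(False, index=m.counts.columns)
    if masked_region is not None:
        if m.gene_meta is None:
            raise ValueError("masking requires gene metadata")
        chrom, start, end = masked_region
        gm = m.gene_meta.reindex(m.counts.columns)
        masked = ((gm["chrom"] == chrom) & (gm["start"] < end)
                  & (gm["end"] > start)).fillna(False)

    z = normalize_no(m).values
    test_genes = [g for g in z.columns if not masked[g] and z[g].std() > 0]
    X = z[test_genes].to_numpy()
    # regress out cell type: subtract per-type gene means
    if celltype is not None:
        ct = celltype.loc[m.counts.index]
        for t in ct.unique():
            rows = (ct == t).to_numpy()
            X[rows] -= X[rows].mean(axis=0)
    else:
        X = X - X.mean(axis=0)

    y = (geno == groups[1]).to_numpy(float)[:, None]
    vip = vip_scores(_fit_pls(X, y, 2))
    null = _permuted_null(X, y, 2, n_perm, rng)
    # pooled-null gene-level p with +1 smoothing
    n_ge = len(null) - np.searchsorted(np.sort(null), vip, side="left")
    p = (1.0 + n_ge) / (len(null) + 1.0)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    mut_rows = (geno == groups[1]).to_numpy()
    delta_no = X[mut_rows].mean(axis=0) - X[~mut_rows].mean(axis=0)

    rows = pd.DataFrame({
        "gene": test_genes, "vip": vip, "p": p, "q": q,
        "delta_no": delta_no,
        "direction": np.where(delta_no > 0, "activity_down", "activity_up"),
        "significant": q < fdr, "masked": False,
    })
    masked_rows = pd.DataFrame({
        "gene": [g for g in z.columns if masked[g]],
        "vip": np.nan, "p": np.nan, "q": np.nan, "delta_no": np.nan,
        "direction": "-", "significant": False, "masked": True,
    })
    return pd.concat([rows, masked_rows], ignore_index=True)
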