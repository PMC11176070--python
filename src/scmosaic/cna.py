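"""Targeted CNA re-calling in single-cell expression data.

Copy-number alterations leave a dosage footprint on the mean expression of
the genes they cover. For each known candidate region, the per-cell mean of
normalized expression over the region's expressed genes is fit with a
one-component and a two-component Gaussian mixture; regions where the
two-component model wins (chi-squared LRT within a 1% FDR and a better BIC)
are called bimodal, and cells are assigned to the normal or CNA clone when
their posterior reaches 0.8. Regions with fewer than five expressed genes
are skipped. Clone/cell-type association uses BH-adjusted Fisher tests.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class ExpressionMatrix:
    """Cells x genes UMI counts with gene coordinates and cell metadata."""

    counts: pd.DataFrame
    gene_meta: pd.DataFrame | None = None    # index gene; chrom/start/end
    cell_meta: pd.DataFrame | None = None    # index cell; cell_type/donor/...

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")


def normalize_expression(m: ExpressionMatrix) -> pd.DataFrame:
    """Counts-per-million scaled to log2(CPM/10 + 1)."""
    lib = m.counts.sum(axis=1).astype(float)
    if (lib == 0).any():
        raise ValueError("cells with zero library size")
    cpm = m.counts.div(lib, axis=0) * 1e6
    return np.log2(cpm / 10.0 + 1.0)


# ---------------------------------------------------------------------------
# 1-D Gaussian mixtures with an explicit EM (log-likelihood trace exposed)

_VAR_FLOOR = 1e-8


def _gauss_logpdf(x, mu, var):
    return -0.5 * (np.log(2 * np.pi * var) + (x - mu) ** 2 / var)


@dataclass
class TwoComponentFit:
    weight: float          # weight of component 1 (lower mean)
    means: tuple[float, float]
    variances: tuple[float, float]
    loglik: float
    ll_trace: list = field(default_factory=list)
    converged: bool = True

    def responsibilities(self, x: np.ndarray) -> np.ndarray:
        """Posterior probability of component 1 (lower mean) per point."""
        l1 = np.log(self.weight) + _gauss_logpdf(x, self.means[0], self.variances[0])
        l2 = np.log1p(-self.weight) + _gauss_logpdf(x, self.means[1], self.variances[1])
        m = np.maximum(l1, l2)
        return np.exp(l1 - m) / (np.exp(l1 - m) + np.exp(l2 - m))


def fit_two_component(x: np.ndarray, n_restarts: int = 10, tol: float = 1e-6,
                      max_iter: int = 500, seed: int = 0,
                      variance_mode: str = "pooled") -> TwoComponentFit:
    """EM for a two-component 1-D Gaussian mixture, multiple seeded restarts.

    ``variance_mode="pooled"`` (default) constrains both components to a
    shared variance: with free variances the broader component's posterior
    is non-monotone in the score (extreme cells on BOTH sides get absorbed
    by it), which biases clone assignment. ``"free"`` fits separate
    variances. The returned fit carries its log-likelihood trace, which is
    non-decreasing by construction of EM.
    """
    if variance_mode not in ("pooled", "free"):
        raise ValueError("variance_mode must be 'pooled' or 'free'")
    rng = np.random.default_rng(seed)
    x = np.asarray(x, float)
    n = len(x)
    best: TwoComponentFit | None = None
    for r in range(n_restarts):
        if r == 0:
            mu1, mu2 = np.quantile(x, [0.25, 0.75])
        else:
            mu1, mu2 = np.sort(rng.choice(x, 2, replace=False))
        var1 = var2 = max(x.var() / 4.0, _VAR_FLOOR)
        w = 0.5
        trace = []
        converged = False
        for _ in range(max_iter):
            l1 = np.log(w) + _gauss_logpdf(x, mu1, var1)
            l2 = np.log1p(-w) + _gauss_logpdf(x, mu2, var2)
            m = np.maximum(l1, l2)
            ll = float(np.sum(m + np.log(np.exp(l1 - m) + np.exp(l2 - m))))
            if trace and ll - trace[-1] < tol:
                trace.append(ll)
                converged = True
                break
            trace.append(ll)
            g = np.exp(l1 - m) / (np.exp(l1 - m) + np.exp(l2 - m))
            s1, s2 = g.sum(), n - g.sum()
            if s1 < 1e-6 or s2 < 1e-6:
                break
            w = s1 / n
            mu1 = float((g * x).sum() / s1)
            mu2 = float(((1 - g) * x).sum() / s2)
            if variance_mode == "free":
                var1 = max(float((g * (x - mu1) ** 2).sum() / s1), _VAR_FLOOR)
                var2 = max(float(((1 - g) * (x - mu2) ** 2).sum() / s2), _VAR_FLOOR)
            else:
                pooled = float((g * (x - mu1) ** 2
                                + (1 - g) * (x - mu2) ** 2).sum() / n)
                var1 = var2 = max(pooled, _VAR_FLOOR)
        if mu1 > mu2:   # order components by mean
            mu1, mu2, var1, var2, w = mu2, mu1, var2, var1, 1 - w
        fit = TwoComponentFit(w, (mu1, mu2), (var1, var2), trace[-1], trace,
                              converged)
        if best is None or fit.loglik > best.loglik:
            best = fit
    return best


@dataclass
class MixtureFit:
    """Mixture evidence for one candidate CNA region."""

    region_id: str
    n_expressed: int
    scores: pd.Series | None          # per-cell region score (z-scaled)
    covered: pd.Series | None         # per-cell: any region-gene count > 0
    ll1: float = np.nan
    ll2: float = np.nan
    bic1: float = np.nan
    bic2: float = np.nan
    lrt_p: float = np.nan
    q: float = np.nan
    bimodal: bool = False
    skipped: str | None = None
    two_comp: TwoComponentFit | None = None


def region_mixture_test(normalized: pd.DataFrame, region_genes: list[str],
                        region_id: str = "region", min_genes: int = 5,
                        counts: pd.DataFrame | None = None,
                        seed: int = 0,
                        variance_mode: str = "pooled") -> MixtureFit:
    """Fit 1- vs 2-component mixtures to the per-cell region score.

    ``region_genes`` are the genes inside the candidate region; only genes
    expressed somewhere in the dataset count toward ``min_genes`` (regions
    below it are skipped, reason recorded). The per-cell score is the mean
    normalized expression over expressed region genes, z-scaled across
    cells. FDR and the bimodal flag are applied afterwards across regions
    (:func:`flag_bimodal_regions`).
    """
    present = [g for g in region_genes if g in normalized.columns]
    expressed = [g for g in present if normalized[g].sum() > 0]
    if len(expressed) < min_genes:
        return MixtureFit(region_id, len(expressed), None, None,
                          skipped=f"only {len(expressed)} expressed genes "
                                  f"(need >= {min_genes})")
    raw = normalized[expressed].mean(axis=1)
    sd = raw.std(ddof=1)
    score = (raw - raw.mean()) / (sd if sd > 0 else 1.0)
    if counts is not None:
        covered = counts[expressed].sum(axis=1) > 0
    else:
        covered = pd.Series(True, index=normalized.index)

    x = score.to_numpy()
    n = len(x)
    mu, var = x.mean(), max(x.var(), _VAR_FLOOR)
    ll1 = float(_gauss_logpdf(x, mu, var).sum())
    two = fit_two_component(x, seed=seed, variance_mode=variance_mode)
    ll2 = two.loglik
    k2 = 5 if variance_mode == "free" else 4
    bic1 = -2 * ll1 + 2 * np.log(n)
    bic2 = -2 * ll2 + k2 * np.log(n)
    lrt = max(0.0, 2 * (ll2 - ll1))
    p = float(stats.chi2.sf(lrt, df=k2 - 2))
    return MixtureFit(region_id, len(expressed), score, covered,
                      ll1, ll2, bic1, bic2, p, two_comp=two)


def flag_bimodal_regions(fits: list[MixtureFit], fdr: float = 0.01,
                         require_bic: bool = True) -> list[MixtureFit]:
    """BH across tested regions; bimodal at q < fdr (and BIC preference)."""
    tested = [f for f in fits if f.skipped is None]
    if tested:
        _, qs, _, _ = multipletests([f.lrt_p for f in tested], method="fdr_bh")
        for f, q in zip(tested, qs):
            f.q = float(q)
            f.bimodal = (q < fdr) and (f.bic2 < f.bic1 or not require_bic)
    return fits


def assign_clones(fit: MixtureFit, dosage: float,
                  posterior_cutoff: float = 0.8) -> pd.DataFrame:
    """Per-cell clone assignment from the two-component responsibilities.

    ``dosage`` declares which component carries the CNA: the lower-mean one
    for losses (dosage < 1), the higher-mean one for gains (> 1). Cells are
    ``CNA``/``normal`` when the respective posterior reaches the cutoff,
    otherwise ``unassigned``; cells with zero region coverage are unassigned
    and excluded from the cell-fraction denominator.
    """
    if fit.scores is None:
        raise ValueError(f"region {fit.region_id} was skipped: {fit.skipped}")
    if dosage == 1.0:
        raise ValueError("dosage direction required to orient the CNA clone")
    post_low = fit.two_comp.responsibilities(fit.scores.to_numpy())
    post_cna = post_low if dosage < 1.0 else 1.0 - post_low
    assignment = np.where(post_cna >= posterior_cutoff, "CNA",
                          np.where(1.0 - post_cna >= posterior_cutoff,
                                   "normal", "unassigned"))
    assignment = np.where(fit.covered.to_numpy(), assignment, "unassigned")
    return pd.DataFrame({"cell": fit.scores.index, "posterior_cna": post_cna,
                         "assignment": assignment}).set_index("cell")


def clone_cell_fraction(assignments: pd.DataFrame) -> float:
    """CF among assigned cells: CNA / (CNA + normal)."""
    a = assignments["assignment"]
    n_assigned = int((a != "unassigned").sum())
    if n_assigned == 0:
        return float("nan")
    return float((a == "CNA").sum() / n_assigned)


def clone_celltype_fisher(in_clone: pd.Series, cell_types: pd.Series,
                          fdr: float = 0.05) -> pd.DataFrame:
    """Per-type 2x2 Fisher exact test (in clone vs not x is type vs not)."""
    ct = cell_types.loc[in_clone.index]
    rows = []
    for t in sorted(ct.unique()):
        a = int((in_clone & (ct == t)).sum())
        b = int((in_clone & (ct != t)).sum())
        c = int((~in_clone & (ct == t)).sum())
        d = int((~in_clone & (ct != t)).sum())
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append({"cell_type": t, "in_clone": a, "odds_ratio": odds, "p": p})
    out = pd.DataFrame(rows)
    _, q, _, _ = multipletests(out["p"], method="fdr_bh")
    out["q"] = q
    out["enriched"] = (q < fdr) & (out["odds_ratio"] > 1)
    return out


def clone_cooccurrence(assignments: pd.DataFrame) -> pd.DataFrame:
    """Pairwise association between clone assignments across regions.

    ``assignments`` is cells x regions with values normal/CNA/unassigned.
    For each region pair, a Fisher test among doubly-assigned cells plus the
    nested-clone consistency score P(B carrier | A carrier).
    """
    regions = list(assignments.columns)
    rows = []
    for i in range(len(regions)):
        for j in range(len(regions)):
            if i == j:
                continue
            a, b = regions[i], regions[j]
            sub = assignments[(assignments[a] != "unassigned")
                              & (assignments[b] != "unassigned")]
            ca = sub[a] == "CNA"
            cb = sub[b] == "CNA"
            table = [[int((ca & cb).sum()), int((ca & ~cb).sum())],
                     [int((~ca & cb).sum()), int((~ca & ~cb).sum())]]
            odds, p = stats.fisher_exact(table)
            cond = float((ca & cb).sum() / ca.sum()) if ca.sum() else np.nan
            rows.append({"region_a": a, "region_b": b, "n_both_assigned": len(sub),
                         "odds_ratio": odds, "p": p,
                         "p_b_given_a": cond})
    return pd.DataFrame(rows)
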