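"""Haplotype-specific nucleosome occupancy in sliding windows at CREs.

A balanced rearrangement can rewire regulation in cis on one haplotype only.
The signal is the per-cell ratio of haplotype-1 to haplotype-2 NO summed
over the cis-regulatory elements in a window (300 kb wide, advancing 10 kb),
compared between rearrangement carriers and wild-type cells by a Gaussian
likelihood-ratio test on log ratios. Multiple testing is controlled by
shuffling genotype labels: the adjusted p of a window is the fraction of
label permutations with an equal or lower nominal p. Significant windows are
annotated with the nearest gene inside the same TAD.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def make_windows(region: tuple[str, int, int], size: int = 300_000,
                 step: int = 10_000) -> pd.DataFrame:
    """Sliding windows over a half-open region.

    Windows start at ``start, start+step, ...`` while they fit inside the
    region; a region shorter than one window yields a single clipped window.
    ``step > size`` leaves gaps (logged, allowed).
    """
    chrom, start, end = region
    if step > size:
        logger.warning("step %d > size %d: windows leave gaps", step, size)
    if end - start <= size:
        return pd.DataFrame({"chrom": [chrom], "start": [start], "end": [min(end, start + size)]})
    starts = np.arange(start, end - size + 1, step, dtype=np.int64)
    return pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + size})


def window_log_ratios(counts: pd.DataFrame, cres: pd.DataFrame,
                      windows: pd.DataFrame, numerator: str = "H1",
                      pseudocount: float = 0.5,
                      min_cres: int = 3) -> pd.DataFrame:
    """Per-cell log2 haplotype NO ratio for every testable window.

    ``counts`` has a (cre_id, haplotype) column MultiIndex; values are first
    scaled to reads per million per cell (making results invariant to
    per-cell library size), then summed over the CREs of each window per
    haplotype; ``pseudocount`` guards zero denominators. Windows with fewer
    than ``min_cres`` covered CREs are dropped.
    """
    denominator = "H2" if numerator == "H1" else "H1"
    lib = counts.sum(axis=1).astype(float)
    if (lib == 0).any():
        raise ValueError("cells with zero total CRE coverage")
    rpm = counts.div(lib, axis=0) * 1e6
    num = rpm.xs(numerator, axis=1, level="haplotype")
    den = rpm.xs(denominator, axis=1, level="haplotype")
    covered = counts.T.groupby(level="cre_id").sum().T > 0  # cell x cre any-hap

    cols = {}
    for i, w in windows.iterrows():
        in_w = ((cres["chrom"] == w["chrom"]) & (cres["start"] < w["end"])
                & (cres["end"] > w["start"]))
        ids = [c for c in cres.loc[in_w, "cre_id"] if c in num.columns]
        if len(ids) == 0:
            continue
        n_cov = covered[ids].any(axis=0).sum()
        if n_cov < min_cres:
            continue
        cols[i] = np.log2((num[ids].sum(axis=1) + pseudocount)
                          / (den[ids].sum(axis=1) + pseudocount))
    return pd.DataFrame(cols)


def _lrt_columns(R: np.ndarray, is_mut: np.ndarray):
    """Vectorized 1-df Gaussian LRT (equal vs separate means, shared
    variance) per column of R. Returns (log2fc, p)."""
    n = R.shape[0]
    mu_all = R.mean(axis=0)
    var0 = ((R - mu_all) ** 2).mean(axis=0)
    mu_m = R[is_mut].mean(axis=0)
    mu_w = R[~is_mut].mean(axis=0)
    resid = np.where(is_mut[:, None], R - mu_m, R - mu_w)
    var1 = (resid ** 2).mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = n * np.log(np.maximum(var0, 1e-300) / np.maximum(var1, 1e-300))
    stat = np.clip(stat, 0.0, None)
    return mu_m - mu_w, stats.chi2.sf(stat, df=1)


def window_lrt(R: pd.DataFrame, genotype: pd.Series) -> pd.DataFrame:
    """Nominal LRT per window.

    ``R`` is the cells x windows log2-ratio matrix from
    :func:`window_log_ratios`; ``genotype`` maps cells to "mutant"/"wt".
    log2FC is mutant minus wild-type mean of the log2 haplotype NO ratio.
    """
    geno = genotype.loc[R.index]
    is_mut = (geno == "mutant").to_numpy()
    if is_mut.sum() < 2 or (~is_mut).sum() < 2:
        raise ValueError("insufficient cells: need >= 2 per genotype group")
    fc, p = _lrt_columns(R.to_numpy(), is_mut)
    return pd.DataFrame({"window": R.columns, "log2fc": fc, "p_nominal": p})


def window_permutation_fdr(R: pd.DataFrame, genotype: pd.Series,
                           n_perm: int = 1000, seed: int = 0,
                           threshold: float = 0.1) -> pd.DataFrame:
    """Label-permutation adjusted p per window.

    adjusted p = (1 + #{permutation p <= real p}) / (n_perm + 1), computed
    per window against that window's own permutation distribution.
    Significant below ``threshold``.
    """
    rng = np.random.default_rng(seed)
    res = window_lrt(R, genotype)
    geno = genotype.loc[R.index]
    is_mut = (geno == "mutant").to_numpy()
    X = R.to_numpy()
    count_le = np.zeros(X.shape[1])
    real_p = res["p_nominal"].to_numpy()
    for _ in range(n_perm):
        _, p = _lrt_columns(X, is_mut[rng.permutation(len(is_mut))])
        count_le += p <= real_p
    res["p_adjusted"] = (1.0 + count_le) / (n_perm + 1.0)
    res["significant"] = res["p_adjusted"] < threshold
    return res


def assign_nearest_gene(windows: pd.DataFrame, genes: pd.DataFrame,
                        tads: pd.DataFrame) -> pd.DataFrame:
    """Annotate windows with the nearest gene inside the same TAD.

    A window straddling a TAD boundary considers both TADs (nearest over the
    union). A gene qualifies when its body overlaps a considered TAD; the
    nearest gene by body-to-window distance wins (0 on overlap). Windows
    whose TADs contain no gene get an empty annotation.
    """
    out = windows.copy()
    annot = []
    for _, w in windows.iterrows():
        my_tads = tads[(tads["chrom"] == w["chrom"]) & (tads["start"] < w["end"])
                       & (tads["end"] > w["start"])]
        if len(my_tads) > 1:
            logger.info("window %s:%d-%d straddles %d TADs",
                        w["chrom"], w["start"], w["end"], len(my_tads))
        best_gene, best_d = "", np.inf
        for _, t in my_tads.iterrows():
            cand = genes[(genes["chrom"] == t["chrom"])
                         & (genes["start"] < t["end"]) & (genes["end"] > t["start"])]
            for _, g in cand.iterrows():
                d = max(0, max(g["start"] - w["end"], w["start"] - g["end"]))
                if d < best_d:
                    best_gene, best_d = g["name"], d
        annot.append(best_gene)
    out["nearest_gene"] = annot
    return out
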