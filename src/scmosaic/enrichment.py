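"""Cell-type enrichment of mSV subclones.

Is a subclone skewed toward particular HSPC cell types? Each type gets a
one-sided binomial test against a control composition, then a resampling
adjustment: subclone-sized draws (without replacement) from the full cell
population give the null distribution of per-type counts. BH across types
controls the FDR within a subclone.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def binomial_enrichment(k: int, n: int, p0: float) -> float:
    """One-sided upper-tail binomial p-value P(X >= k | n, p0)."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must lie in [0, 1]")
    return float(stats.binom.sf(k - 1, n, p0))


def permutation_adjust(subclone_types: pd.Series, population_types: pd.Series,
                       n_perm: int = 100_000, seed: int = 0) -> pd.DataFrame:
    """Resampling-adjusted per-type enrichment p-values.

    For every cell type, draws of ``len(subclone)`` cells without replacement
    from the population give the null count distribution (marginally
    hypergeometric, sampled exactly); adjusted
    p = (1 + #{perm count >= observed}) / (n_perm + 1).
    """
    n = len(subclone_types)
    if n > len(population_types):
        raise ValueError("subclone larger than population")
    rng = np.random.default_rng(seed)
    rows = []
    pop_counts = population_types.value_counts()
    for ctype, ngood in pop_counts.items():
        k = int((subclone_types == ctype).sum())
        perm = rng.hypergeometric(ngood, len(population_types) - ngood, n,
                                  size=n_perm)
        p = (1.0 + np.sum(perm >= k)) / (n_perm + 1.0)
        rows.append({"cell_type": ctype, "observed": k, "subclone_size": n,
                     "population_fraction": ngood / len(population_types),
                     "p_adjusted": p})
    return pd.DataFrame(rows)


def subclone_enrichment(subclone_cells, population: pd.DataFrame,
                        control_composition: pd.Series | None = None,
                        n_perm: int = 100_000, seed: int = 0,
                        fdr: float = 0.10) -> pd.DataFrame:
    """Full enrichment table for one subclone.

    ``population`` maps every analyzed cell to its type (columns cell /
    cell_type); ``control_composition`` gives the expected type proportions
    for the binomial test (defaults to the population's own composition).
    ``enriched`` flags types passing BH at ``fdr`` on the resampling-adjusted
    p-values.
    """
    pop = population.set_index("cell")["cell_type"]
    sub = pop.loc[list(subclone_cells)]
    if control_composition is None:
        control_composition = pop.value_counts(normalize=True)
    out = permutation_adjust(sub, pop, n_perm=n_perm, seed=seed)
    out["p0"] = out["cell_type"].map(control_composition).fillna(0.0)
    out["p_binomial"] = [
        binomial_enrichment(int(k), int(n), float(p0))
        for k, n, p0 in zip(out["observed"], out["subclone_size"], out["p0"])]
    _, q, _, _ = multipletests(out["p_adjusted"], method="fdr_bh")
    out["q"] = q
    out["enriched"] = q < fdr
    return out
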