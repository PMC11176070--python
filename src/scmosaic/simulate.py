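"""Synthetic single-cell data with known ground truth.

Generators for the four substrates of the pipeline:

* binned Watson/Crick strand counts with planted sister-chromatid exchanges
  (SCEs) and mosaic structural variant (mSV) footprints,
* per-cell x per-gene nucleosome-occupancy (NO) fragment counts with
  cell-type signature structure,
* haplotype-tagged counts over cis-regulatory elements (CREs) with planted
  haplotype-specific accessibility shifts,
* UMI expression counts with region-restricted dosage shifts in planted
  subclones.

Counts are generated at bin/feature level (not read level), because every
downstream statistic operates on binned counts. Each generator is fully
determined by its config's seed.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import Genome, make_bins
from .strand import StrandCountMatrix

MSV_CLASSES = ("del", "dup", "inv", "invdup", "chrom_loss")


class ConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass
class MsvEvent:
    """One planted mosaic SV: class, footprint interval, haplotype, cell fraction."""

    svclass: str
    chrom: str
    start: int
    end: int
    haplotype: str = "H1"  # H1 or H2
    cell_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.svclass not in MSV_CLASSES:
            raise ConfigError(f"unknown mSV class {self.svclass!r}")
        if self.haplotype not in ("H1", "H2"):
            raise ConfigError("haplotype must be H1 or H2")
        if not 0.0 <= self.cell_fraction <= 1.0:
            raise ConfigError("cell_fraction must lie in [0,1]")


@dataclass
class SimConfig:
    """Configuration of the strand-count simulator.

    ``sce_hotspots`` is a list of ((chrom, start, end), rate_multiplier)
    entries; SCE breakpoints are drawn from a mixture that upweights those
    intervals relative to the uniform background.
    """

    genome: list[tuple[str, int]]
    bin_width: int = 200_000
    n_cells: int = 50
    reads_per_cell: float = 40_000.0
    sce_rate: float = 4.0
    sce_hotspots: list = field(default_factory=list)
    msv_events: list = field(default_factory=list)
    background_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ConfigError("bin_width must be positive")
        if not 0.0 <= self.background_noise < 0.5:
            raise ConfigError("background_noise must lie in [0, 0.5)")
        self.msv_events = [e if isinstance(e, MsvEvent) else MsvEvent(*e)
                           for e in self.msv_events]
        gen = Genome.from_pairs(self.genome)
        for ev in self.msv_events:
            if ev.chrom not in gen:
                raise ConfigError(f"mSV on unknown chromosome {ev.chrom}")
            if not (0 <= ev.start < ev.end <= gen.length_of(ev.chrom)):
                raise ConfigError("mSV interval outside its chromosome")
        # two events may not touch the same haplotype in overlapping intervals
        evs = self.msv_events
        for i in range(len(evs)):
            for j in range(i + 1, len(evs)):
                a, b = evs[i], evs[j]
                if (a.chrom == b.chrom and a.haplotype == b.haplotype
                        and a.start < b.end and b.start < a.end):
                    raise ConfigError(
                        "overlapping mSV events on the same haplotype")


@dataclass
class SimTruth:
    """Ground truth of a simulation run; every planted event is recoverable."""

    sce_positions: dict = field(default_factory=dict)   # cell -> [(chrom, bp, homolog)]
    msv_carriers: dict = field(default_factory=dict)    # event id -> sorted cell list
    msv_events: list = field(default_factory=list)      # parallel MsvEvent descriptions
    ground_states: dict = field(default_factory=dict)   # (cell, chrom) -> "WW"/"WC"/"CW"/"CC"
    celltype_labels: dict = field(default_factory=dict)  # cell -> class label
    signature_genes: dict = field(default_factory=dict)  # class -> [gene]
    signature_effect: float = 0.0
    cis_windows: list = field(default_factory=list)     # planted accessibility windows
    clone_labels: dict = field(default_factory=dict)    # cell -> clone id


def _cell_names(n: int) -> list[str]:
    return [f"cell_{i:04d}" for i in range(n)]


def _draw_sce_positions(rng, genome: Genome, n: int, hotspots) -> list[tuple[str, int]]:
    """Breakpoints at bp resolution, uniform or hotspot-weighted mixture."""
    # weight per chromosome = length + extra mass for hotspot intervals
    chroms = list(genome.chroms)
    lengths = np.array(genome.lengths, float)
    extra = np.zeros(len(chroms))
    hs_by_chrom: dict[str, list] = {}
    for (interval, mult) in hotspots:
        c, s, e = interval
        extra[chroms.index(c)] += (mult - 1.0) * (e - s)
        hs_by_chrom.setdefault(c, []).append((s, e, mult))
    w = lengths + extra
    out = []
    for _ in range(n):
        ci = rng.choice(len(chroms), p=w / w.sum())
        chrom = chroms[ci]
        # within the chromosome, sample from the piecewise-constant density
        pieces = [(0, genome.length_of(chrom), 1.0)]
        for (s, e, mult) in hs_by_chrom.get(chrom, []):
            new = []
            for (ps, pe, pm) in pieces:
                for qs, qe in ((ps, min(pe, s)), (max(ps, s), min(pe, e)),
                               (max(ps, e), pe)):
                    if qe > qs:
                        new.append((qs, qe, pm * (mult if (qs >= s and qe <= e) else 1.0)))
            pieces = new
        pw = np.array([(pe - ps) * pm for ps, pe, pm in pieces])
        pi = rng.choice(len(pieces), p=pw / pw.sum())
        ps, pe, _ = pieces[pi]
        out.append((chrom, int(rng.integers(ps, pe))))
    return out


def simulate_strand_cells(config: SimConfig) -> tuple[StrandCountMatrix, SimTruth]:
    """Simulate binned Watson/Crick counts for a population of cells.

    Each cell inherits, per chromosome, an independent template-strand
    orientation for each homolog (Bernoulli(1/2)), giving the WW/WC/CW/CC
    ground states. Reads per bin are Poisson with mean proportional to bin
    width, split between homologs. Planted SCEs flip one homolog's
    orientation distal to the breakpoint; planted mSVs modify copy number
    and/or orientation of one haplotype inside their footprint for carrier
    cells; ``background_noise`` reassigns each read to the wrong strand
    independently.
    """
    rng = np.random.default_rng(config.seed)
    genome = Genome.from_pairs(config.genome)
    bins = make_bins(genome, config.bin_width)
    cells = _cell_names(config.n_cells)
    n_bins = len(bins)
    lam_bp = config.reads_per_cell / genome.total_length()

    truth = SimTruth()
    # carriers per event
    for k, ev in enumerate(config.msv_events):
        n_carr = int(round(ev.cell_fraction * config.n_cells))
        carr = sorted(rng.choice(config.n_cells, size=n_carr, replace=False).tolist())
        eid = f"msv_{k}"
        truth.msv_carriers[eid] = [cells[i] for i in carr]
        truth.msv_events.append(ev)

    bin_chrom = bins["chrom"].to_numpy()
    bin_start = bins["start"].to_numpy()
    bin_end = bins["end"].to_numpy()

    W = np.zeros((config.n_cells, n_bins))
    C = np.zeros((config.n_cells, n_bins))

    for ci, cell in enumerate(cells):
        # per-chromosome homolog orientations: True = Watson template
        orient = {ch: (rng.random() < 0.5, rng.random() < 0.5) for ch in genome.chroms}
        for ch in genome.chroms:
            h1w, h2w = orient[ch]
            state = ("W" if h1w else "C") + ("W" if h2w else "C")
            truth.ground_states[(cell, ch)] = state

        n_sce = rng.poisson(config.sce_rate)
        sces = _draw_sce_positions(rng, genome, n_sce, config.sce_hotspots)
        sce_list = []
        for chrom, bp in sces:
            homolog = int(rng.integers(2))  # 0 = H1, 1 = H2
            sce_list.append((chrom, bp, "H1" if homolog == 0 else "H2"))
        truth.sce_positions[cell] = sorted(sce_list)

        for chrom in genome.chroms:
            L = genome.length_of(chrom)
            mask = bin_chrom == chrom
            bs, be = bin_start[mask], bin_end[mask]
            widths = (be - bs).astype(float)
            for hap_idx, hap in enumerate(("H1", "H2")):
                base_w = orient[chrom][hap_idx]
                # SCE flip points on this homolog
                flips = np.sort([bp for (c2, bp, h2) in truth.sce_positions[cell]
                                 if c2 == chrom and h2 == hap])
                # events affecting this cell/haplotype/chromosome
                my_events = [ev for eid, ev in zip(truth.msv_carriers, truth.msv_events)
                             if ev.chrom == chrom and ev.haplotype == hap
                             and cell in truth.msv_carriers[eid]]

                # piecewise orientation from SCEs: orientation(x) flips at each bp
                cuts = np.concatenate([[0], flips, [L]])
                exp_w = np.zeros(len(bs))
                exp_c = np.zeros(len(bs))
                for pi in range(len(cuts) - 1):
                    ps, pe = cuts[pi], cuts[pi + 1]
                    is_w = base_w ^ (pi % 2 == 1)
                    ov = np.clip(np.minimum(be, pe) - np.maximum(bs, ps), 0, None)
                    lam = lam_bp / 2.0 * ov
                    # copy/orientation modifications from events within [ps,pe)
                    w_copy = np.where(is_w, 1.0, 0.0) * np.ones(len(bs))
                    c_copy = np.where(is_w, 0.0, 1.0) * np.ones(len(bs))
                    for ev in my_events:
                        if ev.svclass == "chrom_loss":
                            inside = np.ones(len(bs), bool)
                        else:
                            inside = (np.minimum(be, pe) > ev.start) & \
                                     (np.maximum(bs, ps) < ev.end)
                        if not inside.any():
                            continue
                        # fraction of the piece-overlap lying inside the event
                        if ev.svclass == "chrom_loss":
                            frac = np.ones(len(bs))
                        else:
                            es = np.maximum(np.maximum(bs, ps), ev.start)
                            ee = np.minimum(np.minimum(be, pe), ev.end)
                            with np.errstate(invalid="ignore", divide="ignore"):
                                frac = np.where(ov > 0, np.clip(ee - es, 0, None) / ov, 0.0)
                        if ev.svclass in ("del", "chrom_loss"):
                            w_copy = w_copy * (1 - frac)
                            c_copy = c_copy * (1 - frac)
                        elif ev.svclass == "dup":
                            w_copy = w_copy + frac * (1.0 if is_w else 0.0)
                            c_copy = c_copy + frac * (0.0 if is_w else 1.0)
                        elif ev.svclass == "inv":
                            # move copy mass to the opposite strand inside event
                            if is_w:
                                w_copy = w_copy - frac
                                c_copy = c_copy + frac
                            else:
                                c_copy = c_copy - frac
                                w_copy = w_copy + frac
                        elif ev.svclass == "invdup":
                            # original copy stays; inverted duplicate on opposite strand
                            if is_w:
                                c_copy = c_copy + frac
                            else:
                                w_copy = w_copy + frac
                    exp_w += lam * w_copy
                    exp_c += lam * c_copy
                W[ci, mask] += rng.poisson(np.clip(exp_w, 0, None))
                C[ci, mask] += rng.poisson(np.clip(exp_c, 0, None))

    if config.background_noise > 0:
        eps = config.background_noise
        w2c = rng.binomial(W.astype(np.int64), eps)
        c2w = rng.binomial(C.astype(np.int64), eps)
        W = W - w2c + c2w
        C = C - c2w + w2c

    m = StrandCountMatrix(bins=bins, cells=cells,
                          W=W.astype(np.int64), C=C.astype(np.int64))
    return m, truth


# ---------------------------------------------------------------------------
# nucleosome-occupancy reference simulation


@dataclass
class NOSimConfig:
    """Config of the NO cell-type reference simulator.

    ``effect`` is the log2 shift applied to each class's signature genes in
    cells of that class; ``dispersion`` is the negative-binomial size.
    """

    n_classes: int = 8
    n_cells: int = 300
    n_genes: int = 2000
    signature_size: int = 40
    effect: float = 1.0
    dispersion: float = 2.0
    baseline_mean: float = 20.0
    class_proportions: list | None = None
    gene_chrom: str = "chr1"
    gene_length: int = 10_000
    seed: int = 0


def _nb_sample(rng, mean, size):
    """Negative binomial with mean/size parameterization (size = dispersion)."""
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_no_matrix(config: NOSimConfig):
    """Simulate a cell-type NO reference: NB counts with class signatures.

    Returns (NOMatrix, SimTruth). Signature genes are disjoint blocks of
    ``signature_size`` genes per class, shifted by ``effect`` on the log2
    scale in cells of that class.
    """
    from .celltyping import NOMatrix

    if config.n_classes < 2:
        raise ConfigError("need at least two classes")
    need = config.n_classes * config.signature_size
    if need > config.n_genes:
        raise ConfigError("not enough genes for the requested signatures")
    if config.effect == 0:
        warnings.warn("effect=0: classes will not be separable", stacklevel=2)

    rng = np.random.default_rng(config.seed)
    cells = _cell_names(config.n_cells)
    genes = [f"gene_{g:05d}" for g in range(config.n_genes)]
    classes = [f"class_{k}" for k in range(config.n_classes)]
    props = config.class_proportions or [1.0 / config.n_classes] * config.n_classes
    labels = [classes[k] for k in rng.choice(config.n_classes, size=config.n_cells,
                                             p=np.asarray(props) / np.sum(props))]

    base = config.baseline_mean * np.exp(rng.normal(0, 0.4, size=config.n_genes))
    truth = SimTruth(signature_effect=config.effect)
    sig = {}
    for k, cls in enumerate(classes):
        idx = range(k * config.signature_size, (k + 1) * config.signature_size)
        sig[cls] = [genes[i] for i in idx]
    truth.signature_genes = sig
    truth.celltype_labels = dict(zip(cells, labels))

    mean = np.tile(base, (config.n_cells, 1))
    for k, cls in enumerate(classes):
        rows = np.array([lab == cls for lab in labels])
        cols = slice(k * config.signature_size, (k + 1) * config.signature_size)
        mean[np.ix_(rows, np.arange(config.n_genes)[cols])] *= 2.0 ** config.effect
    counts = _nb_sample(rng, mean, config.dispersion)

    gene_meta = pd.DataFrame({
        "gene": genes,
        "chrom": config.gene_chrom,
        "start": np.arange(config.n_genes) * config.gene_length,
        "end": (np.arange(config.n_genes) + 1) * config.gene_length,
    }).set_index("gene")
    m = NOMatrix(counts=pd.DataFrame(counts, index=cells, columns=genes),
                 labels=pd.Series(labels, index=cells),
                 gene_meta=gene_meta)
    return m, truth


# ---------------------------------------------------------------------------
# haplotype-tagged CRE counts


@dataclass
class CreSimConfig:
    """Config of the haplotype-resolved CRE count simulator.

    ``planted_windows`` entries are (chrom, start, end, haplotype, effect):
    in carrier cells, NO counts of CREs inside the window on that haplotype
    are scaled by ``effect`` (0.5 = half occupancy = doubled accessibility).
    """

    cres: pd.DataFrame | None = None   # BED-like chrom/start/end
    n_cres: int = 200
    cre_chrom: str = "chrX"
    cre_spacing: int = 20_000
    cre_width: int = 1_000
    n_cells: int = 80
    carrier_fraction: float = 0.25
    mean_count: float = 10.0
    dispersion: float = 2.0
    planted_windows: list = field(default_factory=list)
    seed: int = 0


def simulate_cre_haplotype_counts(config: CreSimConfig):
    """Per-cell, per-CRE, per-haplotype NO counts with planted cis windows.

    Returns (counts DataFrame indexed by cell with a column MultiIndex
    (cre_id, haplotype), cres BED DataFrame, SimTruth). Truth records carrier
    cells under clone id ``"carrier"``.
    """
    rng = np.random.default_rng(config.seed)
    if config.cres is not None:
        cres = config.cres.reset_index(drop=True).copy()
    else:
        starts = np.arange(config.n_cres) * config.cre_spacing
        cres = pd.DataFrame({"chrom": config.cre_chrom, "start": starts,
                             "end": starts + config.cre_width})
    cres["cre_id"] = [f"cre_{i:04d}" for i in range(len(cres))]

    for (chrom, ws, we, hap, effect) in config.planted_windows:
        inside = (cres["chrom"] == chrom) & (cres["start"] < we) & (cres["end"] > ws)
        if not inside.any():
            raise ConfigError("planted window contains zero CREs")

    cells = _cell_names(config.n_cells)
    n_carr = int(round(config.carrier_fraction * config.n_cells))
    carriers = set(rng.choice(config.n_cells, size=n_carr, replace=False).tolist())

    base = config.mean_count * np.exp(rng.normal(0, 0.3, size=len(cres)))
    data = {}
    for hap in ("H1", "H2"):
        mean = np.tile(base, (config.n_cells, 1))
        for (chrom, ws, we, whap, effect) in config.planted_windows:
            if whap != hap:
                continue
            cols = ((cres["chrom"] == chrom) & (cres["start"] < we)
                    & (cres["end"] > ws)).to_numpy()
            rows = np.array([i in carriers for i in range(config.n_cells)])
            mean[np.ix_(rows, np.where(cols)[0])] *= effect
        data[hap] = _nb_sample(rng, mean, config.dispersion)

    columns = pd.MultiIndex.from_product([cres["cre_id"], ("H1", "H2")],
                                         names=["cre_id", "haplotype"])
    mat = np.empty((config.n_cells, 2 * len(cres)), dtype=np.int64)
    mat[:, 0::2] = data["H1"]
    mat[:, 1::2] = data["H2"]
    counts = pd.DataFrame(mat, index=cells, columns=columns)

    truth = SimTruth()
    truth.clone_labels = {c: ("carrier" if i in carriers else "wt")
                          for i, c in enumerate(cells)}
    truth.cis_windows = list(config.planted_windows)
    return counts, cres, truth


# ---------------------------------------------------------------------------
# expression with planted CNA clones


@dataclass
class ExprSimConfig:
    """Config of the UMI-expression simulator with planted CNA subclones.

    ``clones`` entries are (clone_id, (chrom, start, end), dosage, fraction):
    genes inside the region are scaled by ``dosage`` (0.5 = heterozygous
    loss) in cells of the clone. Unassigned cells form the "normal" clone.

    Defaults emulate the genes that survive the expressed-gene filter of
    targeted CNA re-calling: moderately expressed (rare zero counts) with
    mild overdispersion — droplet UMI counts are close to Poisson, so the
    NB dispersion here is much larger than for fragment-count simulators.
    """

    n_cells: int = 2000
    n_genes: int = 500
    gene_chrom: str = "chr17"
    gene_length: int = 50_000
    mean_count: float = 5.0
    dispersion: float = 10.0
    libsize_sigma: float = 0.2
    clones: list = field(default_factory=list)
    seed: int = 0


def simulate_expression(config: ExprSimConfig):
    """Simulate UMI counts with region-restricted dosage shifts.

    Returns (ExpressionMatrix, SimTruth). Clone fractions must sum to <= 1;
    remaining cells are labelled ``"normal"``.
    """
    from .cna import ExpressionMatrix

    rng = np.random.default_rng(config.seed)
    fracs = [f for (_, _, _, f) in config.clones]
    if sum(fracs) > 1.0 + 1e-9:
        raise ConfigError("clone fractions sum beyond 1")

    cells = _cell_names(config.n_cells)
    genes = [f"gene_{g:05d}" for g in range(config.n_genes)]
    gene_start = np.arange(config.n_genes) * config.gene_length
    gene_meta = pd.DataFrame({"gene": genes, "chrom": config.gene_chrom,
                              "start": gene_start,
                              "end": gene_start + config.gene_length}).set_index("gene")

    order = rng.permutation(config.n_cells)
    clone_of = np.full(config.n_cells, "normal", dtype=object)
    pos = 0
    for (cid, _, _, frac) in config.clones:
        k = int(round(frac * config.n_cells))
        clone_of[order[pos:pos + k]] = cid
        pos += k

    base = config.mean_count * np.exp(rng.normal(0, 0.6, size=config.n_genes))
    libfac = np.exp(rng.normal(0, config.libsize_sigma, size=config.n_cells))
    mean = libfac[:, None] * base[None, :]
    for (cid, (chrom, s, e), dosage, _) in config.clones:
        cols = ((gene_meta["chrom"] == chrom) & (gene_meta["start"] < e)
                & (gene_meta["end"] > s)).to_numpy()
        rows = clone_of == cid
        mean[np.ix_(rows, np.where(cols)[0])] *= dosage
    counts = _nb_sample(rng, mean, config.dispersion)

    truth = SimTruth()
    truth.clone_labels = dict(zip(cells, clone_of))
    m = ExpressionMatrix(counts=pd.DataFrame(counts, index=cells, columns=genes),
                         gene_meta=gene_meta)
    return m, truth
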