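"""Strand-state segmentation, SCE calling and mSV footprint genotyping.

Strand-seq preserves template-strand identity, so each chromosome of each
cell shows a characteristic Watson/Crick read mixture per homolog: both
templates Watson (WW), both Crick (CC), or one of each (WC). A sister
chromatid exchange (SCE) flips one homolog's template distal to the
breakpoint and appears as a single strand-state changepoint; structural
variants leave "diagnostic footprints" — class-specific combinations of read
depth and strand orientation inside their interval.

Strand alone cannot distinguish WC from CW (that requires haplotype phase),
so the mixed ground state is reported as ``WC`` throughout.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import validate_intervals
from .io import gz_compression

logger = logging.getLogger(__name__)

STATES = ("WW", "WC", "CC")


@dataclass
class StrandCountMatrix:
    """Per-cell, per-bin Watson and Crick read counts.

    ``bins`` is a BED-like frame (chrom/start/end, 0-based half-open) tiling
    each chromosome; ``W`` and ``C`` are cells x bins integer arrays.
    """

    bins: pd.DataFrame
    cells: list[str]
    W: np.ndarray
    C: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W)
        self.C = np.asarray(self.C)
        if self.W.shape != (len(self.cells), len(self.bins)):
            raise ValueError("W shape does not match cells x bins")
        if self.C.shape != self.W.shape:
            raise ValueError("C shape does not match W")
        if (self.W < 0).any() or (self.C < 0).any():
            raise ValueError("counts must be non-negative")
        validate_intervals(self.bins)

    @property
    def total(self) -> np.ndarray:
        return self.W + self.C

    def chrom_mask(self, chrom: str) -> np.ndarray:
        return (self.bins["chrom"] == chrom).to_numpy()

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.bins["chrom"]))

    def write_tsv(self, w_path, c_path) -> None:
        cols = [f"{r.chrom}:{r.start}-{r.end}" for r in self.bins.itertuples()]
        pd.DataFrame(self.W, index=self.cells, columns=cols).to_csv(
            w_path, sep="\t", compression=gz_compression(w_path))
        pd.DataFrame(self.C, index=self.cells, columns=cols).to_csv(
            c_path, sep="\t", compression=gz_compression(c_path))

    @classmethod
    def read_tsv(cls, w_path, c_path) -> "StrandCountMatrix":
        w = pd.read_csv(w_path, sep="\t", index_col=0)
        c = pd.read_csv(c_path, sep="\t", index_col=0)
        if list(w.columns) != list(c.columns) or list(w.index) != list(c.index):
            raise ValueError("W and C matrices disagree on cells or bins")
        parts = [col.replace(":", "-").split("-") for col in w.columns]
        bins = pd.DataFrame({"chrom": [p[0] for p in parts],
                             "start": [int(p[1]) for p in parts],
                             "end": [int(p[2]) for p in parts]})
        return cls(bins=bins, cells=list(w.index), W=w.to_numpy(), C=c.to_numpy())


@dataclass
class StrandStateSegment:
    cell: str
    chrom: str
    start: int
    end: int
    state: str           # WW / WC / CC / unknown
    w_fraction: float
    n_bins: int


@dataclass
class SCECall:
    cell: str
    chrom: str
    ci_start: int
    ci_end: int
    flipped: str         # e.g. "W->C": one homolog's template flipped W to C


@dataclass
class SCEResult:
    """Callset plus the chromosomes held back from it."""

    calls: list[SCECall] = field(default_factory=list)
    review: list[tuple[str, str, int]] = field(default_factory=list)   # (cell, chrom, n_changepoints)
    msv_candidates: list[tuple[str, str, str, str]] = field(default_factory=list)  # state jump not explicable by one flip


@dataclass
class MosaicCall:
    event_id: str
    svclass: str         # del / dup / inv / invdup / complex / chrom_loss
    chrom: str
    start: int
    end: int
    haplotype: str       # W-homolog / C-homolog / ambiguous
    carriers: list[str]
    n_analyzed: int
    status: str = ""     # singleton / subclonal

    @property
    def cell_fraction(self) -> float:
        return len(self.carriers) / self.n_analyzed

    @property
    def cf_percent(self) -> float:
        """CF as a percentage rounded to one decimal, for reports."""
        return round(100.0 * self.cell_fraction, 1)


def _state_probs(error_rate: float) -> dict[str, float]:
    e = min(max(error_rate, 1e-6), 0.49)
    return {"WW": 1.0 - e, "WC": 0.5, "CC": e}


def _seg_ll(sw, sc, probs):
    """Max binomial log-likelihood of a segment over the three states."""
    sw = np.asarray(sw, float)
    sc = np.asarray(sc, float)
    best = None
    for p in probs.values():
        ll = sw * np.log(p) + sc * np.log1p(-p)
        best = ll if best is None else np.maximum(best, ll)
    return best


def _seg_state(sw, sc, probs) -> str:
    lls = {s: sw * np.log(p) + sc * np.log1p(-p) for s, p in probs.items()}
    return max(lls, key=lls.get)


def _binary_segment(w, c, probs, penalty):
    """Recursive binary segmentation; returns sorted changepoint indices."""
    cw = np.concatenate([[0], np.cumsum(w)])
    cc = np.concatenate([[0], np.cumsum(c)])

    def ll(i, j):
        return float(_seg_ll(cw[j] - cw[i], cc[j] - cc[i], probs))

    cuts = []

    def recurse(i, j):
        if j - i < 2:
            return
        ks = np.arange(i + 1, j)
        left = _seg_ll(cw[ks] - cw[i], cc[ks] - cc[i], probs)
        right = _seg_ll(cw[j] - cw[ks], cc[j] - cc[ks], probs)
        gain = left + right - ll(i, j)
        k = ks[int(np.argmax(gain))]
        if gain.max() > penalty:
            cuts.append(int(k))
            recurse(i, k)
            recurse(k, j)

    recurse(0, len(w))
    return sorted(cuts)


def call_strand_states(m: StrandCountMatrix, min_bins: int = 3,
                       error_rate: float = 0.02,
                       min_reads_per_chrom: int = 20) -> list[StrandStateSegment]:
    """Segment each (cell, chromosome) into constant strand-state stretches.

    A binomial model of the per-bin Watson fraction with expected fractions
    {WW: 1-e, WC: 0.5, CC: e} is segmented by recursive binary splitting; a
    split is kept when the log-likelihood gain exceeds a BIC-style penalty of
    2*ln(n_bins). Segments shorter than ``min_bins`` are merged into the
    neighbour giving the higher joint likelihood; chromosomes below
    ``min_reads_per_chrom`` total reads get a single ``unknown`` segment.
    """
    probs = _state_probs(error_rate)
    segments: list[StrandStateSegment] = []
    bin_chrom = m.bins["chrom"].to_numpy()
    starts = m.bins["start"].to_numpy()
    ends = m.bins["end"].to_numpy()

    for ci, cell in enumerate(m.cells):
        for chrom in m.chromosomes():
            mask = bin_chrom == chrom
            w = m.W[ci, mask].astype(float)
            c = m.C[ci, mask].astype(float)
            bs, be = starts[mask], ends[mask]
            if w.sum() + c.sum() < min_reads_per_chrom:
                segments.append(StrandStateSegment(cell, chrom, int(bs[0]),
                                                   int(be[-1]), "unknown",
                                                   float("nan"), len(w)))
                continue
            penalty = 2.0 * np.log(max(len(w), 2))
            cuts = _binary_segment(w, c, probs, penalty)
            bounds = [0] + cuts + [len(w)]
            # merge segments shorter than min_bins into their best neighbour
            while len(bounds) > 2:
                lens = np.diff(bounds)
                short = np.where(lens < min_bins)[0]
                if len(short) == 0:
                    break
                k = int(short[np.argmin(lens[short])])
                # candidate merges: with left neighbour or right neighbour
                if k == 0:
                    drop = 1
                elif k == len(lens) - 1:
                    drop = len(bounds) - 2
                else:
                    # choose merge direction by joint likelihood
                    def merged_ll(a, b):
                        sw = w[bounds[a]:bounds[b]].sum()
                        sc = c[bounds[a]:bounds[b]].sum()
                        return float(_seg_ll(sw, sc, probs))
                    gain_left = merged_ll(k - 1, k + 1)
                    gain_right = merged_ll(k, k + 2)
                    drop = k if gain_left >= gain_right else k + 1
                bounds.pop(drop)
            # state per segment; merge adjacent equal states
            segs = []
            for a, b in zip(bounds[:-1], bounds[1:]):
                sw, sc = w[a:b].sum(), c[a:b].sum()
                state = _seg_state(sw, sc, probs)
                segs.append([a, b, state, sw, sc])
            merged = [segs[0]]
            for seg in segs[1:]:
                if seg[2] == merged[-1][2]:
                    merged[-1][1] = seg[1]
                    merged[-1][3] += seg[3]
                    merged[-1][4] += seg[4]
                else:
                    merged.append(seg)
            for a, b, state, sw, sc in merged:
                tot = sw + sc
                segments.append(StrandStateSegment(
                    cell, chrom, int(bs[a]), int(be[b - 1]), state,
                    float(sw / tot) if tot else float("nan"), b - a))
    return segments


_SINGLE_FLIP = {("WW", "WC"): "W->C", ("WC", "WW"): "C->W",
                ("CC", "WC"): "C->W", ("WC", "CC"): "W->C"}


def detect_sces(segments: list[StrandStateSegment]) -> SCEResult:
    """Call SCEs from segmented strand states.

    Only chromosomes with exactly one changepoint enter the callset, and only
    when the state change is consistent with a single homolog flipping its
    template (WW<->WC or CC<->WC). Chromosomes with two or more changepoints
    go to a review list; a WW<->CC jump is flagged as a candidate mSV. The
    confidence interval is the segment boundary padded by 1 bp on each side.
    """
    res = SCEResult()
    by_cc: dict[tuple[str, str], list[StrandStateSegment]] = {}
    for s in segments:
        by_cc.setdefault((s.cell, s.chrom), []).append(s)
    for (cell, chrom), segs in by_cc.items():
        segs = sorted(segs, key=lambda s: s.start)
        if any(s.state == "unknown" for s in segs):
            continue
        n_change = len(segs) - 1
        if n_change == 0:
            continue
        if n_change >= 2:
            res.review.append((cell, chrom, n_change))
            continue
        a, b = segs
        key = (a.state, b.state)
        if key not in _SINGLE_FLIP:
            res.msv_candidates.append((cell, chrom, a.state, b.state))
            continue
        boundary = a.end
        res.calls.append(SCECall(cell, chrom, boundary - 1, boundary + 1,
                                 _SINGLE_FLIP[key]))
    return res


# ---------------------------------------------------------------------------
# diagnostic-footprint genotyping

# expected (W, C) copy numbers per hypothesis given each ground state.
# "W-homolog"/"C-homolog" name the homolog by the strand it contributes in
# the cell's ground state; in WW and CC the homologs are strand-equivalent.
def _footprints(ground: str) -> dict[tuple[str, str], tuple[float, float]]:
    if ground == "WC":
        return {
            ("ref", "-"): (1, 1),
            ("del", "W-homolog"): (0, 1), ("del", "C-homolog"): (1, 0),
            ("dup", "W-homolog"): (2, 1), ("dup", "C-homolog"): (1, 2),
            ("inv", "W-homolog"): (0, 2), ("inv", "C-homolog"): (2, 0),
            ("invdup", "W-homolog"): (1, 2), ("invdup", "C-homolog"): (2, 1),
        }
    if ground == "WW":
        return {
            ("ref", "-"): (2, 0),
            ("del", "ambiguous"): (1, 0),
            ("dup", "ambiguous"): (3, 0),
            ("inv", "ambiguous"): (1, 1),
            ("invdup", "ambiguous"): (2, 1),
        }
    if ground == "CC":
        return {
            ("ref", "-"): (0, 2),
            ("del", "ambiguous"): (0, 1),
            ("dup", "ambiguous"): (0, 3),
            ("inv", "ambiguous"): (1, 1),
            ("invdup", "ambiguous"): (1, 2),
        }
    raise ValueError(f"no footprints for ground state {ground!r}")


_CLASS_PRIORITY = {"ref": 0, "del": 1, "dup": 2, "inv": 3, "invdup": 4}


def _poisson_ll(k, mu):
    mu = max(mu, 1e-9)
    return k * np.log(mu) - mu


def genotype_cell(w: float, c: float, per_copy: float, ground: str,
                  error_rate: float = 0.02):
    """Maximum-likelihood footprint for one cell x interval.

    ``per_copy`` is the expected read count in the interval contributed by a
    single chromosomal copy. Returns (class, haplotype, posterior dict over
    hypotheses). Ties break toward the lowest-priority class (ref first) —
    conservative calling.
    """
    hyps = _footprints(ground)
    lls = {}
    for (cls, hap), (nw, nc) in hyps.items():
        mu_w = per_copy * nw
        mu_c = per_copy * nc
        ew = (1 - error_rate) * mu_w + error_rate * mu_c
        ec = (1 - error_rate) * mu_c + error_rate * mu_w
        lls[(cls, hap)] = _poisson_ll(w, ew) + _poisson_ll(c, ec)
    mx = max(lls.values())
    post = {k: np.exp(v - mx) for k, v in lls.items()}
    z = sum(post.values())
    post = {k: v / z for k, v in post.items()}
    best = min((k for k, v in lls.items() if v >= mx - 1e-9),
               key=lambda k: _CLASS_PRIORITY[k[0]])
    return best[0], best[1], post


def genotype_footprints(m: StrandCountMatrix,
                        segments: list[StrandStateSegment],
                        events: list[dict],
                        error_rate: float = 0.02) -> list[MosaicCall]:
    """Genotype candidate intervals in every cell and aggregate carriers.

    ``events`` entries need chrom/start/end (and optionally ``id``). The
    cell's ground state comes from its majority strand-state outside the
    candidate interval; cells with an unknown ground state are excluded from
    the carrier denominator. The per-copy depth is estimated from all bins
    outside the interval assuming two copies genome-wide.
    """
    bin_chrom = m.bins["chrom"].to_numpy()
    bs = m.bins["start"].to_numpy()
    be = m.bins["end"].to_numpy()
    widths = (be - bs).astype(float)

    seg_by_cc: dict[tuple[str, str], list[StrandStateSegment]] = {}
    for s in segments:
        seg_by_cc.setdefault((s.cell, s.chrom), []).append(s)

    calls = []
    for k, ev in enumerate(events):
        chrom, start, end = ev["chrom"], int(ev["start"]), int(ev["end"])
        eid = str(ev.get("id", f"event_{k}"))
        inside = (bin_chrom == chrom) & \
            ((np.minimum(be, end) - np.maximum(bs, start)) * 2 > widths)
        if not inside.any():
            raise ValueError(f"candidate interval {eid} shorter than one bin")
        chrom_len = float(be[bin_chrom == chrom].max())
        is_chrom_scale = (end - start) >= 0.9 * chrom_len
        outside = ~inside
        interval_bp = widths[inside].sum()

        carriers, class_votes, hap_votes = [], {}, {}
        n_analyzed = 0
        for ci, cell in enumerate(m.cells):
            # ground state: majority bp among non-unknown segments off-interval
            segs = [s for s in seg_by_cc.get((cell, chrom), [])
                    if s.state != "unknown"]
            cover: dict[str, float] = {}
            for s in segs:
                ov = max(0, min(s.end, start) - s.start) + \
                    max(0, s.end - max(s.start, end))
                cover[s.state] = cover.get(s.state, 0.0) + ov
            if is_chrom_scale and not cover:
                # whole-chromosome candidate: fall back to whole-chrom state
                for s in segs:
                    cover[s.state] = cover.get(s.state, 0.0) + (s.end - s.start)
            if not cover:
                continue
            ground = max(cover, key=cover.get)
            out_reads = float(m.W[ci, outside].sum() + m.C[ci, outside].sum())
            out_bp = widths[outside].sum()
            if out_reads < 10 or out_bp == 0:
                continue
            per_copy = out_reads / (2.0 * out_bp) * interval_bp
            n_analyzed += 1
            w = float(m.W[ci, inside].sum())
            c = float(m.C[ci, inside].sum())
            cls, hap, _post = genotype_cell(w, c, per_copy, ground, error_rate)
            if cls != "ref":
                carriers.append(cell)
                class_votes[cls] = class_votes.get(cls, 0) + 1
                hap_votes[hap] = hap_votes.get(hap, 0) + 1
        if not carriers:
            warnings.warn(f"candidate {eid}: no carriers called; call dropped",
                          stacklevel=2)
            continue
        svclass = max(class_votes, key=class_votes.get)
        if is_chrom_scale and svclass == "del":
            svclass = "chrom_loss"
        haplotype = max(hap_votes, key=hap_votes.get)
        calls.append(MosaicCall(eid, svclass, chrom, start, end, haplotype,
                                sorted(carriers), n_analyzed))
    return classify_singleton_subclonal(calls)


def classify_singleton_subclonal(calls: list[MosaicCall]) -> list[MosaicCall]:
    """Label calls singleton (one carrier) or subclonal (two or more)."""
    out = []
    for call in calls:
        if len(call.carriers) == 0:
            warnings.warn(f"call {call.event_id} has no carriers; dropped",
                          stacklevel=2)
            continue
        call.status = "singleton" if len(call.carriers) == 1 else "subclonal"
        out.append(call)
    return out


def calls_to_bed(calls: list[MosaicCall]) -> pd.DataFrame:
    """BED6+ representation of mosaic calls (CF as percentage)."""
    return pd.DataFrame([
        {"chrom": c.chrom, "start": c.start, "end": c.end, "name": c.event_id,
         "score": c.cf_percent, "strand": ".", "svclass": c.svclass,
         "haplotype": c.haplotype, "status": c.status,
         "n_carriers": len(c.carriers), "n_analyzed": c.n_analyzed}
        for c in calls])


def sces_to_bed(calls: list[SCECall]) -> pd.DataFrame:
    return pd.DataFrame([
        {"chrom": c.chrom, "start": c.ci_start, "end": c.ci_end,
         "name": c.cell, "score": 0, "strand": ".", "flipped": c.flipped}
        for c in calls])
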