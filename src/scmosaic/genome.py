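"""Genome coordinate utilities: chrom.sizes, tiling bins and interval sets.

All coordinates are 0-based half-open internally. Human-readable reports may
convert to 1-based inclusive, but nothing in this module does.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BED_COLUMNS = ["chrom", "start", "end"]


@dataclass(frozen=True)
class Genome:
    """An ordered set of chromosomes with lengths (UCSC chrom.sizes dialect)."""

    chroms: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chroms) != len(self.lengths):
            raise ValueError("chroms and lengths differ in length")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("chromosome lengths must be positive")
        if len(set(self.chroms)) != len(self.chroms):
            raise ValueError("duplicate chromosome names")

    @classmethod
    def from_pairs(cls, pairs) -> "Genome":
        chroms, lengths = zip(*pairs) if pairs else ((), ())
        return cls(tuple(chroms), tuple(int(x) for x in lengths))

    @classmethod
    def read_chrom_sizes(cls, path) -> "Genome":
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                         dtype={"chrom": str, "length": np.int64})
        return cls.from_pairs(list(df.itertuples(index=False, name=None)))

    def write_chrom_sizes(self, path) -> None:
        pd.DataFrame({"chrom": self.chroms, "length": self.lengths}).to_csv(
            path, sep="\t", header=False, index=False)

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[self.chroms.index(chrom)]
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chroms

    def total_length(self) -> int:
        return int(sum(self.lengths))


def make_bins(genome: Genome, bin_width: int) -> pd.DataFrame:
    """Tile every chromosome with fixed-width bins.

    The last bin of each chromosome may be shorter. Returns a DataFrame with
    columns chrom/start/end sorted by (chrom order in genome, start).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    rows = []
    for chrom, length in zip(genome.chroms, genome.lengths):
        starts = np.arange(0, length, bin_width, dtype=np.int64)
        ends = np.minimum(starts + bin_width, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


def validate_intervals(df: pd.DataFrame, genome: Genome | None = None) -> None:
    """Check chrom/start/end sanity; raises ValueError on violation."""
    if (df["start"] < 0).any() or (df["end"] <= df["start"]).any():
        raise ValueError("intervals must satisfy 0 <= start < end")
    if genome is not None:
        for chrom, sub in df.groupby("chrom", sort=False):
            if chrom not in genome:
                raise ValueError(f"interval on unknown chromosome {chrom!r}")
            if (sub["end"] > genome.length_of(chrom)).any():
                raise ValueError(f"interval beyond end of {chrom}")


def read_bed(path, extra_cols: list[str] | None = None) -> pd.DataFrame:
    names = BED_COLUMNS + (extra_cols or [])
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : len(names)]
    df.columns = names
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in df.columns if c in BED_COLUMNS] + \
        [c for c in df.columns if c not in BED_COLUMNS]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


class IntervalSet:
    """Per-chromosome sorted, merged intervals supporting fast overlap queries."""

    def __init__(self, df: pd.DataFrame):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy(np.int64)
            ends = sub["end"].to_numpy(np.int64)
            order = np.argsort(starts, kind="stable")
            starts, ends = starts[order], ends[order]
            # merge touching/overlapping intervals so queries are searchsorted-safe
            ms, me = [], []
            for s, e in zip(starts, ends):
                if me and s <= me[-1]:
                    me[-1] = max(me[-1], e)
                else:
                    ms.append(s)
                    me.append(e)
            self._by_chrom[str(chrom)] = (np.asarray(ms, np.int64),
                                          np.asarray(me, np.int64))

    def overlaps(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Boolean vector: does each query interval intersect the set?"""
        starts = np.atleast_1d(np.asarray(starts, np.int64))
        ends = np.atleast_1d(np.asarray(ends, np.int64))
        if chrom not in self._by_chrom:
            return np.zeros(starts.shape, dtype=bool)
        ms, me = self._by_chrom[chrom]
        # candidate merged interval: the last one starting before the query end
        idx = np.searchsorted(ms, ends, side="left") - 1
        ok = idx >= 0
        hit = np.zeros(starts.shape, dtype=bool)
        hit[ok] = me[idx[ok]] > starts[ok]
        return hit
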