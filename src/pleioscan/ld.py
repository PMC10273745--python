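"""LD proxy lookup and approximately independent LD-block assignment.

Two small genomic resources back the cross-trait analysis: a pairwise r²
table used to substitute a close LD proxy when a lead variant is absent from
the other trait's summary statistics, and a genome partition into
approximately independent LD blocks used to scope colocalization to the
block containing each lead variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = ["LDProxyTable", "LDBlockSet", "best_proxy", "assign_block"]


@dataclass
class LDProxyTable:
    """Pairwise r² lookups: rows of (variant_a, variant_b, r2, population).

    The symmetric closure is applied on construction: a row (a, b, r2)
    implies (b, a, r2).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        required = {"variant_a", "variant_b", "r2"}
        if not required.issubset(df.columns):
            raise ConfigurationError(f"proxy table needs columns {sorted(required)}")
        if "population" not in df.columns:
            df = df.assign(population="NA")
        bad = (df["r2"] < 0) | (df["r2"] > 1)
        if bad.any():
            raise ConfigurationError("proxy table contains r2 outside [0, 1]")
        mirrored = df.rename(columns={"variant_a": "variant_b", "variant_b": "variant_a"})
        full = pd.concat([df, mirrored[df.columns]], ignore_index=True)
        full = full.drop_duplicates(["variant_a", "variant_b"], keep="first")
        self.df = full.reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LDProxyTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"variant_a": str, "variant_b": str}))

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def best_proxy(
    variant: str,
    proxies: LDProxyTable,
    available: Iterable[str],
    r2_min: float = 0.8,
    positions: Mapping[str, tuple[str, int]] | None = None,
) -> str | None:
    """The highest-r² proxy of ``variant`` among ``available`` variants.

    Candidates are rows with variant_a == variant, r2 strictly greater than
    ``r2_min`` (default 0.8) and variant_b present in ``available``.  Ties at
    the maximal r² break to the candidate nearest the query in genomic
    position (when ``positions`` supplies coordinates), then to the
    lexicographically smallest id, making the result independent of row
    order.  Returns None when no candidate qualifies.
    """
    if not 0 <= r2_min <= 1:
        raise ValueError("r2_min must lie in [0, 1]")
    df = proxies.df
    available = set(available)
    cand = df.loc[
        (df["variant_a"] == variant)
        & (df["r2"] > r2_min)
        & df["variant_b"].isin(available)
        & (df["variant_b"] != variant)
    ]
    if cand.empty:
        return None
    top = cand.loc[cand["r2"] == cand["r2"].max()]
    if len(top) == 1:
        return str(top["variant_b"].iloc[0])

    def sort_key(vid: str) -> tuple[float, str]:
        dist = np.inf
        if positions and variant in positions and vid in positions:
            qchrom, qpos = positions[variant]
            cchrom, cpos = positions[vid]
            if qchrom == cchrom:
                dist = abs(int(cpos) - int(qpos))
        return (dist, vid)

    return min((str(v) for v in top["variant_b"]), key=sort_key)


@dataclass
class LDBlockSet:
    """Non-overlapping genomic intervals (chrom, start, end), BED semantics.

    Intervals are 0-based half-open as loaded from BED3; within each
    chromosome they are sorted and must not overlap.
    """

    df: pd.DataFrame
    _by_chrom: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        df = self.df
        if not {"chrom", "start", "end"}.issubset(df.columns):
            raise ConfigurationError("block set needs columns chrom, start, end")
        if (df["start"] >= df["end"]).any():
            raise ConfigurationError("block with start >= end")
        df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        for chrom, grp in df.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if np.any(starts[1:] < ends[:-1]):
                raise ConfigurationError(f"overlapping blocks on {chrom}")
            self._by_chrom[chrom] = (starts, ends)
        self.df = df

    @classmethod
    def from_bed(cls, path: str | Path) -> "LDBlockSet":
        df = pd.read_csv(
            path, sep="\t", header=None, usecols=[0, 1, 2],
            names=["chrom", "start", "end"], dtype={"chrom": str},
        )
        return cls(df)

    def to_bed(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", header=False, index=False)

    def assign(self, chrom: str, pos: int) -> tuple[str, int, int] | None:
        """Block containing the 1-based position ``pos``, or None.

        The BED convention makes a 1-based position p fall in the block whose
        half-open interval [start, end) contains p - 1.
        """
        entry = self._by_chrom.get(str(chrom))
        if entry is None:
            return None
        starts, ends = entry
        p0 = int(pos) - 1
        i = int(np.searchsorted(starts, p0, side="right")) - 1
        if i >= 0 and p0 < ends[i]:
            return (str(chrom), int(starts[i]), int(ends[i]))
        return None


def assign_block(position: tuple[str, int], blocks: LDBlockSet) -> tuple[str, int, int] | None:
    """Functional form of :meth:`LDBlockSet.assign`."""
    chrom, pos = position
    return blocks.assign(chrom, pos)
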