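"""Coordinate system and interval algebra shared by every pipeline stage.

All coordinates are 0-based, half-open (BED convention): an interval
``[start, end)`` covers ``end - start`` base pairs and two intervals that
merely abut (``a.end == b.start``) do not overlap.  Strand is carried for
promoter-window arithmetic but ignored by all overlap operators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeLayout",
    "Interval",
    "PeakSet",
    "overlap_bp",
    "overlap_fraction_of_b",
    "intersect_sets",
]

#: column order of the peak table backing a :class:`PeakSet`
PEAK_COLUMNS = ["chrom", "start", "end", "name", "score", "strand", "fold_enrichment", "summit"]


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths defining the coordinate space."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("chromosome names must be unique")
        if any(length <= 0 for length in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        object.__setattr__(self, "chrom_names", tuple(self.chrom_names))
        object.__setattr__(self, "chrom_lengths", tuple(int(x) for x in self.chrom_lengths))

    @classmethod
    def from_dict(cls, sizes: dict[str, int]) -> "GenomeLayout":
        return cls(tuple(sizes), tuple(sizes.values()))

    @property
    def sizes(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_lengths))

    def length_of(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[self.chrom_names.index(chrom)]
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_names


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def validate(self, layout: GenomeLayout) -> None:
        if self.chrom not in layout:
            raise ValueError(f"chromosome {self.chrom!r} not in genome layout")
        if self.end > layout.length_of(self.chrom):
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end} extends past "
                f"chromosome end ({layout.length_of(self.chrom)})"
            )


def overlap_bp(a: Interval, b: Interval) -> int:
    """Base pairs shared by two intervals (0 on different chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def overlap_fraction_of_b(a: Interval, b: Interval) -> float:
    """Fraction of ``b``'s length covered by ``a``, in [0, 1]."""
    return overlap_bp(a, b) / len(b)


@dataclass
class PeakSet:
    """Scored genomic intervals from one assay and genotype.

    Backed by a pandas DataFrame with columns ``chrom, start, end, name,
    score, strand, fold_enrichment, summit`` kept sorted by (chrom, start)
    in the layout's chromosome order.  ``score`` is a -log10 p or q value,
    ``fold_enrichment`` the observed/expected count ratio and ``summit`` a
    bp offset from ``start`` (-1 when unknown).
    """

    assay: str = ""
    genotype: str = ""
    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=PEAK_COLUMNS))
    layout: GenomeLayout | None = None

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col, default in (
            ("name", "."),
            ("score", 0.0),
            ("strand", "."),
            ("fold_enrichment", np.nan),
            ("summit", -1),
        ):
            if col not in df.columns:
                df[col] = default
        df = df[PEAK_COLUMNS]
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] < 0).any() or (df["end"] <= df["start"]).any():
            raise ValueError("peak set contains an invalid interval (end <= start or start < 0)")
        if self.layout is not None:
            for iv in df.itertuples(index=False):
                Interval(iv.chrom, iv.start, iv.end).validate(self.layout)
            order = {c: i for i, c in enumerate(self.layout.chrom_names)}
            df["_corder"] = df["chrom"].map(order)
            df = df.sort_values(["_corder", "start", "end"], kind="mergesort").drop(columns="_corder")
        else:
            df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals())

    def intervals(self) -> list[Interval]:
        return [
            Interval(r.chrom, int(r.start), int(r.end), r.strand if r.strand in "+-" else ".")
            for r in self.df.itertuples(index=False)
        ]

    def keys(self) -> set[tuple[str, int, int]]:
        """Site identities: exact (chrom, start, end) triples."""
        return set(zip(self.df["chrom"], self.df["start"].astype(int), self.df["end"].astype(int)))

    def subset(self, mask: Sequence[bool] | pd.Series) -> "PeakSet":
        return PeakSet(self.assay, self.genotype, self.df[np.asarray(mask, bool)], self.layout)

    @classmethod
    def from_intervals(
        cls,
        intervals: Iterable[Interval],
        assay: str = "",
        genotype: str = "",
        layout: GenomeLayout | None = None,
    ) -> "PeakSet":
        rows = [
            {"chrom": iv.chrom, "start": iv.start, "end": iv.end, "strand": iv.strand}
            for iv in intervals
        ]
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
        return cls(assay, genotype, df, layout)


def intersect_sets(
    a: PeakSet,
    b: PeakSet,
    min_bp: int = 1,
    min_frac_of_b: float = 0.0,
) -> PeakSet:
    """Peaks of ``a`` having at least one partner in ``b`` that satisfies
    BOTH thresholds: overlap >= ``min_bp`` and overlap >= ``min_frac_of_b``
    of the partner's length.

    Thresholds apply per partner, never summed across partners, so a site
    qualifies as soon as any single ``b`` peak clears them.  Each ``a``
    peak is reported at most once.  Sweep-line over the sorted tables,
    O(n + m + hits).
    """
    if len(a) == 0 or len(b) == 0:
        return a.subset([False] * len(a))
    keep = np.zeros(len(a), dtype=bool)
    b_by_chrom: dict[str, np.ndarray] = {
        chrom: grp[["start", "end"]].to_numpy(np.int64)
        for chrom, grp in b.df.groupby("chrom", sort=False)
    }
    for chrom, grp in a.df.groupby("chrom", sort=False):
        if chrom not in b_by_chrom:
            continue
        bs = b_by_chrom[chrom]
        j0 = 0
        for idx, a_start, a_end in zip(grp.index, grp["start"].to_numpy(), grp["end"].to_numpy()):
            # advance past b peaks that can never overlap later a peaks
            while j0 < len(bs) and bs[j0, 1] <= a_start:
                # safe only because a is start-sorted; a later a peak starts >= a_start
                j0 += 1
            j = j0
            while j < len(bs) and bs[j, 0] < a_end:
                ov = min(a_end, bs[j, 1]) - max(a_start, bs[j, 0])
                if ov >= min_bp and ov >= min_frac_of_b * (bs[j, 1] - bs[j, 0]):
                    keep[idx] = True
                    break
                j += 1
    return a.subset(keep)
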