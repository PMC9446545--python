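"""Normalized signal tracks and binned signal matrices around peak centers.

Mirrors the reference-point mode of deeptools computeMatrix: for every
site, the mean normalized signal in fixed-width bins across a window
centered on the peak midpoint (default +/-2 kb in 40-bp bins, i.e. 100
bins).  Windows are clipped at chromosome edges; a clipped bin averages
only the covered bases and a bin entirely off-chromosome reads 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome import GenomeLayout, Interval, PeakSet

__all__ = ["SignalTrack", "BinnedMatrix", "compute_matrix", "order_sites", "profile"]


@dataclass
class SignalTrack:
    """Stepped per-bp normalized signal (fold change over background).

    Dense per-chromosome arrays; positions outside any bedGraph step are 0.
    """

    assay: str
    genotype: str
    layout: GenomeLayout
    data: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom in self.layout.chrom_names:
            arr = np.asarray(self.data[chrom], dtype=np.float64)
            if arr.size != self.layout.length_of(chrom):
                raise ValueError(f"signal length mismatch on {chrom!r}")
            self.data[chrom] = arr

    def mean_over(self, chrom: str, start: int, end: int) -> float:
        """Mean per-bp signal on [start, end), clipped to the chromosome."""
        lo, hi = max(start, 0), min(end, self.layout.length_of(chrom))
        if hi <= lo:
            return 0.0
        return float(self.data[chrom][lo:hi].mean())


@dataclass
class BinnedMatrix:
    """sites x bins mean-signal matrix around peak centers."""

    sites: list[Interval]
    flank: int
    bin: int
    values: np.ndarray  # shape (n_sites, 2*flank//bin)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.sites), 2 * self.flank // self.bin):
            raise ValueError("matrix shape inconsistent with sites/flank/bin")
        if not np.isfinite(self.values).all():
            raise ValueError("matrix contains non-finite values")

    @property
    def n_bins(self) -> int:
        return 2 * self.flank // self.bin

    def row_stat(self, statistic: str) -> np.ndarray:
        if statistic == "mean":
            return self.values.mean(axis=1)
        if statistic == "median":
            return np.median(self.values, axis=1)
        raise ValueError(f"unknown statistic {statistic!r}")

    def to_tsv(self, path: str | Path) -> None:
        """Site id + one column per bin, plain TSV (gzip if path ends .gz)."""
        import gzip

        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "wt") as fh:
            header = ["site"] + [f"bin{i}" for i in range(self.n_bins)]
            fh.write("\t".join(header) + "\n")
            for site, row in zip(self.sites, self.values):
                sid = f"{site.chrom}:{site.start}-{site.end}"
                fh.write(sid + "\t" + "\t".join(format(v, ".6g") for v in row) + "\n")


def compute_matrix(
    track: SignalTrack,
    sites: PeakSet | Sequence[Interval],
    flank: int = 2000,
    bin: int = 40,
) -> BinnedMatrix:
    """Bin the signal around each site's center (floor of the midpoint).

    Default 40-bp bins across center +/- 2 kb -> 100 bins per site.
    """
    if (2 * flank) % bin != 0:
        raise ValueError("bin width must divide the full window (2*flank)")
    site_list = sites.intervals() if isinstance(sites, PeakSet) else list(sites)
    if not site_list:
        raise ValueError("no sites given")
    n_bins = 2 * flank // bin
    values = np.zeros((len(site_list), n_bins))
    for i, site in enumerate(site_list):
        chrom_len = track.layout.length_of(site.chrom)
        arr = track.data[site.chrom]
        w_start = site.center - flank
        for j in range(n_bins):
            lo = max(w_start + j * bin, 0)
            hi = min(w_start + (j + 1) * bin, chrom_len)
            if hi > lo:
                values[i, j] = arr[lo:hi].mean()
    return BinnedMatrix(site_list, flank, bin, values)


def order_sites(
    matrices: Sequence[BinnedMatrix],
    statistic: str = "mean",
    across: str = "all_samples",
    sample_index: int = 0,
) -> np.ndarray:
    """Permutation of site indices, descending by a per-site signal statistic.

    ``across='all_samples'`` ranks by the mean over all matrices of the
    per-matrix row statistic (heatmap-panel ordering); ``'named_sample'``
    ranks by the statistic of ``matrices[sample_index]`` alone.  Ties break
    by genomic position (chrom, start) ascending.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    ref_sites = matrices[0].sites
    for m in matrices[1:]:
        if [(s.chrom, s.start, s.end) for s in m.sites] != [
            (s.chrom, s.start, s.end) for s in ref_sites
        ]:
            raise ValueError("matrices are not row-aligned over the same sites")
    if across == "all_samples":
        stat = np.mean([m.row_stat(statistic) for m in matrices], axis=0)
    elif across == "named_sample":
        stat = matrices[sample_index].row_stat(statistic)
    else:
        raise ValueError(f"unknown across mode {across!r}")
    keys = [(-stat[i], s.chrom, s.start) for i, s in enumerate(ref_sites)]
    return np.array(sorted(range(len(ref_sites)), key=lambda i: keys[i]), dtype=np.int64)


def profile(matrix: BinnedMatrix) -> np.ndarray:
    """Meta-profile: per-bin mean across all sites."""
    if matrix.values.shape[0] == 0:
        raise ValueError("empty matrix")
    return matrix.values.mean(axis=0)


def plot_heatmap(
    matrices: Sequence[BinnedMatrix],
    labels: Sequence[str],
    path: str | Path,
    order: np.ndarray | None = None,
) -> None:
    """Side-by-side heatmap panels (sites descending by `order`), for docs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if order is None:
        order = order_sites(matrices)
    fig, axes = plt.subplots(1, len(matrices), figsize=(2.2 * len(matrices), 6), squeeze=False)
    for ax, m, label in zip(axes[0], matrices, labels):
        ax.imshow(m.values[order], aspect="auto", cmap="Reds", interpolation="nearest")
        ax.set_title(label, fontsize=8)
        ax.set_xticks([0, m.n_bins // 2, m.n_bins])
        ax.set_xticklabels([f"-{m.flank // 1000}kb", "center", f"+{m.flank // 1000}kb"], fontsize=6)
        ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
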