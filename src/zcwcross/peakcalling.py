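"""Windowed Poisson fold-enrichment peak caller.

The caller slides a fixed window over fragment coverage, tests each window
count against a Poisson background expectation lambda (genome-wide, or a
local flank estimate floored at the genome-wide value), corrects for
multiple testing when a q-threshold is configured, merges significant
windows into peaks, and discards peaks whose fold enrichment (max window
count over its lambda) does not strictly exceed the per-assay threshold.

Per-assay presets mirror the published calling settings:

========== =========== ============ ============= ================
preset      threshold   background   FE filter     assay
========== =========== ============ ============= ================
zcwpw1_chip p < 0.001   genome       FE > 3        ZCWPW1 ChIP-seq
h3k9ac_chip q < 0.05    genome       none          H3K9ac ChIP-seq
cutandtag   q < 0.01    genome       FE > 10       CUT&Tag
atac        q < 0.01    local 10 kb  FE > 4        ATAC-seq
========== =========== ============ ============= ================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import GenomeLayout, PeakSet
from .tracks import SignalTrack

__all__ = [
    "CoverageTrack",
    "CallerConfig",
    "PRESETS",
    "window_scan",
    "call_peaks",
    "normalize_fold_change",
]


@dataclass
class CoverageTrack:
    """Per-bp fragment coverage for one assay and genotype.

    ``data`` maps chromosome name to a dense non-negative array covering
    every base of the layout.
    """

    assay: str
    genotype: str
    layout: GenomeLayout
    data: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom in self.layout.chrom_names:
            if chrom not in self.data:
                raise ValueError(f"coverage missing chromosome {chrom!r}")
            arr = np.asarray(self.data[chrom], dtype=np.float64)
            if arr.size != self.layout.length_of(chrom):
                raise ValueError(f"coverage length mismatch on {chrom!r}")
            if (arr < 0).any():
                raise ValueError("coverage values must be non-negative")
            self.data[chrom] = arr

    @property
    def total(self) -> float:
        return float(sum(self.data[c].sum() for c in self.layout.chrom_names))

    def mean_rate(self) -> float:
        """Genome-wide mean coverage per bp."""
        return self.total / self.layout.total_length


@dataclass(frozen=True)
class CallerConfig:
    """Window-scan settings; ``p_threshold`` and ``q_threshold`` are mutually
    exclusive (q triggers Benjamini-Hochberg over all scanned windows)."""

    window: int = 200
    step: int = 50
    p_threshold: float | None = None
    q_threshold: float | None = 0.05
    min_fold_enrichment: float = 0.0
    local_lambda_flank: int | None = None  # bp of flank each side; None = genome lambda
    merge_gap: int = 100
    genome_lambda: float | None = None  # expected count per window; None = estimate from track

    def __post_init__(self) -> None:
        if self.step <= 0 or self.window < self.step:
            raise ValueError("require window >= step > 0")
        if (self.p_threshold is None) == (self.q_threshold is None):
            raise ValueError("exactly one of p_threshold / q_threshold must be set")
        thr = self.p_threshold if self.p_threshold is not None else self.q_threshold
        if not 0 < thr < 1:
            raise ValueError("significance threshold must lie in (0, 1)")
        if self.min_fold_enrichment < 0:
            raise ValueError("min_fold_enrichment must be >= 0")


PRESETS: dict[str, CallerConfig] = {
    "zcwpw1_chip": CallerConfig(p_threshold=0.001, q_threshold=None, min_fold_enrichment=3.0),
    "h3k9ac_chip": CallerConfig(q_threshold=0.05, min_fold_enrichment=0.0),
    "cutandtag": CallerConfig(q_threshold=0.01, min_fold_enrichment=10.0),
    "atac": CallerConfig(q_threshold=0.01, min_fold_enrichment=4.0, local_lambda_flank=10_000),
}


def window_scan(track: CoverageTrack, cfg: CallerConfig) -> pd.DataFrame:
    """Scan fixed windows and test counts against the Poisson background.

    Returns one row per window: ``chrom, start, end, count, lam, p``,
    where ``p`` is the upper tail P(X >= count | lam).  With
    ``local_lambda_flank`` set, lambda is the mean count expected from the
    +/-flank region around the window (window itself excluded), floored at
    the genome-wide lambda.
    """
    if cfg.window > min(track.layout.chrom_lengths):
        raise ValueError("window larger than the smallest chromosome")
    genome_lam = (
        cfg.genome_lambda
        if cfg.genome_lambda is not None
        else track.mean_rate() * cfg.window
    )
    frames = []
    for chrom in track.layout.chrom_names:
        values = track.data[chrom]
        length = values.size
        csum = np.concatenate(([0.0], np.cumsum(values)))
        starts = np.arange(0, length - cfg.window + 1, cfg.step, dtype=np.int64)
        ends = starts + cfg.window
        counts = csum[ends] - csum[starts]
        if cfg.local_lambda_flank:
            lo = np.maximum(starts - cfg.local_lambda_flank, 0)
            hi = np.minimum(ends + cfg.local_lambda_flank, length)
            flank_sum = (csum[hi] - csum[lo]) - counts
            flank_len = (hi - lo) - cfg.window
            lam = np.maximum(flank_sum / flank_len * cfg.window, genome_lam)
        else:
            lam = np.full(starts.size, genome_lam)
        p = stats.poisson.sf(np.round(counts) - 1, lam)
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends, "count": counts, "lam": lam, "p": p}
            )
        )
    return pd.concat(frames, ignore_index=True)


def call_peaks(track: CoverageTrack, cfg: CallerConfig) -> PeakSet:
    """Call peaks: significant windows merged across gaps <= ``merge_gap``,
    annotated with fold enrichment and filtered at strict
    ``fold_enrichment > min_fold_enrichment``."""
    windows = window_scan(track, cfg)
    if cfg.q_threshold is not None:
        reject, qvals, _, _ = multipletests(windows["p"], alpha=cfg.q_threshold, method="fdr_bh")
        windows = windows.assign(sig=reject, stat=qvals)
    else:
        windows = windows.assign(sig=windows["p"] < cfg.p_threshold, stat=windows["p"])

    rows = []
    for chrom, grp in windows.groupby("chrom", sort=False):
        sig = grp[grp["sig"]]
        if sig.empty:
            continue
        starts = sig["start"].to_numpy()
        ends = sig["end"].to_numpy()
        counts = sig["count"].to_numpy()
        lams = sig["lam"].to_numpy()
        stats_ = sig["stat"].to_numpy()
        # merge windows whose gap is <= merge_gap
        breaks = np.nonzero(starts[1:] - ends[:-1] > cfg.merge_gap)[0] + 1
        for block in np.split(np.arange(starts.size), breaks):
            fe_windows = counts[block] / lams[block]
            best = block[int(np.argmax(fe_windows))]
            fe = float(np.max(fe_windows))
            if fe <= cfg.min_fold_enrichment:
                continue
            score = float(-np.log10(max(stats_[block].min(), 1e-300)))
            peak_start = int(starts[block[0]])
            rows.append(
                {
                    "chrom": chrom,
                    "start": peak_start,
                    "end": int(ends[block[-1]]),
                    "name": ".",
                    "score": score,
                    "strand": ".",
                    "fold_enrichment": fe,
                    "summit": int((starts[best] + ends[best]) // 2 - peak_start),
                }
            )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand", "fold_enrichment", "summit"])
    peaks = PeakSet(track.assay, track.genotype, df, track.layout)
    peaks.df["name"] = [f"{track.assay or 'peak'}_{i + 1}" for i in range(len(peaks))]
    return peaks


def normalize_fold_change(
    treatment: CoverageTrack,
    control: float | CoverageTrack,
    pseudocount: float = 0.0,
) -> SignalTrack:
    """Per-bp fold change of treatment over a control expectation.

    ``control`` is either a scalar per-bp lambda (genome background) or a
    coverage track; the value at each base is
    ``treatment / (control + pseudocount)``.  A zero control anywhere
    requires a positive pseudocount.
    """
    data: dict[str, np.ndarray] = {}
    for chrom in treatment.layout.chrom_names:
        t = treatment.data[chrom]
        c = control.data[chrom] if isinstance(control, CoverageTrack) else np.full(t.size, float(control))
        denom = c + pseudocount
        if (denom <= 0).any():
            raise ValueError("control is zero somewhere and pseudocount is not positive")
        data[chrom] = t / denom
    return SignalTrack(treatment.assay, treatment.genotype, treatment.layout, data)
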