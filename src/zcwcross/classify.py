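"""Cross-talk classification of ZCWPW1 binding sites.

Every ZCWPW1 binding site (a WT ZCWPW1 peak) is labelled along two axes by
comparing wild-type and Zcwpw1-knockout chromatin:

* H3K9ac axis — a site is *marked* if it overlaps a WT H3K9ac peak by at
  least 1 bp.  Marked sites split into group **H1** (acetylation lost in
  the knockout) and group **H2** (retained): a site retains H3K9ac only if
  it still overlaps a knockout H3K9ac peak and its WT/KO mean-signal ratio
  stays below the loss threshold (default 2-fold); failing either
  criterion puts it in H1.
* accessibility axis — a site is *open* if it overlaps at least 20% of a
  WT ATAC peak (fraction measured on the ATAC peak's length, inclusive).
  Open sites split into group **A1** (accessibility lost: WT ATAC signal
  at least 2-fold above KO) and **A2** (retained).

Sites are also flagged as promoter-proximal when they touch a strand-aware
TSS window (default -2000/+500 bp).  Site identity across every stage is
the exact (chrom, start, end) of the ZCWPW1 peak.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import json

import numpy as np
import pandas as pd

from .genome import Interval, PeakSet, intersect_sets, overlap_bp
from .tracks import SignalTrack

__all__ = [
    "mark_h3k9ac",
    "find_open_sites",
    "classify_atac_loss",
    "classify_h3k9ac_loss",
    "joint_loss",
    "annotate_promoters",
    "classify_sites",
    "summarize",
    "ClassificationReport",
    "percent",
]


def percent(numerator: int, denominator: int, decimals: int = 0) -> float:
    """Percentage rounded half-up to ``decimals`` places; 0 for empty denominators."""
    if denominator == 0:
        return 0.0
    quantum = Decimal(1).scaleb(-decimals)
    value = (Decimal(numerator) * 100 / Decimal(denominator)).quantize(
        quantum, rounding=ROUND_HALF_UP
    )
    return float(value)


def mark_h3k9ac(zcwpw1: PeakSet, h3k9ac_wt: PeakSet) -> PeakSet:
    """ZCWPW1 sites overlapping a WT H3K9ac peak by >= 1 bp ("marked")."""
    return intersect_sets(zcwpw1, h3k9ac_wt, min_bp=1, min_frac_of_b=0.0)


def find_open_sites(
    zcwpw1: PeakSet,
    atac_wt: PeakSet,
    min_frac: float = 0.2,
    fraction_of: str = "atac",
) -> PeakSet:
    """ZCWPW1 sites covering >= ``min_frac`` of some WT ATAC peak ("open").

    The fraction is measured on the ATAC peak's length by default;
    ``fraction_of='site'`` switches the denominator to the ZCWPW1 peak.
    """
    if fraction_of == "atac":
        return intersect_sets(zcwpw1, atac_wt, min_bp=1, min_frac_of_b=min_frac)
    if fraction_of == "site":
        atac_ivs = atac_wt.intervals()
        keep = []
        for site in zcwpw1.intervals():
            frac = max(
                (overlap_bp(site, p) / len(site) for p in atac_ivs if p.chrom == site.chrom),
                default=0.0,
            )
            keep.append(frac >= min_frac and frac > 0)
        return zcwpw1.subset(keep)
    raise ValueError(f"unknown fraction_of mode {fraction_of!r}")


def _mean_ratio(
    site: Interval,
    wt: SignalTrack,
    ko: SignalTrack,
    pseudocount: float = 0.01,
) -> float:
    wt_mean = wt.mean_over(site.chrom, site.start, site.end)
    ko_mean = ko.mean_over(site.chrom, site.start, site.end)
    return wt_mean / (ko_mean + pseudocount)


def classify_atac_loss(
    open_sites: PeakSet,
    atac_wt_signal: SignalTrack,
    atac_ko_signal: SignalTrack,
    loss_ratio: float = 2.0,
    pseudocount: float = 0.01,
) -> tuple[PeakSet, PeakSet]:
    """Partition open sites into (A1 lost, A2 retained).

    A site loses accessibility when its WT mean ATAC signal is at least
    ``loss_ratio``-fold the knockout mean (inclusive >=).
    """
    lost = [
        _mean_ratio(site, atac_wt_signal, atac_ko_signal, pseudocount) >= loss_ratio
        for site in open_sites.intervals()
    ]
    lost = np.array(lost, dtype=bool) if lost else np.zeros(0, bool)
    return open_sites.subset(lost), open_sites.subset(~lost)


def classify_h3k9ac_loss(
    marked_sites: PeakSet,
    h3k9ac_ko_peaks: PeakSet | None,
    h3k9ac_wt_signal: SignalTrack,
    h3k9ac_ko_signal: SignalTrack,
    loss_ratio: float = 2.0,
    pseudocount: float = 0.01,
    require_ko_peak: bool = True,
    require_ratio: bool = True,
) -> tuple[PeakSet, PeakSet]:
    """Partition marked sites into (H1 lost, H2 retained).

    Retention (H2) demands every enabled criterion: overlap with a
    knockout H3K9ac peak by >= 1 bp, and a WT/KO mean-signal ratio below
    ``loss_ratio``.  Anything else is loss (H1).
    """
    retained = np.ones(len(marked_sites), dtype=bool)
    if require_ko_peak:
        if h3k9ac_ko_peaks is None:
            raise ValueError("require_ko_peak=True needs the knockout peak set")
        ko_keys = intersect_sets(marked_sites, h3k9ac_ko_peaks, min_bp=1).keys()
        has_peak = [
            (r.chrom, int(r.start), int(r.end)) in ko_keys
            for r in marked_sites.df.itertuples(index=False)
        ]
        retained &= np.array(has_peak, dtype=bool) if has_peak else np.zeros(0, bool)
    if require_ratio:
        below = [
            _mean_ratio(site, h3k9ac_wt_signal, h3k9ac_ko_signal, pseudocount) < loss_ratio
            for site in marked_sites.intervals()
        ]
        retained &= np.array(below, dtype=bool) if below else np.zeros(0, bool)
    return marked_sites.subset(~retained), marked_sites.subset(retained)


def joint_loss(a1: PeakSet, h1: PeakSet) -> tuple[int, float]:
    """Count and fraction of A1 sites that are also H1 (by site identity)."""
    inter = a1.keys() & h1.keys()
    if len(a1) == 0:
        return 0, 0.0
    return len(inter), len(inter) / len(a1)


def annotate_promoters(
    sites: PeakSet,
    tss: list[tuple[str, int, str]],
    window_upstream: int = 2000,
    window_downstream: int = 500,
) -> np.ndarray:
    """Boolean promoter flag per site: overlap >= 1 bp with any strand-aware
    TSS window [TSS - upstream, TSS + downstream) (mirrored on '-')."""
    if not tss:
        raise ValueError("TSS list is empty")
    windows: dict[str, list[tuple[int, int]]] = {}
    for chrom, pos, strand in tss:
        if strand == "-":
            lo, hi = pos - window_downstream, pos + window_upstream
        else:
            lo, hi = pos - window_upstream, pos + window_downstream
        windows.setdefault(chrom, []).append((max(lo, 0), hi))
    flags = np.zeros(len(sites), dtype=bool)
    for i, site in enumerate(sites.intervals()):
        for lo, hi in windows.get(site.chrom, ()):
            if min(site.end, hi) - max(site.start, lo) >= 1:
                flags[i] = True
                break
    return flags


@dataclass(frozen=True)
class ClassificationReport:
    """Counts of the classification groups; percentages are always derived
    from the counts (never stored) with half-up rounding."""

    n_sites: int
    n_marked: int
    n_h1: int
    n_h2: int
    n_open: int
    n_a1: int
    n_a2: int
    n_joint: int
    n_h1_promoter: int = 0
    n_h2_promoter: int = 0
    n_a1_promoter: int = 0
    n_a2_promoter: int = 0

    def __post_init__(self) -> None:
        if self.n_h1 + self.n_h2 != self.n_marked:
            raise ValueError("H1/H2 do not partition the marked sites")
        if self.n_a1 + self.n_a2 != self.n_open:
            raise ValueError("A1/A2 do not partition the open sites")
        if self.n_joint > min(self.n_a1, self.n_h1):
            raise ValueError("joint-loss count exceeds one of its parent groups")

    @property
    def fractions(self) -> dict[str, float]:
        return {
            "marked_percent": percent(self.n_marked, self.n_sites),
            "open_percent": percent(self.n_open, self.n_sites),
            "h1_percent": percent(self.n_h1, self.n_marked),
            "h2_percent": percent(self.n_h2, self.n_marked),
            "a1_percent": percent(self.n_a1, self.n_open),
            "a2_percent": percent(self.n_a2, self.n_open),
            "joint_loss_percent": percent(self.n_joint, self.n_a1),
            "h1_promoter_percent": percent(self.n_h1_promoter, self.n_h1, 1),
            "h2_promoter_percent": percent(self.n_h2_promoter, self.n_h2, 1),
            "a1_promoter_percent": percent(self.n_a1_promoter, self.n_a1, 1),
            "a2_promoter_percent": percent(self.n_a2_promoter, self.n_a2, 1),
        }

    def to_dict(self) -> dict:
        counts = {
            "n_sites": self.n_sites,
            "n_marked": self.n_marked,
            "n_h1": self.n_h1,
            "n_h2": self.n_h2,
            "n_open": self.n_open,
            "n_a1": self.n_a1,
            "n_a2": self.n_a2,
            "n_joint": self.n_joint,
            "n_h1_promoter": self.n_h1_promoter,
            "n_h2_promoter": self.n_h2_promoter,
            "n_a1_promoter": self.n_a1_promoter,
            "n_a2_promoter": self.n_a2_promoter,
        }
        return {"counts": counts, "fractions": self.fractions}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def summarize(labels: pd.DataFrame) -> ClassificationReport:
    """Fold a per-site label table into a :class:`ClassificationReport`.

    Expects columns ``h3k9ac_status`` in {H1, H2, unmarked}, ``atac_status``
    in {A1, A2, closed} and boolean ``promoter``.
    """
    h, a = labels["h3k9ac_status"], labels["atac_status"]
    prom = labels["promoter"].astype(bool) if "promoter" in labels else pd.Series(False, index=labels.index)
    return ClassificationReport(
        n_sites=len(labels),
        n_marked=int(h.isin(["H1", "H2"]).sum()),
        n_h1=int((h == "H1").sum()),
        n_h2=int((h == "H2").sum()),
        n_open=int(a.isin(["A1", "A2"]).sum()),
        n_a1=int((a == "A1").sum()),
        n_a2=int((a == "A2").sum()),
        n_joint=int(((h == "H1") & (a == "A1")).sum()),
        n_h1_promoter=int(((h == "H1") & prom).sum()),
        n_h2_promoter=int(((h == "H2") & prom).sum()),
        n_a1_promoter=int(((a == "A1") & prom).sum()),
        n_a2_promoter=int(((a == "A2") & prom).sum()),
    )


def classify_sites(
    zcwpw1: PeakSet,
    h3k9ac_wt_peaks: PeakSet,
    h3k9ac_ko_peaks: PeakSet,
    atac_wt_peaks: PeakSet,
    h3k9ac_wt_signal: SignalTrack,
    h3k9ac_ko_signal: SignalTrack,
    atac_wt_signal: SignalTrack,
    atac_ko_signal: SignalTrack,
    tss: list[tuple[str, int, str]] | None = None,
    open_frac: float = 0.2,
    loss_ratio: float = 2.0,
    promoter_window: tuple[int, int] = (2000, 500),
) -> pd.DataFrame:
    """End-to-end per-site labelling; returns one row per ZCWPW1 site with
    ``h3k9ac_status``, ``atac_status``, ``promoter`` and per-assay mean
    signals."""
    marked = mark_h3k9ac(zcwpw1, h3k9ac_wt_peaks)
    open_ = find_open_sites(zcwpw1, atac_wt_peaks, min_frac=open_frac)
    h1, h2 = classify_h3k9ac_loss(
        marked, h3k9ac_ko_peaks, h3k9ac_wt_signal, h3k9ac_ko_signal, loss_ratio=loss_ratio
    )
    a1, a2 = classify_atac_loss(open_, atac_wt_signal, atac_ko_signal, loss_ratio=loss_ratio)
    h1_keys, h2_keys = h1.keys(), h2.keys()
    a1_keys, a2_keys = a1.keys(), a2.keys()

    rows = []
    for site in zcwpw1.intervals():
        key = (site.chrom, site.start, site.end)
        h_status = "H1" if key in h1_keys else "H2" if key in h2_keys else "unmarked"
        a_status = "A1" if key in a1_keys else "A2" if key in a2_keys else "closed"
        rows.append(
            {
                "chrom": site.chrom,
                "start": site.start,
                "end": site.end,
                "h3k9ac_status": h_status,
                "atac_status": a_status,
                "h3k9ac_wt_mean": h3k9ac_wt_signal.mean_over(site.chrom, site.start, site.end),
                "h3k9ac_ko_mean": h3k9ac_ko_signal.mean_over(site.chrom, site.start, site.end),
                "atac_wt_mean": atac_wt_signal.mean_over(site.chrom, site.start, site.end),
                "atac_ko_mean": atac_ko_signal.mean_over(site.chrom, site.start, site.end),
            }
        )
    labels = pd.DataFrame(rows)
    if tss:
        labels["promoter"] = annotate_promoters(zcwpw1, tss, *promoter_window)
    else:
        labels["promoter"] = False
    return labels
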