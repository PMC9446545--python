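"""Seeded synthetic data with known ground truth.

The generator emulates the genotype structure of the knockout study at
desk scale: a small multi-chromosome genome carrying two classes of
planted ZCWPW1 binding sites.

* **hotspot-class** sites behave like meiotic recombination hotspots:
  strong ZCWPW1/DMC1 enrichment in WT, H3K9ac and ATAC enrichment where
  the truth labels say so, H3K9ac/ATAC attenuated in the *Zcwpw1* knockout
  at the designated loss sites, all hotspot enrichment absent in the
  *Prdm9* knockout, and DMC1 absent (only) in the *Spo11* knockout.
* **promoter-class** sites sit on a TSS and keep their H3K9ac/ATAC
  enrichment in every genotype.

Coverage is Poisson fragment noise drawn at 10-bp resolution and expanded
to per-bp rates, so window counts behave like true Poisson counts with
per-bp mean equal to ``background_rate`` in unenriched regions.

The default group fractions are the study's printed group fractions: 45%
of sites H3K9ac-marked, 27.3% open, 74%/67% of marked/open sites losing
H3K9ac/accessibility in the knockout, and 84% of accessibility-losing
sites also losing H3K9ac.  The generator turns those fractions into exact
integer per-class counts, so the planted truth reproduces them up to
rounding at any site count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeLayout, PeakSet
from .io import write_bed, write_bedgraph, write_chrom_sizes, write_tss
from .peakcalling import CoverageTrack, normalize_fold_change
from .tracks import SignalTrack

__all__ = ["SimConfig", "SimResult", "simulate", "make_rime_table"]

ASSAYS = ("zcwpw1", "h3k9ac", "atac", "dmc1")
GENOTYPES = ("WT", "Zcwpw1KO", "Prdm9KO", "Spo11KO")

DEFAULT_LAYOUT = GenomeLayout(("chr1", "chr2", "chr3"), (2_000_000, 2_000_000, 2_000_000))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic genome.

    Enrichment values are fold over background at planted sites;
    ``ko_multiplier`` scales the enrichment of losing sites in the
    *Zcwpw1* knockout.  The ``*_fraction`` fields are the target group
    fractions (over all sites for marked/open, over the marked/open sets
    for the loss groups) from which exact per-class site counts are
    derived.
    """

    layout: GenomeLayout = DEFAULT_LAYOUT
    n_hotspot_sites: int = 274
    n_promoter_sites: int = 26
    site_width: int = 600
    min_site_gap: int = 5_000
    background_rate: float = 0.1  # fragments per bp
    resolution: int = 10  # bp per Poisson draw
    enrichment: dict[str, float] = field(
        default_factory=lambda: {"zcwpw1": 12.0, "h3k9ac": 8.0, "atac": 8.0, "dmc1": 10.0}
    )
    promoter_zcwpw1_enrichment: float = 6.0
    ko_multiplier: float = 0.2  # residual enrichment at losing sites in Zcwpw1KO
    marked_fraction: float = 0.45
    open_fraction: float = 4015 / 14688
    h3k9ac_loss_fraction: float = 0.74
    atac_loss_fraction: float = 0.67
    joint_loss_fraction: float = 0.84
    n_decoy_tss: int = 30
    seed: int = 42

    def __post_init__(self) -> None:
        n_sites = self.n_hotspot_sites + self.n_promoter_sites
        if n_sites * self.site_width >= self.layout.total_length / 2:
            raise ValueError("sites would cover more than half the genome")
        for name in ("marked_fraction", "open_fraction", "h3k9ac_loss_fraction",
                     "atac_loss_fraction", "joint_loss_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if any(v < 0 for v in self.enrichment.values()) or self.ko_multiplier < 0:
            raise ValueError("multipliers must be >= 0")


def _derive_counts(cfg: SimConfig) -> dict[str, int]:
    """Exact per-class site counts realizing the configured fractions.

    Promoter-class sites are always marked, open and retaining, so the
    loss groups live entirely on hotspot-class sites; infeasible fraction
    combinations raise.
    """
    n_total = cfg.n_hotspot_sites + cfg.n_promoter_sites
    n_marked = round(cfg.marked_fraction * n_total)
    n_open = round(cfg.open_fraction * n_total)
    n_h1 = round(cfg.h3k9ac_loss_fraction * n_marked)
    n_a1 = round(cfg.atac_loss_fraction * n_open)
    n_joint = round(cfg.joint_loss_fraction * n_a1)
    n_h2_hot = (n_marked - n_h1) - cfg.n_promoter_sites
    n_a2_hot = (n_open - n_a1) - cfg.n_promoter_sites
    n_h1_only = n_h1 - n_joint
    n_a1_only = n_a1 - n_joint
    n_plain = cfg.n_hotspot_sites - (n_joint + n_h1_only + n_h2_hot + n_a1_only)
    counts = {
        "joint": n_joint,          # marked H1 + open A1
        "h1_only": n_h1_only,      # marked H1, closed
        "h2_hot": n_h2_hot,        # marked H2 (n_a2_hot of them also open A2)
        "a2_hot": n_a2_hot,
        "a1_only": n_a1_only,      # unmarked, open A1
        "plain": n_plain,          # ZCWPW1-only
    }
    if min(counts.values()) < 0 or n_a2_hot > n_h2_hot or n_joint > min(n_h1, n_a1):
        raise ValueError(f"infeasible group-fraction combination: {counts}")
    return counts


def _assign_truth(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-site truth labels (before placement), in random order."""
    counts = _derive_counts(cfg)
    rows = []

    def add(n: int, klass: str, h: str, a: str) -> None:
        rows.extend({"class": klass, "h_label": h, "a_label": a} for _ in range(n))

    add(counts["joint"], "hotspot", "H1", "A1")
    add(counts["h1_only"], "hotspot", "H1", "closed")
    add(counts["a2_hot"], "hotspot", "H2", "A2")
    add(counts["h2_hot"] - counts["a2_hot"], "hotspot", "H2", "closed")
    add(counts["a1_only"], "hotspot", "unmarked", "A1")
    add(counts["plain"], "hotspot", "unmarked", "closed")
    add(cfg.n_promoter_sites, "promoter", "H2", "A2")
    truth = pd.DataFrame(rows)
    return truth.iloc[rng.permutation(len(truth))].reset_index(drop=True)


def _place_sites(cfg: SimConfig, n: int, rng: np.random.Generator) -> list[tuple[str, int, int]]:
    """Uniform random non-overlapping placement, >= min_site_gap apart,
    starts aligned to the simulation resolution."""
    placed: dict[str, list[int]] = {c: [] for c in cfg.layout.chrom_names}
    out: list[tuple[str, int, int]] = []
    lengths = np.array(cfg.layout.chrom_lengths, dtype=np.float64)
    probs = lengths / lengths.sum()
    margin = cfg.site_width + cfg.min_site_gap
    for _ in range(n):
        for _attempt in range(10_000):
            chrom = cfg.layout.chrom_names[rng.choice(len(probs), p=probs)]
            limit = cfg.layout.length_of(chrom) - margin
            start = int(rng.integers(cfg.min_site_gap, limit)) // cfg.resolution * cfg.resolution
            if all(abs(start - other) >= margin for other in placed[chrom]):
                placed[chrom].append(start)
                out.append((chrom, start, start + cfg.site_width))
                break
        else:
            raise RuntimeError("could not place sites; genome too crowded")
    return out


def _multiplier(cfg: SimConfig, assay: str, genotype: str, row: pd.Series) -> float:
    """Enrichment multiplier over background for one site/assay/genotype."""
    enr = cfg.enrichment[assay]
    promoter = row["class"] == "promoter"
    if assay == "zcwpw1":
        base = cfg.promoter_zcwpw1_enrichment if promoter else enr
        if genotype == "Zcwpw1KO":
            return 1.0  # the protein itself is gone
        if genotype == "Prdm9KO":
            return base if promoter else 1.0
        return base
    if assay == "dmc1":
        if promoter or genotype == "Spo11KO":
            return 1.0
        if genotype == "Prdm9KO":
            return 1.0
        return enr
    # h3k9ac / atac
    label = row["h_label"] if assay == "h3k9ac" else row["a_label"]
    present = label in ("H1", "H2", "A1", "A2")
    if not present:
        return 1.0
    if promoter:
        return enr  # persists in every genotype
    if genotype == "Prdm9KO":
        return 1.0  # hotspot enrichment never established
    if genotype == "Zcwpw1KO" and label in ("H1", "A1"):
        return max(1.0, enr * cfg.ko_multiplier)
    return enr


@dataclass
class SimResult:
    """Everything one simulation produced, plus the planted truth."""

    config: SimConfig
    truth: pd.DataFrame  # chrom,start,end,class,h_label,a_label
    coverage: dict[tuple[str, str], CoverageTrack]  # (assay, genotype) -> track
    tss: list[tuple[str, int, str]]

    @property
    def layout(self) -> GenomeLayout:
        return self.config.layout

    def truth_sites(self) -> PeakSet:
        """Planted site intervals as a PeakSet (caller-independent shortcut)."""
        return PeakSet("zcwpw1_truth", "WT", self.truth[["chrom", "start", "end"]].copy(), self.layout)

    def signal(self, assay: str, genotype: str) -> SignalTrack:
        """Fold-change track: coverage over the genome-wide background rate."""
        track = self.coverage[(assay, genotype)]
        return normalize_fold_change(track, self.config.background_rate)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_chrom_sizes(self.layout, outdir / "genome.chrom.sizes")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        write_tss(self.tss, outdir / "tss.tsv")
        write_bed(self.truth_sites(), outdir / "planted_sites.bed")
        for (assay, genotype), track in self.coverage.items():
            write_bedgraph(track.data, outdir / f"{assay}_{genotype}.coverage.bedGraph", self.layout)


def _simulate_coverage(
    cfg: SimConfig,
    truth: pd.DataFrame,
    assay: str,
    genotype: str,
    rng: np.random.Generator,
) -> CoverageTrack:
    res = cfg.resolution
    data: dict[str, np.ndarray] = {}
    rates: dict[str, np.ndarray] = {}
    for chrom in cfg.layout.chrom_names:
        n_bins = -(-cfg.layout.length_of(chrom) // res)
        rates[chrom] = np.full(n_bins, cfg.background_rate * res)
    for _, row in truth.iterrows():
        mult = _multiplier(cfg, assay, genotype, row)
        if mult != 1.0:
            rates[row["chrom"]][row["start"] // res : row["end"] // res] *= mult
    for chrom in cfg.layout.chrom_names:
        draws = rng.poisson(rates[chrom]).astype(np.float64)
        expanded = np.repeat(draws, res)[: cfg.layout.length_of(chrom)] / res
        data[chrom] = expanded
    return CoverageTrack(assay, genotype, cfg.layout, data)


# fixed child-stream keys so adding one track never perturbs the others
_PAIR_KEY = {(a, g): 10 * ai + gi for ai, a in enumerate(ASSAYS) for gi, g in enumerate(GENOTYPES)}
_PLACEMENT_KEY, _TSS_KEY, _RIME_KEY = 900, 901, 902


def _child_rng(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def simulate(
    config: SimConfig = SimConfig(),
    pairs: list[tuple[str, str]] | None = None,
) -> SimResult:
    """Generate the synthetic study: planted sites with truth labels, TSS
    annotation and Poisson coverage for every requested (assay, genotype)
    pair (default: all 16).  Identical config and seed give identical
    output, track by track."""
    cfg = config
    rng_place = _child_rng(cfg.seed, _PLACEMENT_KEY)
    truth = _assign_truth(cfg, rng_place)
    n_sites = len(truth)
    coords = _place_sites(cfg, n_sites + cfg.n_decoy_tss, rng_place)
    site_coords, decoy_coords = coords[:n_sites], coords[n_sites:]
    truth = truth.assign(
        chrom=[c for c, _, _ in site_coords],
        start=[s for _, s, _ in site_coords],
        end=[e for _, _, e in site_coords],
    )[["chrom", "start", "end", "class", "h_label", "a_label"]]

    rng_tss = _child_rng(cfg.seed, _TSS_KEY)
    tss: list[tuple[str, int, str]] = []
    for _, row in truth[truth["class"] == "promoter"].iterrows():
        strand = "+" if rng_tss.random() < 0.5 else "-"
        tss.append((row["chrom"], int((row["start"] + row["end"]) // 2), strand))
    for chrom, start, end in decoy_coords:
        strand = "+" if rng_tss.random() < 0.5 else "-"
        tss.append((chrom, (start + end) // 2, strand))
    tss.sort()

    if pairs is None:
        pairs = [(a, g) for a in ASSAYS for g in GENOTYPES]
    coverage = {
        (assay, genotype): _simulate_coverage(
            cfg, truth, assay, genotype, _child_rng(cfg.seed, _PAIR_KEY[(assay, genotype)])
        )
        for assay, genotype in pairs
    }
    # order truth rows by genome position to match PeakSet sorting downstream
    order = {c: i for i, c in enumerate(cfg.layout.chrom_names)}
    truth = truth.sort_values(
        ["chrom", "start"], key=lambda s: s.map(order) if s.name == "chrom" else s
    ).reset_index(drop=True)
    return SimResult(cfg, truth, coverage, tss)


def match_to_truth(labels: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Align a per-site label table (called peaks) with the planted truth.

    A called site matches the planted site that contains its center.
    Returns the inner join with truth columns suffixed ``_true``; called
    sites over background (no planted partner) are dropped.
    """
    by_chrom: dict[str, pd.DataFrame] = {c: g for c, g in truth.groupby("chrom")}
    rows = []
    for i, row in labels.iterrows():
        grp = by_chrom.get(row["chrom"])
        if grp is None:
            continue
        center = (row["start"] + row["end"]) // 2
        hit = grp[(grp["start"] <= center) & (center < grp["end"])]
        if len(hit) == 1:
            t = hit.iloc[0]
            rows.append(
                {
                    **row.to_dict(),
                    "class_true": t["class"],
                    "h_label_true": t["h_label"],
                    "a_label_true": t["a_label"],
                }
            )
    return pd.DataFrame(rows)


def make_rime_table(
    n_true_interactors: int = 177,
    n_background: int = 150,
    contamination_rate: float = 0.15,
    seed: int = 0,
) -> tuple[pd.DataFrame, set[str]]:
    """Synthetic RIME evidence table with a known interactor truth list.

    True interactors pass every filter criterion in at least one replicate
    and never appear in IgG; background proteins fail at least one
    criterion or (at ``contamination_rate``) appear in a batch-matched IgG
    control despite passing scores.  Each replicate is its own batch with
    its own IgG control, matching a three-repeat pulldown design.
    """
    rng = _child_rng(seed, _RIME_KEY)
    reps = ("Rep1", "Rep2", "Rep3")
    rows: list[dict] = []
    truth: set[str] = set()

    def target_row(pid: str, rep: str, score: float, unique: int, spectra: int) -> dict:
        return {
            "protein_id": pid,
            "replicate": rep,
            "antibody": "target",
            "batch": rep,
            "neg10lgP": round(score, 2),
            "unique_peptides": unique,
            "spectral_counts": spectra,
        }

    for i in range(n_true_interactors):
        pid = f"TRUE{i:04d}"
        truth.add(pid)
        detected = [r for r in reps if rng.random() < 0.7]
        if not detected:
            detected = [reps[int(rng.integers(3))]]
        for rep in detected:
            rows.append(
                target_row(pid, rep, 20 + rng.uniform(0, 40), int(rng.integers(1, 10)),
                           int(rng.integers(5, 50)))
            )

    fail_modes = ("score", "spectra", "igg")
    for i in range(n_background):
        pid = f"BG{i:04d}"
        mode = "igg" if rng.random() < contamination_rate else fail_modes[int(rng.integers(2))]
        detected = [r for r in reps if rng.random() < 0.6] or [reps[int(rng.integers(3))]]
        for rep in detected:
            if mode == "score":
                rows.append(target_row(pid, rep, rng.uniform(0, 19.9), int(rng.integers(1, 5)),
                                       int(rng.integers(5, 30))))
            elif mode == "spectra":
                rows.append(target_row(pid, rep, 20 + rng.uniform(0, 20), int(rng.integers(1, 5)),
                                       int(rng.integers(0, 5))))
            else:  # passes thresholds but contaminates the matched IgG control
                rows.append(target_row(pid, rep, 20 + rng.uniform(0, 20), int(rng.integers(1, 5)),
                                       int(rng.integers(5, 30))))
                rows.append(
                    {
                        "protein_id": pid,
                        "replicate": rep,
                        "antibody": "IgG",
                        "batch": rep,
                        "neg10lgP": round(rng.uniform(5, 30), 2),
                        "unique_peptides": int(rng.integers(1, 3)),
                        "spectral_counts": int(rng.integers(1, 10)),
                    }
                )
    return pd.DataFrame(rows), truth
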