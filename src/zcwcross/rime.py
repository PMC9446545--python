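"""RIME interactor filtering and replicate-overlap (Venn) counting.

RIME (rapid immunoprecipitation mass spectrometry of endogenous proteins)
yields per-replicate protein identification tables.  A protein counts as a
positive interactor in a replicate when, in the target-antibody pulldown,
its identification score -10*log10(P) is >= 20, it has at least 1 unique
peptide and at least 5 spectral counts — and it was never identified in an
IgG control of the same experimental batch (any IgG detection excludes it,
regardless of scores).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import pandas as pd

__all__ = ["RimeThresholds", "read_evidence", "filter_evidence", "replicate_venn"]

REPLICATES = ("Rep1", "Rep2", "Rep3")

#: default column names of the evidence TSV; override via `columns=` mapping
DEFAULT_COLUMNS = {
    "protein_id": "protein_id",
    "replicate": "replicate",
    "antibody": "antibody",
    "batch": "batch",
    "neg10lgP": "neg10lgP",
    "unique_peptides": "unique_peptides",
    "spectral_counts": "spectral_counts",
}


@dataclass(frozen=True)
class RimeThresholds:
    """Inclusive acceptance thresholds for a target-pulldown identification."""

    min_neg10lgP: float = 20.0
    min_unique_peptides: int = 1
    min_spectral_counts: int = 5


def read_evidence(path: str | Path, columns: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a one-row-per-(protein, replicate, antibody) evidence TSV and
    normalize its column names to the canonical set."""
    mapping = dict(DEFAULT_COLUMNS)
    if columns:
        mapping.update(columns)
    df = pd.read_csv(path, sep="\t")
    rename = {src: dst for dst, src in mapping.items()}
    missing = [src for src in rename if src not in df.columns]
    if missing:
        raise ValueError(f"evidence table missing columns: {missing}")
    df = df.rename(columns=rename)[list(DEFAULT_COLUMNS)]
    bad = set(df["antibody"]) - {"target", "IgG"}
    if bad:
        raise ValueError(f"unknown antibody labels: {sorted(bad)} (expected 'target' or 'IgG')")
    return df


def filter_evidence(
    rows: pd.DataFrame,
    thresholds: RimeThresholds = RimeThresholds(),
) -> dict[str, set[str]]:
    """Per-replicate positive protein sets under the score/peptide/spectra
    thresholds with batch-matched IgG exclusion.

    A protein present in ANY IgG control row of a batch is excluded from
    every target replicate of that batch, whatever its scores.
    """
    bad = set(rows["antibody"]) - {"target", "IgG"}
    if bad:
        raise ValueError(f"unknown antibody labels: {sorted(bad)}")
    igg = rows[rows["antibody"] == "IgG"]
    igg_by_batch = {batch: set(grp["protein_id"]) for batch, grp in igg.groupby("batch")}
    target = rows[rows["antibody"] == "target"]
    passing = target[
        (target["neg10lgP"] >= thresholds.min_neg10lgP)
        & (target["unique_peptides"] >= thresholds.min_unique_peptides)
        & (target["spectral_counts"] >= thresholds.min_spectral_counts)
    ]
    positives: dict[str, set[str]] = {rep: set() for rep in sorted(target["replicate"].unique())}
    for row in passing.itertuples(index=False):
        if row.protein_id in igg_by_batch.get(row.batch, ()):  # batch-matched control hit
            continue
        positives.setdefault(row.replicate, set()).add(row.protein_id)
    return positives


def replicate_venn(sets: dict[str, set[str]]) -> dict[str, int]:
    """Counts of the 7 exclusive regions of a three-set Venn diagram plus
    the union ("detected in at least one replicate").

    Region keys join replicate names with '&' (e.g. ``Rep1&Rep3`` is the
    proteins in exactly those two replicates).
    """
    names = sorted(sets)
    if len(names) != 3:
        raise ValueError("replicate_venn expects exactly three sets")
    universe = set().union(*sets.values())
    regions: dict[str, int] = {}
    for k in (1, 2, 3):
        for combo in combinations(names, k):
            inside = set(universe)
            for n in combo:
                inside &= sets[n]
            for n in names:
                if n not in combo:
                    inside -= sets[n]
            regions["&".join(combo)] = len(inside)
    regions["union"] = len(universe)
    return regions
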