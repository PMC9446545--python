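"""Plain-text genomics I/O: BED3/BED6(+FE), bedGraph, chrom-sizes and TSS tables.

bedGraph and BED share the 0-based half-open convention.  Lines starting
with ``track`` or ``#`` are skipped on read.  Writers emit deterministic,
byte-stable output so round-trips and reruns can be compared verbatim.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genome import PEAK_COLUMNS, GenomeLayout, Interval, PeakSet


class BedParseError(ValueError):
    """Malformed record in a BED-family file; names the offending line."""


def _fmt(x: float) -> str:
    """Stable numeric formatting: integers without a decimal point."""
    if float(x) == int(x):
        return str(int(x))
    return format(float(x), ".6g")


def read_chrom_sizes(path: str | Path) -> GenomeLayout:
    """Two-column TSV of chromosome name and length."""
    names, lengths = [], []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise BedParseError(f"{path}:{lineno}: expected 2 tab-separated columns")
        names.append(parts[0])
        lengths.append(int(parts[1]))
    return GenomeLayout(tuple(names), tuple(lengths))


def write_chrom_sizes(layout: GenomeLayout, path: str | Path) -> None:
    lines = [f"{c}\t{l}" for c, l in zip(layout.chrom_names, layout.chrom_lengths)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_bed(
    path: str | Path,
    layout: GenomeLayout | None = None,
    assay: str = "",
    genotype: str = "",
) -> PeakSet:
    """Read BED3/BED6 with optional 7th (fold enrichment) and 8th (summit
    offset) columns into a :class:`PeakSet` validated against ``layout``.
    """
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise BedParseError(f"{path}:{lineno}: BED record needs >= 3 columns")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
        if end <= start or start < 0:
            raise BedParseError(f"{path}:{lineno}: invalid interval [{start}, {end})")
        row = {
            "chrom": parts[0],
            "start": start,
            "end": end,
            "name": parts[3] if len(parts) > 3 else ".",
            "score": float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0,
            "strand": parts[5] if len(parts) > 5 and parts[5] in "+-" else ".",
            "fold_enrichment": float(parts[6]) if len(parts) > 6 and parts[6] != "." else np.nan,
            "summit": int(parts[7]) if len(parts) > 7 and parts[7] != "." else -1,
        }
        if layout is not None:
            try:
                Interval(row["chrom"], start, end).validate(layout)
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
        rows.append(row)
    df = pd.DataFrame(rows, columns=PEAK_COLUMNS)
    return PeakSet(assay, genotype, df, layout)


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    """Write BED6 + fold-enrichment + summit columns (trailing optional
    columns emitted as ``.`` when absent)."""
    lines = []
    for r in peaks.df.itertuples(index=False):
        fe = "." if pd.isna(r.fold_enrichment) else _fmt(r.fold_enrichment)
        summit = "." if r.summit < 0 else str(int(r.summit))
        lines.append(
            f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{_fmt(r.score)}\t{r.strand}\t{fe}\t{summit}"
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_bedgraph(path: str | Path, layout: GenomeLayout) -> dict[str, np.ndarray]:
    """Read a 4-column bedGraph into dense per-bp float arrays (gaps = 0)."""
    data = {c: np.zeros(layout.length_of(c), dtype=np.float64) for c in layout.chrom_names}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise BedParseError(f"{path}:{lineno}: bedGraph record needs 4 columns")
        chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
        if chrom not in layout:
            raise BedParseError(f"{path}:{lineno}: chromosome {chrom!r} not in genome layout")
        if end <= start or end > layout.length_of(chrom):
            raise BedParseError(f"{path}:{lineno}: invalid interval [{start}, {end})")
        data[chrom][start:end] = value
    return data


def write_bedgraph(data: dict[str, np.ndarray], path: str | Path, layout: GenomeLayout) -> None:
    """Write dense per-bp arrays as run-length-compacted bedGraph.

    Zero runs are omitted (implicit 0), matching the read convention.
    """
    lines: list[str] = []
    for chrom in layout.chrom_names:
        values = np.asarray(data[chrom], dtype=np.float64)
        if values.size == 0:
            continue
        change = np.nonzero(np.diff(values))[0] + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [values.size]))
        for s, e in zip(starts, ends):
            v = values[s]
            if v != 0.0:
                lines.append(f"{chrom}\t{s}\t{e}\t{_fmt(v)}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_tss(path: str | Path) -> list[tuple[str, int, str]]:
    """TSS table: TSV of (chrom, position, strand); strand defaults to '+'."""
    tss = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise BedParseError(f"{path}:{lineno}: TSS record needs >= 2 columns")
        strand = parts[2] if len(parts) > 2 and parts[2] in "+-" else "+"
        tss.append((parts[0], int(parts[1]), strand))
    return tss


def write_tss(tss: list[tuple[str, int, str]], path: str | Path) -> None:
    Path(path).write_text("".join(f"{c}\t{p}\t{s}\n" for c, p, s in tss))
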