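"""End-to-end orchestration: simulate -> call peaks -> classify -> report.

The pipeline mirrors the study's analysis order.  WT ZCWPW1 peaks define
the binding sites; H3K9ac peaks are called in WT and knockout; ATAC peaks
in WT; fold-change signal tracks feed the loss/retention rules; the
result is a per-site label table, a ClassificationReport and a run
manifest sufficient to re-run bit-identically.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import ClassificationReport, classify_sites, summarize
from .genome import PeakSet
from .io import write_bed
from .peakcalling import PRESETS, call_peaks
from .simulate import SimConfig, SimResult, simulate

logger = logging.getLogger("zcwcross")

__all__ = ["PipelineResult", "RunManifest", "run_pipeline", "validate_report_dict"]

#: (assay, genotype) coverage needed by the default classification run
PIPELINE_PAIRS = [
    ("zcwpw1", "WT"),
    ("dmc1", "WT"),
    ("h3k9ac", "WT"),
    ("h3k9ac", "Zcwpw1KO"),
    ("atac", "WT"),
    ("atac", "Zcwpw1KO"),
]

REPORT_SCHEMA = {
    "counts": [
        "n_sites", "n_marked", "n_h1", "n_h2", "n_open", "n_a1", "n_a2", "n_joint",
        "n_h1_promoter", "n_h2_promoter", "n_a1_promoter", "n_a2_promoter",
    ],
    "fractions": [
        "marked_percent", "open_percent", "h1_percent", "h2_percent", "a1_percent",
        "a2_percent", "joint_loss_percent", "h1_promoter_percent", "h2_promoter_percent",
        "a1_promoter_percent", "a2_promoter_percent",
    ],
}


def validate_report_dict(report: dict) -> None:
    """Structural + invariant check of a serialized ClassificationReport."""
    for section, keys in REPORT_SCHEMA.items():
        if section not in report:
            raise ValueError(f"report missing section {section!r}")
        missing = [k for k in keys if k not in report[section]]
        if missing:
            raise ValueError(f"report section {section!r} missing keys {missing}")
    c = report["counts"]
    if c["n_h1"] + c["n_h2"] != c["n_marked"] or c["n_a1"] + c["n_a2"] != c["n_open"]:
        raise ValueError("report counts violate the partition invariants")
    if c["n_joint"] > min(c["n_a1"], c["n_h1"]):
        raise ValueError("joint count exceeds a parent group")


@dataclass
class RunManifest:
    """What ran, on what, with which settings — enough to re-run exactly."""

    subcommand: str
    seed: int
    config: dict
    inputs: dict
    outputs: dict
    version: str = __version__
    python: str = platform.python_version()
    started: str = ""
    finished: str = ""

    def write(self, path: str | Path) -> None:
        tmp = Path(str(path) + ".tmp")
        tmp.write_text(json.dumps(self.__dict__, indent=2, default=str) + "\n")
        tmp.replace(path)  # atomic alongside the outputs


@dataclass
class PipelineResult:
    labels: pd.DataFrame
    report: ClassificationReport
    peaks: dict[str, PeakSet]
    sim: SimResult | None = None


def _now() -> str:
    return datetime.now(timezone.utc).isoformat(timespec="seconds")


def run_pipeline(
    config: SimConfig | None = None,
    seed: int | None = None,
    outdir: str | Path | None = None,
    open_frac: float = 0.2,
    loss_ratio: float = 2.0,
    promoter_window: tuple[int, int] = (2000, 500),
    sim: SimResult | None = None,
) -> PipelineResult:
    """Simulate (unless ``sim`` is given), call peaks with the per-assay
    presets, classify every ZCWPW1 site and summarize.

    When ``outdir`` is set, writes peaks (BED), the per-site label table
    (TSV), the report (JSON) and a run manifest.
    """
    started = _now()
    if sim is None:
        config = config or SimConfig()
        if seed is not None:
            from dataclasses import replace

            config = replace(config, seed=seed)
        logger.info("simulating synthetic study (seed=%d)", config.seed)
        sim = simulate(config, pairs=PIPELINE_PAIRS)
    config = sim.config

    logger.info("calling peaks")
    peaks = {
        "zcwpw1_WT": call_peaks(sim.coverage[("zcwpw1", "WT")], PRESETS["zcwpw1_chip"]),
        "h3k9ac_WT": call_peaks(sim.coverage[("h3k9ac", "WT")], PRESETS["h3k9ac_chip"]),
        "h3k9ac_Zcwpw1KO": call_peaks(sim.coverage[("h3k9ac", "Zcwpw1KO")], PRESETS["h3k9ac_chip"]),
        "atac_WT": call_peaks(sim.coverage[("atac", "WT")], PRESETS["atac"]),
        "atac_Zcwpw1KO": call_peaks(sim.coverage[("atac", "Zcwpw1KO")], PRESETS["atac"]),
    }
    for name, ps in peaks.items():
        logger.info("  %s: %d peaks", name, len(ps))

    logger.info("classifying ZCWPW1 binding sites")
    labels = classify_sites(
        zcwpw1=peaks["zcwpw1_WT"],
        h3k9ac_wt_peaks=peaks["h3k9ac_WT"],
        h3k9ac_ko_peaks=peaks["h3k9ac_Zcwpw1KO"],
        atac_wt_peaks=peaks["atac_WT"],
        h3k9ac_wt_signal=sim.signal("h3k9ac", "WT"),
        h3k9ac_ko_signal=sim.signal("h3k9ac", "Zcwpw1KO"),
        atac_wt_signal=sim.signal("atac", "WT"),
        atac_ko_signal=sim.signal("atac", "Zcwpw1KO"),
        tss=sim.tss,
        open_frac=open_frac,
        loss_ratio=loss_ratio,
        promoter_window=promoter_window,
    )
    report = summarize(labels)
    logger.info(
        "report: %d sites, H1 %d/%d (%s%%), A1 %d/%d (%s%%)",
        report.n_sites, report.n_h1, report.n_marked, report.fractions["h1_percent"],
        report.n_a1, report.n_open, report.fractions["a1_percent"],
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        sim.write(outdir / "simulated")
        for name, ps in peaks.items():
            write_bed(ps, outdir / f"{name}.peaks.bed")
        labels.to_csv(outdir / "site_labels.tsv", sep="\t", index=False)
        report.to_json(outdir / "classification_report.json")
        validate_report_dict(json.loads((outdir / "classification_report.json").read_text()))
        manifest = RunManifest(
            subcommand="run-all",
            seed=config.seed,
            config={k: str(v) for k, v in config.__dict__.items()},
            inputs={"mode": "simulated"},
            outputs={p.name: str(p) for p in sorted(outdir.glob("*"))},
            started=started,
            finished=_now(),
        )
        manifest.write(outdir / "manifest.json")

    return PipelineResult(labels=labels, report=report, peaks=peaks, sim=sim)
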