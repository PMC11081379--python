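"""End-to-end orchestration: load -> classify -> annotate -> report.

Stages run in order with per-stage logging; each stage failure aborts with
the stage name and cause.  The report is JSON with fixed key order and
floats serialized at six decimals so re-runs are byte-diffable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import genome_io
from .genome_io import (
    CpgIslandParams,
    Genome,
    GenomicInterval,
    find_cpg_islands,
    read_bed_intervals,
    read_fasta,
    read_genes_tsv,
    read_peaks_bed,
)
from .g4_engine import G4Params, hits_to_bed6_rows
from .peak_annotation import (
    DEFAULT_TSS_BIN_EDGES,
    compare_top_bottom_gc,
    cpg_overlap_fraction,
    motif_enrichment,
    rank_peaks,
    tss_distance_histogram,
)
from .site_classifier import classify_site, profiles_to_tsv, summarize_cohort
from .synthetic_data import read_truth_tsv, truth_confusion

logger = logging.getLogger("compoundg4")

DEFAULT_MOTIF = "GGVGGCNGVGGHDGS"


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name for diagnosis."""

    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Paths and parameters for one pipeline run."""

    genome: str
    peaks: str
    genes: str | None = None
    islands: str = "auto"  # 'auto' = call CpG islands from the genome
    truth: str | None = None
    motif: str = DEFAULT_MOTIF
    top_n: int = 100
    tss_bin_edges: tuple[int, ...] = DEFAULT_TSS_BIN_EDGES
    g4: G4Params = field(default_factory=G4Params)
    cpg: CpgIslandParams = field(default_factory=CpgIslandParams)
    outdir: str = "compoundg4_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "g4" in raw:
            raw["g4"] = G4Params(**raw["g4"])
        if "cpg" in raw:
            raw["cpg"] = CpgIslandParams(**raw["cpg"])
        if "tss_bin_edges" in raw:
            raw["tss_bin_edges"] = tuple(raw["tss_bin_edges"])
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["tss_bin_edges"] = list(self.tss_bin_edges)
        return d


def _round_floats(obj: Any, ndigits: int = 6) -> Any:
    if isinstance(obj, float):
        if math.isnan(obj):
            return None
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        t0 = time.perf_counter()
        logger.info("stage %s: start", name)
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(name, str(exc)) from exc
        logger.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
        return out

    return wrap


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute all stages and return the report dict (also written to disk).

    Artifacts in ``config.outdir``: g4_hits.bed, sites.tsv, islands.bed
    (when called in auto mode) and report.json.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def load_inputs():
        genome = read_fasta(config.genome)
        peaks = read_peaks_bed(config.peaks)
        genes = read_genes_tsv(config.genes) if config.genes else []
        if config.islands == "auto":
            islands = find_cpg_islands(genome, config.cpg)
            genome_io.write_bed6(islands, outdir / "islands.bed")
        else:
            islands = read_bed_intervals(config.islands)
        truth = read_truth_tsv(config.truth) if config.truth else None
        return genome, peaks, genes, islands, truth

    genome, peaks, genes, islands, truth = _stage("load")(load_inputs)

    report: dict[str, Any] = {
        "tool": "compoundg4",
        "version": _version(),
        "n_sites": len(peaks),
        "cohort_summary": None,
        "gc_comparison": None,
        "cpg_overlap": None,
        "tss_histogram": None,
        "motif_enrichment": None,
        "confusion": None,
        "config": config.to_dict(),
    }

    if not peaks:
        (outdir / "report.json").write_text(
            json.dumps(_round_floats(report), indent=2) + "\n"
        )
        logger.info("no peaks; wrote empty report")
        return report

    def classify_all():
        ranked = rank_peaks(peaks)
        profiles = [
            classify_site(genome, p.interval, config.g4, site_id=p.name)
            for p in ranked
        ]
        return ranked, profiles

    ranked, profiles = _stage("classify")(classify_all)

    def write_site_artifacts():
        profiles_to_tsv(profiles, outdir / "sites.tsv")
        with open(outdir / "g4_hits.bed", "w") as fh:
            for prof in profiles:
                for row in hits_to_bed6_rows(list(prof.hits), prof.interval.chrom):
                    fh.write("\t".join(str(x) for x in row) + "\n")

    _stage("write_sites")(write_site_artifacts)

    def annotate():
        summary = summarize_cohort(profiles)
        n = min(config.top_n, len(ranked) // 2)
        gc_cmp = compare_top_bottom_gc(ranked, genome, n) if n >= 1 else None
        top = ranked[:n]
        bottom = ranked[-n:] if n >= 1 else []
        cpg = {
            "all": cpg_overlap_fraction(ranked, islands),
            "top": cpg_overlap_fraction(top, islands) if top else None,
            "bottom": cpg_overlap_fraction(bottom, islands) if bottom else None,
        }
        tss = tss_distance_histogram(ranked, genes, config.tss_bin_edges) if genes else None
        motif = (
            motif_enrichment(top, genome, config.motif, bottom)
            if top and bottom
            else None
        )
        return summary, gc_cmp, cpg, tss, motif

    summary, gc_cmp, cpg, tss, motif = _stage("annotate")(annotate)

    report["cohort_summary"] = {
        "n_sites": summary.n_sites,
        "frac_any_g4": summary.frac_any_g4,
        "frac_both_strands": summary.frac_both_strands,
        "frac_compound": summary.frac_compound,
        "frac_two_tetrad_hits": summary.frac_two_tetrad_hits,
        "n_hits": summary.n_hits,
    }
    if gc_cmp:
        report["gc_comparison"] = dataclasses.asdict(gc_cmp)
    report["cpg_overlap"] = cpg
    if tss:
        report["tss_histogram"] = {
            "bin_edges": list(tss.bin_edges),
            "labels": list(tss.labels),
            "counts": list(tss.counts),
            "unassigned": tss.unassigned,
        }
    if motif:
        report["motif_enrichment"] = dataclasses.asdict(motif)

    if truth is not None:
        def confusion():
            table = truth_confusion(profiles, truth)
            return {
                "tp": table.tp, "fn": table.fn, "fp": table.fp, "tn": table.tn,
                "sensitivity": table.sensitivity,
                "specificity": table.specificity,
                "by_label": table.by_label,
            }

        report["confusion"] = _stage("confusion")(confusion)

    (outdir / "report.json").write_text(
        json.dumps(_round_floats(report), indent=2) + "\n"
    )
    logger.info("report written to %s", outdir / "report.json")
    return report


def _version() -> str:
    from . import __version__

    return __version__
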