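"""End-to-end driver: normalize -> call -> fit -> classify -> summarize.

Ties the library modules into the published post-alignment workflow.  Every
stage writes plain-text outputs (bedGraph, BED, TSV) plus a JSON manifest
recording parameters and per-stage status, so any stage can be reproduced by
the corresponding subcommand with the manifest's parameters.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import fragments as fio
from .calling import call_nucleosomes, pool_dyads, write_calls_bed
from .fitting import FitConfig, extract_timecourses, fit_all
from .seqfeat import two_d_occupancy, write_matrix_tsv

log = logging.getLogger("qnuc")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    sample_sheet: str
    outdir: str
    genome_fasta: str | None = None      # required only for the 2D occupancy stage
    chrom_sizes: str | None = None       # inferred from the FASTA when omitted
    spikein_target: float = fio.DEFAULT_SPIKEIN_TARGET
    spikein_prefix: str = fio.DEFAULT_SPIKEIN_PREFIX
    min_len: int = 100
    max_len: int = 200
    bandwidth: float = 30.0
    min_separation: int = 147
    min_support: float | None = None
    fit_window: int = 147
    fragile_threshold: float = 10.0
    n_bins: int = 9
    write_tracks: bool = True
    seed: int = 0
    log_level: str = "INFO"


def _chrom_sizes(config: PipelineConfig, frames) -> dict[str, int]:
    if config.chrom_sizes:
        return fio.read_chrom_sizes(config.chrom_sizes)
    if config.genome_fasta:
        from pyfaidx import Fasta

        fa = Fasta(config.genome_fasta)
        return {
            name: len(fa[name])
            for name in fa.keys()
            if not name.startswith(config.spikein_prefix)
        }
    # fall back to the observed fragment extents
    sizes: dict[str, int] = {}
    for df in frames:
        tgt = df[df["genome"] == fio.TARGET]
        for chrom, grp in tgt.groupby("chrom"):
            sizes[chrom] = max(sizes.get(chrom, 0), int(grp["end"].max()))
    return sizes


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full workflow; returns the manifest dict (also written as JSON)."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "parameters": asdict(config),
        "stages": {},
        "outputs": {},
    }

    # ---- stage: load ----
    stage = "load"
    try:
        sheet = fio.read_sample_sheet(config.sample_sheet)
        for p in sheet["fragments_path"]:
            if not Path(p).exists():
                raise FileNotFoundError(f"fragment file missing: {p}")
        frames = [
            fio.read_fragments_frame(p, spikein_prefix=config.spikein_prefix)
            for p in sheet["fragments_path"]
        ]
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    manifest["stages"][stage] = "ok"

    # ---- stage: normalize ----
    stage = "normalize"
    try:
        chrom_sizes = _chrom_sizes(config, frames)
        kept = [fio.filter_by_length(df, config.min_len, config.max_len) for df in frames]
        spike = [fio.count_spikein(df) for df in kept]
        dyads = fio.spikein_normalize(
            [(fio.dyad_track(df, chrom_sizes), n) for df, n in zip(kept, spike)],
            config.spikein_target,
            sheet["sample_id"],
            sheet["time_min"],
        )
        cov = fio.spikein_normalize(
            [(fio.coverage_track(df, chrom_sizes), n) for df, n in zip(kept, spike)],
            config.spikein_target,
            sheet["sample_id"],
            sheet["time_min"],
        )
        scales = pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in dyads],
                "time_min": [s.time_min for s in dyads],
                "raw_spikein_count": [s.raw_spikein_count for s in dyads],
                "scale_factor": [s.scale_factor for s in dyads],
            }
        )
        scales.to_csv(outdir / "scale_factors.tsv", sep="\t", index=False)
        manifest["outputs"]["scale_factors"] = "scale_factors.tsv"
        if config.write_tracks:
            for s in cov:
                fio.write_bedgraph(s.tracks, outdir / f"coverage_{s.sample_id}.bedGraph")
            manifest["outputs"]["coverage_tracks"] = [
                f"coverage_{s.sample_id}.bedGraph" for s in cov
            ]
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    manifest["stages"][stage] = "ok"

    # ---- stage: call ----
    stage = "call"
    try:
        pooled = pool_dyads(dyads)
        if config.write_tracks:
            fio.write_bedgraph(pooled, outdir / "dyads_pooled.bedGraph")
            manifest["outputs"]["pooled_dyads"] = "dyads_pooled.bedGraph"
        calls = call_nucleosomes(
            pooled,
            bandwidth=config.bandwidth,
            min_separation=config.min_separation,
            min_support=config.min_support,
        )
        write_calls_bed(calls, outdir / "calls.bed")
        manifest["outputs"]["calls"] = "calls.bed"
        manifest["n_calls"] = len(calls)
        log.info("called %d nucleosome positions", len(calls))
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    manifest["stages"][stage] = "ok"

    # ---- stage: fit ----
    stage = "fit"
    try:
        tcs = extract_timecourses(calls, cov, window=config.fit_window)
        fit_cfg = FitConfig(
            fragile_threshold=config.fragile_threshold, n_bins=config.n_bins
        )
        table = fit_all(tcs, fit_cfg, calls=calls)
        table.to_csv(outdir / "fits.tsv", sep="\t", index=False, float_format="%.6g")
        manifest["outputs"]["fits"] = "fits.tsv"
        manifest["convergence_rate"] = (
            float(table["converged"].mean()) if len(table) else float("nan")
        )
        summary = (
            table.groupby("time_class").size().rename("n_loci").reset_index()
        )
        summary["share"] = summary["n_loci"] / len(table) if len(table) else np.nan
        summary.to_csv(outdir / "time_class_summary.tsv", sep="\t", index=False)
        manifest["outputs"]["time_class_summary"] = "time_class_summary.tsv"
        manifest["n_fragile"] = int(table["fragile"].sum())
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    manifest["stages"][stage] = "ok"

    # ---- stage: plot2do (optional, needs the genome) ----
    stage = "plot2do"
    if config.genome_fasta:
        try:
            from pyfaidx import Fasta

            fa = Fasta(config.genome_fasta)
            for df, s in zip(kept, cov):
                mat = two_d_occupancy(
                    _as_records_frame(df),
                    fa,
                    length_range=(config.min_len, config.max_len),
                    weight=s.scale_factor,
                )
                write_matrix_tsv(mat, outdir / f"occupancy2d_{s.sample_id}.tsv")
            manifest["outputs"]["occupancy2d"] = [
                f"occupancy2d_{s.sample_id}.tsv" for s in cov
            ]
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc
        manifest["stages"][stage] = "ok"
    else:
        manifest["stages"][stage] = "skipped (no genome FASTA)"

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["outputs"]["manifest"] = "manifest.json"
    return manifest


def _as_records_frame(df: pd.DataFrame):
    """Iterate a fragment DataFrame as lightweight records for seqfeat."""
    from .fragments import FragmentRecord

    for chrom, start, end, genome in zip(
        df["chrom"], df["start"], df["end"], df["genome"]
    ):
        yield FragmentRecord(chrom, int(start), int(end), genome)
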