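"""Pipeline orchestration: configuration, staged execution, reporting.

Wires the stages in analysis order — filter → annotate → arrays → flanks →
LINE insertions — with one flat key-value configuration whose keys match
the CLI flag names. Every stage writes its outputs to the run directory and
registers them in a manifest; reruns with identical config and inputs are
bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import annotation, arrays, interspersion, io, lines
from .annotation import segments_to_bed
from .interspersion import arrays_as_features, Feature

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    pass


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All numeric knobs of the analysis, with workflow defaults.

    Lengths in bp. Keys match CLI flag names with ``-`` replaced by ``_``.
    """

    min_length: int = 30_000          # read-length filter
    min_mean_q: float = 8.0           # mean-Phred filter (maq semantics)
    xdrop: int = 10                   # external-engine search params
    hspthresh: int = 1_000
    monomer_length: int = 389
    bin: int = 5_000                  # array histogram bin
    last_bin_floor: int = 120_000
    weight: str = "bp"                # histogram weighting: bp | count
    flank_window: int = 10_000
    min_window: int = 190             # insertion-site window filters
    window: int = 200
    fl_min: int = 5_000
    fl_max: int = 7_000
    assoc_dist: int = 10_000
    plot_threshold: float = 0.05
    merge_gap: int = 50
    min_segment_length: int = 100
    split_gap: int = 100
    edge_tol: int = 10
    adjacency_gap: int = 50
    enrich_fold: float = 5.0
    tol: int = 20                     # periodicity fit tolerance
    l_min: int = 100                  # periodicity search range
    l_max: int = 800
    min_ssr_array: int = 60
    family: str = "CUS-TR24"
    engine: str = "builtin"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_window > self.window:
            raise ConfigurationError("min_window must be <= window")
        if self.fl_min > self.fl_max:
            raise ConfigurationError("fl_min must be <= fl_max")
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not isinstance(v, bool) \
                    and f.name not in ("seed",) and v < 0:
                raise ConfigurationError(f"{f.name} must be non-negative")

    def to_text(self) -> str:
        out = []
        for f in fields(self):
            key = f.name.replace("_", "-")
            out.append(f"{key} = {getattr(self, f.name)}")
        return "\n".join(out) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "PipelineConfig":
        kwargs = {}
        defaults = cls()
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigurationError(f"line {lineno}: expected key = value")
            key, _, value = (p.strip() for p in line.partition("="))
            name = key.replace("-", "_")
            if not hasattr(defaults, name):
                raise ConfigurationError(f"line {lineno}: unknown key {key!r}")
            current = getattr(defaults, name)
            if isinstance(current, bool):
                kwargs[name] = value.lower() in ("1", "true", "yes")
            elif isinstance(current, int):
                kwargs[name] = int(value)
            elif isinstance(current, float):
                kwargs[name] = float(value)
            else:
                kwargs[name] = value
        return cls(**kwargs)


def run_pipeline(config: PipelineConfig,
                 reads_path: str | Path,
                 refdb_path: str | Path,
                 out_dir: str | Path,
                 monomer: str | None = None) -> dict:
    """Execute all stages, writing per-stage outputs and a manifest.

    Returns the manifest dict. Any stage failure raises :class:`StageError`
    after writing the partial manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reads_path = Path(reads_path)
    refdb_path = Path(refdb_path)
    if not reads_path.exists():
        raise ConfigurationError(f"reads file not found: {reads_path}")
    if not refdb_path.exists():
        raise ConfigurationError(f"reference database not found: {refdb_path}")

    (out / "config.txt").write_text(config.to_text())
    manifest: dict = {"config": "config.txt", "stages": {}}

    def save_manifest() -> None:
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True))

    summary: dict = {}
    try:
        stage = "filter"
        refdb = annotation.load_reference_db(refdb_path)
        raw = list(io.load_reads(reads_path))
        kept = list(io.filter_reads(raw, config.min_mean_q, config.min_length))
        stats = io.read_stats(kept)
        (out / "read_stats.json").write_text(stats.to_json())
        manifest["stages"][stage] = ["read_stats.json"]
        summary["reads"] = dataclasses.asdict(stats)

        stage = "annotate"
        annotated, hits = annotation.annotate_reads(
            kept, refdb, engine=config.engine,
            min_ssr_array=config.min_ssr_array,
            min_segment_length=config.min_segment_length,
            merge_gap=config.merge_gap)
        read_lengths = {r.read_id: r.length for r in kept}
        ref_lengths = {r.name: r.length for r in refdb}
        annotation.hits_to_frame(hits, read_lengths, ref_lengths).to_csv(
            out / "hits.tsv", sep="\t", index=False)
        segments_to_bed(annotated).to_csv(out / "annotation.bed", sep="\t",
                                          index=False, header=False)
        manifest["stages"][stage] = ["hits.tsv", "annotation.bed"]
        summary["n_segments"] = sum(len(a.segments) for a in annotated)

        stage = "arrays"
        arrs = arrays.detect_arrays_all(annotated, config.family,
                                        split_gap=config.split_gap,
                                        edge_tol=config.edge_tol)
        arr_frame = pd.DataFrame(
            [(a.read_id, a.start, a.end, f"{a.family}/{a.status}", a.length,
              a.strand) for a in arrs],
            columns=["chrom", "start", "end", "name", "score", "strand"])
        arr_frame.to_csv(out / "arrays.bed", sep="\t", index=False,
                         header=False)
        hist = arrays.length_histogram(arrs, bin_size=config.bin,
                                       last_bin_floor=config.last_bin_floor,
                                       weight=config.weight)
        pd.DataFrame({"bin_start": hist.bin_edges,
                      "complete": hist.complete_weight,
                      "truncated": hist.truncated_weight}).to_csv(
            out / "array_histogram.tsv", sep="\t", index=False)
        complete_lengths = arrays.periodicity_lengths(
            annotated, config.family, split_gap=config.split_gap,
            edge_tol=config.edge_tol, exclusion_gap=config.adjacency_gap)
        files = ["arrays.bed", "array_histogram.tsv"]
        summary["n_arrays"] = len(arrs)
        summary["n_complete_arrays"] = len(complete_lengths)
        if len(complete_lengths) >= 2:
            fit = arrays.fit_periodicity(complete_lengths,
                                         L_range=(config.l_min, config.l_max),
                                         tol=config.tol)
            (out / "periodicity.json").write_text(fit.to_json())
            files.append("periodicity.json")
            summary["periodicity"] = {"period_L": fit.period_L,
                                      "offset_t": fit.offset_t,
                                      "concentration": fit.concentration}
        manifest["stages"][stage] = files

        stage = "flanks"
        profile = interspersion.flank_profile(
            annotated, arrays_as_features(arrs), window=config.flank_window,
            focal_type=config.family)
        profile.to_frame().to_csv(out / "flank_profile.tsv", sep="\t",
                                  index=False)
        adj = interspersion.adjacency_summary(
            annotated, config.family, adjacency_gap=config.adjacency_gap,
            split_gap=config.split_gap, edge_tol=config.edge_tol)
        adj.to_frame().to_csv(out / "adjacency.tsv", sep="\t", index=False)
        manifest["stages"][stage] = ["flank_profile.tsv", "adjacency.tsv"]
        summary["adjacency_sides_scored"] = adj.n_sides_scored

        stage = "lines"
        insertions = lines.collect_line_insertions(
            annotated, refdb, fl_min=config.fl_min, fl_max=config.fl_max)
        assoc = lines.classify_association(insertions, arrs,
                                           assoc_dist=config.assoc_dist)
        assoc.to_csv(out / "line_association.tsv", sep="\t", index=False)
        files = ["line_association.tsv", "line_insertions.tsv"]
        fl = [i for i in insertions if i.full_length]
        if monomer is None:
            sat = next((r for r in refdb if r.name == config.family), None)
            monomer = sat.consensus if sat else None
        if fl and monomer:
            prof = lines.insertion_site_profile(
                fl, annotated, monomer, family=config.family,
                win=config.window, min_win=config.min_window)
            prof.to_frame().to_csv(out / "insertion_profile.tsv", sep="\t",
                                   index=False)
            files.append("insertion_profile.tsv")
            motifs = lines.target_motif_consensus(
                prof, monomer, enrich_fold=config.enrich_fold)
            summary["target_motifs"] = [{"position": p, "motif": m}
                                        for p, m in motifs]
            try:
                shift, corr = lines.tsd_estimate(prof)
                summary["tsd_shift"] = shift
                summary["tsd_correlation"] = round(corr, 4)
            except lines.FlatProfileError:
                summary["tsd_shift"] = None
        lines.insertions_to_frame(insertions).to_csv(
            out / "line_insertions.tsv", sep="\t", index=False)
        manifest["stages"][stage] = files
        summary["n_line_segments"] = len(insertions)
        summary["n_full_length_lines"] = len(fl)

        stage = "summary"
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True))
        manifest["stages"][stage] = ["summary.json"]
        save_manifest()
    except Exception as exc:  # noqa: BLE001 - stage-named rethrow
        save_manifest()
        if isinstance(exc, ConfigurationError):
            raise
        raise StageError(stage, exc) from exc
    return manifest


def report(out_dir: str | Path, plots: bool = False) -> dict:
    """Collect a completed run's tables into a human-readable summary.

    Raises if the manifest is missing stages. With ``plots=True`` renders
    the histogram, flank-profile and insertion-profile panels as PNGs.
    """
    out = Path(out_dir)
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest in {out}")
    manifest = json.loads(manifest_path.read_text())
    expected = {"filter", "annotate", "arrays", "flanks", "lines", "summary"}
    missing = expected - set(manifest.get("stages", {}))
    if missing:
        raise RuntimeError(f"incomplete run, missing stages: {sorted(missing)}")
    summary = json.loads((out / "summary.json").read_text())
    if plots:
        _render_plots(out)
    return summary


def _render_plots(out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    hist = pd.read_csv(out / "array_histogram.tsv", sep="\t")
    fig, ax = plt.subplots(figsize=(7, 4))
    width = (hist["bin_start"].iloc[1] - hist["bin_start"].iloc[0]) * 0.9 \
        if len(hist) > 1 else 4000
    ax.bar(hist["bin_start"], hist["complete"], width=width,
           label="complete", color="tab:red", align="edge")
    ax.bar(hist["bin_start"], hist["truncated"], width=width,
           bottom=hist["complete"], label="truncated", color="tab:blue",
           align="edge")
    ax.set_xlabel("array length (bp)")
    ax.set_ylabel("weight")
    ax.legend()
    fig.savefig(out / "array_histogram.png", dpi=120)
    plt.close(fig)

    prof_path = out / "flank_profile.tsv"
    if prof_path.exists():
        prof = pd.read_csv(prof_path, sep="\t")
        if not prof.empty:
            fig, ax = plt.subplots(figsize=(8, 4))
            for (label, orient), grp in prof.groupby(["label", "orientation"]):
                ax.plot(grp["offset"], grp["proportion"],
                        label=f"{label} ({orient})", lw=0.8)
            ax.axvline(0, color="k", lw=0.5)
            ax.set_xlabel("offset from focal feature (bp)")
            ax.set_ylabel("proportion")
            ax.legend(fontsize=7)
            fig.savefig(out / "flank_profile.png", dpi=120)
            plt.close(fig)

    ins_path = out / "insertion_profile.tsv"
    if ins_path.exists():
        ins = pd.read_csv(ins_path, sep="\t")
        fig, axes = plt.subplots(2, 1, figsize=(8, 5), sharex=True)
        axes[0].bar(ins["position"], ins["freq5"], color="tab:orange")
        axes[0].set_ylabel("5' ends")
        axes[1].bar(ins["position"], ins["freq3"], color="tab:green")
        axes[1].set_ylabel("3' ends")
        axes[1].set_xlabel("monomer position (bp)")
        fig.savefig(out / "insertion_profile.png", dpi=120)
        plt.close(fig)
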