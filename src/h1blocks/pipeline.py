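"""End-to-end orchestration: simulate -> call peaks -> targets -> families ->
expression -> overlap, with a manifest that allows bit-identical re-runs.

Every stage writes its tables under the run directory; the manifest records
the full parameter echo (including every seed), package version, and the
headline counts each stage produced.  A stage failure aborts the run with an
error naming the stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import PipelineError
from . import genome_io, overlap_stats, synthetic_data, target_annotation, window_stats
from . import expression_integration as expr
from . import family_analysis as fam

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All stage parameters with the analysis defaults baked in."""

    sim: dict = field(default_factory=dict)   # SimConfig overrides
    width: int = 100
    alpha: float = 0.001
    local_background: int = 50
    flank: int = 3000
    buffer: int = 3000
    density: float = 1.0
    block_width: int = 5000
    min_run: int = 3
    theta: float = 1.5
    pseudocount: float = 0.1
    bin_size: int = 2000
    n_perm: int = 1000
    n_resamples: int = 200
    seed: int = 0
    shuffle_seed: int = 0
    overlap_seed: int = 0
    contrast_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(asdict(self), handle, sort_keys=True)

    def sim_config(self) -> synthetic_data.SimConfig:
        params = dict(self.sim)
        params.setdefault("seed", self.seed)
        params.setdefault("window_width", self.width)
        params.setdefault("flank", self.flank)
        return synthetic_data.SimConfig(**params)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run the full synthetic analysis and return the manifest dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "h1blocks",
        "version": __version__,
        "parameters": asdict(config),
        "seeds": {"simulate": config.seed, "shuffle": config.shuffle_seed,
                  "overlap": config.overlap_seed, "contrast": config.contrast_seed},
        "stages": {},
    }

    sim_cfg = config.sim_config()
    annotation, truth, counts, expression = _stage("simulate")(_simulate)(
        sim_cfg, out, manifest)
    pvals, peaks = _stage("callpeaks")(_callpeaks)(config, counts, out, manifest)
    _stage("blocks")(_blocks)(config, pvals, peaks, out, manifest)
    targets, genic, intergenic = _stage("targets")(_targets)(
        config, annotation, peaks, out, manifest)
    clusters = _stage("families")(_families)(
        config, annotation, targets, pvals, out, manifest)
    _stage("expression")(_expression)(
        config, annotation, targets, clusters, expression, pvals, out, manifest)
    _stage("overlap")(_overlap)(config, annotation, peaks, truth, out, manifest)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %s", out)
    return manifest


def _simulate(sim_cfg, out, manifest):
    annotation = synthetic_data.generate_genome(sim_cfg)
    truth = synthetic_data.plant_blocks(annotation, sim_cfg)
    counts = synthetic_data.simulate_window_counts(annotation, truth, sim_cfg)
    expression = synthetic_data.simulate_expression(annotation, truth, sim_cfg)
    genome_io.write_gene_table(annotation, out / "genes.tsv")
    genome_io.write_chrom_sizes(annotation.chrom_sizes, out / "chrom.sizes")
    genome_io.write_track(window_stats_track(counts, "chip"), out / "chip.bedgraph")
    genome_io.write_track(window_stats_track(counts, "input"), out / "input.bedgraph")
    blocks = genome_io.IntervalSet(truth.intervals[["chrom", "start", "end"]].assign(
        name="block", score=truth.intervals["enrichment"]))
    genome_io.write_intervals(blocks, out / "truth_blocks.bed")
    expression.table.to_csv(out / "expression.tsv", sep="\t")
    manifest["stages"]["simulate"] = {
        "config": sim_cfg.as_dict(), "n_genes": annotation.n_genes,
        "n_blocks": len(truth),
        "outputs": ["genes.tsv", "chrom.sizes", "chip.bedgraph", "input.bedgraph",
                    "truth_blocks.bed", "expression.tsv"],
    }
    return annotation, truth, counts, expression


def window_stats_track(counts: window_stats.WindowCounts, which: str) -> genome_io.WindowTrack:
    data = counts.chip if which == "chip" else counts.input
    return genome_io.WindowTrack(width=counts.width,
                                 data={c: v.astype(float) for c, v in data.items()})


def _callpeaks(config, counts, out, manifest):
    pvals = window_stats.poisson_enrichment(counts, local_background=config.local_background)
    peaks = window_stats.call_peaks(pvals, alpha=config.alpha)
    genome_io.write_track(pvals.score_track(), out / "scores.bedgraph")
    genome_io.write_intervals(peaks.intervals, out / "peaks.bed")
    manifest["stages"]["callpeaks"] = {
        "alpha": config.alpha, "n_peaks": len(peaks),
        "outputs": ["scores.bedgraph", "peaks.bed"],
    }
    return pvals, peaks


def _blocks(config, pvals, peaks, out, manifest):
    hist = window_stats.block_profile(pvals, peaks, block_width=config.block_width,
                                      shuffle_seed=config.shuffle_seed)
    rows = [(lo, hi, c, cc) for lo, hi, c, cc in zip(
        hist.bin_edges[:-1], hist.bin_edges[1:], hist.counts, hist.control_counts)]
    pd.DataFrame(rows, columns=["score_lo", "score_hi", "n_windows", "n_windows_control"]) \
        .to_csv(out / "block_histogram.tsv", sep="\t", index=False)
    manifest["stages"]["blocks"] = {
        "block_width": config.block_width,
        "n_blocks": int(hist.counts.sum()),
        "outputs": ["block_histogram.tsv"],
    }


def _targets(config, annotation, peaks, out, manifest):
    genic = target_annotation.peak_density(
        target_annotation.genic_regions(annotation, flank=config.flank), peaks,
        threshold=config.density)
    intergenic = target_annotation.peak_density(
        target_annotation.intergenic_regions(annotation, buffer=config.buffer), peaks,
        threshold=config.density)
    targets = target_annotation.classify_targets(annotation, genic, intergenic)
    targets.table.to_csv(out / "targets.tsv", sep="\t", index=False)
    genome_io.write_intervals(target_annotation.regions_to_intervals(genic),
                              out / "genic_regions.bed")
    genome_io.write_intervals(target_annotation.regions_to_intervals(intergenic),
                              out / "intergenic_regions.bed")
    manifest["stages"]["targets"] = {
        "counts": targets.counts(),
        "outputs": ["targets.tsv", "genic_regions.bed", "intergenic_regions.bed"],
    }
    return targets, genic, intergenic


def _families(config, annotation, targets, pvals, out, manifest):
    catalog = fam.FamilyCatalog.from_annotation(annotation)
    clusters = fam.detect_clusters(annotation, catalog, min_run=config.min_run)
    report = fam.family_enrichment(targets, catalog, annotation, clusters)
    clusters.clusters.assign(gene_ids=clusters.clusters["gene_ids"].map(",".join)) \
        .to_csv(out / "clusters.tsv", sep="\t", index=False)
    with open(out / "family_enrichment.json", "w") as handle:
        json.dump(asdict(report) | {"pct_family": report.pct_family,
                                    "pct_clustered": report.pct_clustered},
                  handle, indent=2)
    manifest["stages"]["families"] = {
        "n_clusters": len(clusters), "k": report.k, "n": report.n,
        "pct_family": report.pct_family,
        "outputs": ["clusters.tsv", "family_enrichment.json"],
    }
    return clusters


def _gene_binding_scores(annotation, pvals, flank) -> pd.Series:
    """Mean window score over each gene's genic region."""
    regions = target_annotation.genic_regions(annotation, flank=flank).records
    out = {}
    for row in regions.itertuples():
        s = pvals.score.get(row.chrom)
        if s is None:
            continue
        w0, w1 = row.start // pvals.width, -(-row.end // pvals.width)
        chunk = s[max(w0, 0): min(w1, len(s))]
        out[row.gene_id] = float(chunk.mean()) if len(chunk) else 0.0
    return pd.Series(out, name="binding")


def _expression(config, annotation, targets, clusters, expression, pvals, out, manifest):
    binding = _gene_binding_scores(annotation, pvals, config.flank)
    curve = expr.binding_expression_curve(binding, expression.condition("control"),
                                          bin_size=config.bin_size)
    curve.bins.to_csv(out / "binding_expression_curve.tsv", sep="\t", index=False)
    contrast = expr.target_expression_contrast(
        expression.condition("control"), targets, seed=config.contrast_seed,
        n_resamples=config.n_resamples)
    contrast.to_csv(out / "target_expression_contrast.tsv", sep="\t", index=False)
    calls = expr.classify_deregulated(expression.condition("control"),
                                      expression.condition("kd"),
                                      theta=config.theta, pseudocount=config.pseudocount)
    calls.calls.to_csv(out / "deregulation_calls.tsv", sep="\t")
    catalog = fam.FamilyCatalog.from_annotation(annotation)
    breakdown = expr.deregulation_breakdown(calls, targets, catalog, clusters)
    with open(out / "deregulation_breakdown.json", "w") as handle:
        json.dump(asdict(breakdown), handle, indent=2)
    manifest["stages"]["expression"] = {
        "r": curve.r, "n_deregulated": breakdown.n_deregulated,
        "pct_up": breakdown.pct_up,
        "outputs": ["binding_expression_curve.tsv", "target_expression_contrast.tsv",
                    "deregulation_calls.tsv", "deregulation_breakdown.json"],
    }


def _overlap(config, annotation, peaks, truth, out, manifest):
    # accessibility stand-in: the complement of the planted blocks plays the
    # role of the second (open-chromatin) peak set on synthetic runs
    open_rows = []
    for chrom, size in sorted(annotation.chrom_sizes.items()):
        cursor = 0
        for row in truth.intervals[truth.intervals["chrom"] == chrom] \
                .sort_values("start").itertuples():
            if row.start > cursor:
                open_rows.append((chrom, cursor, row.start))
            cursor = row.end
        if cursor < size:
            open_rows.append((chrom, cursor, size))
    open_set = genome_io.IntervalSet(pd.DataFrame(
        open_rows, columns=["chrom", "start", "end"]))
    report = overlap_stats.exclusivity_test(
        peaks.intervals, open_set, annotation.chrom_sizes,
        n_perm=config.n_perm, seed=config.overlap_seed)
    with open(out / "overlap_report.json", "w") as handle:
        json.dump(report.as_dict(), handle, indent=2)
    manifest["stages"]["overlap"] = {
        "shared": report.shared, "fraction": report.fraction, "p": report.p,
        "outputs": ["overlap_report.json"],
    }
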