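"""Pipeline orchestration: QC -> summaries -> DMC/DMR calling -> enrichment.

A :class:`PipelineConfig` (YAML/JSON file or constructed in code) names the
inputs and carries every analysis threshold with its standard default
(Fisher alpha 0.05; cluster gap <=50 bp; >=8 DMCs; net >=8; coverage >=8;
pooled methylation difference >=0.10; 100-kb windows with a 0.15
differential cut; 0.05/0.95 histogram cuts; loess span 0.10 over 50-bp
bins).  :func:`run_pipeline` runs whichever stages have inputs, writes
machine-readable outputs into the output directory and returns a JSON-able
report with all counts and the exact configuration used.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calling, enrichment, expression, qc, windows
from .io import (
    IntervalTrack,
    MethylomeTable,
    ValidationError,
    pair_methylomes,
    read_interval_track,
    read_site_table,
    write_dmr_bed,
)

logger = logging.getLogger("dmrscan")


@dataclass
class PipelineConfig:
    """Inputs, thresholds and output location for a full run.

    Optional inputs left as None skip their stage with a logged notice.
    """

    # inputs
    young_sites: str | None = None
    old_sites: str | None = None
    dialect: str = "minimal"
    segmentation: str | None = None
    peaks: dict = field(default_factory=dict)  # mark name -> BED path
    annotation: str | None = None  # promoter/gene_body BED
    regions: str | None = None  # external region set (e.g. VMRs)
    delta_ct: str | None = None
    genome_sizes: dict = field(default_factory=dict)  # chrom -> length
    control_contig: str = "chrM"

    # thresholds (standard defaults)
    alpha: float = 0.05
    max_gap: int = 50
    min_dmc: int = 8
    min_net: int = 8
    min_cov: float = 8.0
    min_delta: float = 0.10
    max_width: int = 10_000
    window_size: int = 100_000
    window_min_sites: int = 10
    window_delta_threshold: float = 0.15
    cpg_window_k: int = 5
    cpg_window_step: int = 1
    histogram_bins: int = 20
    histogram_min_cov: int = 1
    flank: int = 5000
    bin_size: int = 50
    loess_span: float = 0.10
    clamp: float = 2.5

    # misc
    outdir: str = "dmrscan_out"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)  # YAML superset covers JSON
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def overridden(self) -> dict:
        """Non-default threshold values, echoed into the report."""
        defaults = PipelineConfig()
        return {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if getattr(self, f.name) != getattr(defaults, f.name)
        }


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(
    config: PipelineConfig,
    young: MethylomeTable | None = None,
    old: MethylomeTable | None = None,
) -> dict:
    """Run all stages whose inputs are available; return the report dict.

    The two methylomes may be passed in memory (e.g. fresh from the
    simulator) instead of via config paths.  Outputs land in
    ``config.outdir``; the report is also written there as ``report.json``.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if young is None or old is None:
        if not config.young_sites or not config.old_sites:
            raise ValidationError("young/old site tables are mandatory inputs")
        young = read_site_table(config.young_sites, dialect=config.dialect, sample="young")
        old = read_site_table(config.old_sites, dialect=config.dialect, sample="old")

    report: dict = {"config": config.to_dict(), "overrides": config.overridden(),
                    "stages": {}, "counts": {}}

    # ---------------- QC ----------------
    qc_out: dict = {}
    for name, table in (("young", young), ("old", old)):
        entry: dict = {"n_sites": len(table)}
        control = table.on_contig(config.control_contig)
        if len(control) and control.sites["n_total"].sum() > 0:
            entry["conversion_rate"] = qc.conversion_rate(control)
        try:
            entry["cpg_specificity"] = qc.cpg_specificity(table)
        except ValidationError:
            logger.info("no non-CpG records for %s; CpG-specificity skipped", name)
        qc_out[name] = entry
    with open(outdir / "qc.json", "w") as fh:
        json.dump(qc_out, fh, indent=2)
    report["stages"]["qc"] = qc_out

    # ---------------- histograms / compartments ----------------
    hist_rows = []
    for name, table in (("young", young), ("old", old)):
        analysable = table.sites[table.sites["chrom"] != config.control_contig]
        tab = MethylomeTable(analysable, sample=name)
        hist = qc.methylation_histogram(
            tab, n_bins=config.histogram_bins, min_cov=config.histogram_min_cov
        )
        hist_rows.append({"sample": name, **hist.summary()})
        report["counts"][f"frac_unmethylated_{name}"] = hist.frac_unmethylated
        report["counts"][f"frac_partial_{name}"] = hist.frac_partial
        report["counts"][f"frac_full_{name}"] = hist.frac_full
    _write_tsv(pd.DataFrame(hist_rows), outdir / "histogram_summary.tsv")

    if config.annotation:
        annotation = read_interval_track(config.annotation, name="annotation")
        comp_rows = []
        for name, table in (("young", young), ("old", old)):
            cm = qc.compartment_means(table, annotation)
            df = cm.as_frame()
            df.insert(0, "sample", name)
            comp_rows.append(df)
        _write_tsv(pd.concat(comp_rows, ignore_index=True), outdir / "compartment_means.tsv")
        report["stages"]["compartments"] = "done"
    else:
        logger.info("no annotation track; compartment means skipped")
        report["stages"]["compartments"] = "skipped"

    # ---------------- pairing and windows ----------------
    pair = pair_methylomes(young, old)
    report["counts"]["n_paired_sites"] = len(pair)
    report["counts"]["n_dropped_young"] = pair.n_dropped_young
    report["counts"]["n_dropped_old"] = pair.n_dropped_old

    gw = windows.genomic_windows(
        pair, size_bp=config.window_size, min_sites=config.window_min_sites
    )
    _write_tsv(gw, outdir / "windows_genomic.tsv")
    n_diff = windows.count_differential_windows(gw, config.window_delta_threshold)
    report["counts"]["n_windows"] = len(gw)
    report["counts"]["n_differential_windows"] = n_diff

    cw = windows.cpg_windows(pair, k=config.cpg_window_k, step=config.cpg_window_step)
    _write_tsv(cw, outdir / "windows_cpg.tsv")
    report["counts"]["n_cpg_windows"] = len(cw)

    # ---------------- DMC / DMR calling ----------------
    dmcs, dmrs = calling.call_dmrs(
        pair,
        alpha=config.alpha,
        max_gap=config.max_gap,
        min_dmc=config.min_dmc,
        min_net=config.min_net,
        min_cov=config.min_cov,
        min_delta=config.min_delta,
        max_width=config.max_width,
    )
    calling.validate_dmrs(
        dmrs,
        min_dmc=config.min_dmc,
        min_net=config.min_net,
        min_cov=config.min_cov,
        min_delta=config.min_delta,
        max_width=config.max_width,
    )
    _write_tsv(dmcs, outdir / "dmcs.tsv")
    _write_tsv(dmrs, outdir / "dmrs.tsv")
    write_dmr_bed(dmrs, outdir / "dmrs.bed")
    report["counts"]["n_dmcs"] = len(dmcs)
    report["counts"]["n_dmrs"] = len(dmrs)
    report["counts"]["n_dmrs_hyper_old"] = int((dmrs["direction"] == "hyper_old").sum())
    report["counts"]["n_dmrs_hypo_old"] = int((dmrs["direction"] == "hypo_old").sum())

    # ---------------- enrichment ----------------
    genome_sizes = dict(config.genome_sizes) or _infer_genome_sizes(pair)
    if config.segmentation and len(dmrs):
        seg = read_interval_track(config.segmentation, name="segmentation")
        enr = enrichment.state_enrichment(dmrs, seg, genome_sizes)
        _write_tsv(enr, outdir / "state_enrichment.tsv")
        report["stages"]["state_enrichment"] = "done"
    else:
        logger.info("segmentation missing or no DMRs; state enrichment skipped")
        report["stages"]["state_enrichment"] = "skipped"

    if config.regions and len(dmrs):
        regions = read_interval_track(config.regions, merge=True, name="regions")
        ov = enrichment.region_overlap_enrichment(dmrs, regions, genome_sizes)
        with open(outdir / "region_enrichment.json", "w") as fh:
            json.dump(dataclasses.asdict(ov), fh, indent=2)
        report["counts"]["region_overlap_fold"] = ov.fold
        report["stages"]["region_enrichment"] = "done"
    else:
        report["stages"]["region_enrichment"] = "skipped"

    if config.peaks and len(dmrs):
        for mark, path in sorted(config.peaks.items()):
            peaks = read_interval_track(path, merge=True, name=mark)
            for direction, sub in dmrs.groupby("direction"):
                prof = enrichment.mark_profile(
                    sub, peaks, flank=config.flank, bin_size=config.bin_size,
                    genome_sizes=genome_sizes, mark=mark, dmr_set=direction,
                )
                prof = enrichment.smooth_profile(prof, span=config.loess_span)
                _write_tsv(prof.as_frame(), outdir / f"profile_{mark}_{direction}.tsv")
        report["stages"]["mark_profiles"] = "done"
    else:
        report["stages"]["mark_profiles"] = "skipped"

    # ---------------- expression validation ----------------
    if config.delta_ct:
        dct = expression.read_delta_ct(config.delta_ct)
        matrix = expression.process_delta_ct(dct, clamp=config.clamp)
        expression.write_matrix(matrix, outdir / "expression_matrix.tsv")
        pvals = expression.gene_pvalues(dct)
        pvals.rename_axis("gene").reset_index().to_csv(
            outdir / "expression_pvalues.tsv", sep="\t", index=False
        )
        report["counts"]["n_genes_tested"] = len(pvals)
        report["counts"]["n_genes_significant"] = int((pvals < 0.05).sum())
        report["stages"]["expression"] = "done"
    else:
        logger.info("no delta-Ct table; expression validation skipped")
        report["stages"]["expression"] = "skipped"

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    return report


def _infer_genome_sizes(pair) -> dict:
    """Fallback genome sizes: last covered position per chromosome."""
    return {
        chrom: int(sub["pos"].max()) + 1
        for chrom, sub in pair.sites.groupby("chrom")
    }


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
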