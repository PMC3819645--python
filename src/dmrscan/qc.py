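"""Bisulfite QC metrics and global methylome summaries.

Covers the bisulfite conversion rate (from an unmethylated control contig,
typically mitochondrial DNA), CpG-specificity of the calls, the bimodal
per-CpG methylation-ratio histogram with its unmethylated/partial/full
three-way split (cuts at 0.05 and 0.95), and genome-compartment mean
methylation (promoters, gene bodies, intergenic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import IntervalTrack, MethylomeTable, ValidationError


def conversion_rate(control_sites: MethylomeTable) -> float:
    """Bisulfite conversion rate from an unmethylated control contig.

    ``1 - sum(n_meth) / sum(n_total)`` over all cytosine records (any
    context) in ``control_sites``; the caller restricts the table to the
    control contig (e.g. ``table.on_contig("chrM")``).  On truly unmethylated
    DNA every C call is a conversion failure, so this fraction estimates the
    per-base conversion efficiency.
    """
    total = int(control_sites.sites["n_total"].sum())
    if total == 0:
        raise ValidationError("control contig has zero total calls")
    meth = int(control_sites.sites["n_meth"].sum())
    return 1.0 - meth / total


def cpg_specificity(table: MethylomeTable) -> float:
    """Fraction of C calls among all calls at non-CpG cytosine positions.

    A small value means methylation calls are CpG-specific: virtually all
    retained (unconverted) cytosines sit in CG context.
    """
    non_cpg = table.sites[table.sites["context"] != "CG"]
    denom = int(non_cpg["n_total"].sum())
    if denom == 0:
        raise ValidationError("no calls at non-CpG positions")
    return int(non_cpg["n_meth"].sum()) / denom


@dataclass
class HistogramResult:
    """Per-bin methylation-ratio fractions plus the bimodal three-way split.

    ``frac_unmethylated`` counts ratios strictly below 0.05,
    ``frac_full`` strictly above 0.95, ``frac_partial`` everything in between
    inclusive of both boundaries.
    """

    edges: np.ndarray
    fractions: np.ndarray
    frac_unmethylated: float
    frac_partial: float
    frac_full: float
    n_sites: int

    def summary(self) -> dict:
        return {
            "n_sites": self.n_sites,
            "frac_unmethylated": self.frac_unmethylated,
            "frac_partial": self.frac_partial,
            "frac_full": self.frac_full,
        }


def ratio_histogram(
    ratios: np.ndarray,
    n_bins: int = 20,
    low_cut: float = 0.05,
    high_cut: float = 0.95,
) -> HistogramResult:
    """Histogram an array of methylation ratios over [0, 1].

    The three-way summary uses strict inequalities at both cuts: a ratio of
    exactly ``low_cut`` or ``high_cut`` counts as partially methylated.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    ratios = np.asarray(ratios, dtype=float)
    ratios = ratios[~np.isnan(ratios)]
    if len(ratios) == 0:
        raise ValidationError("no qualifying sites for histogram")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(ratios, bins=edges)
    fractions = counts / len(ratios)
    unmeth = float(np.mean(ratios < low_cut))
    full = float(np.mean(ratios > high_cut))
    return HistogramResult(
        edges=edges,
        fractions=fractions,
        frac_unmethylated=unmeth,
        frac_partial=1.0 - unmeth - full,
        frac_full=full,
        n_sites=len(ratios),
    )


def methylation_histogram(
    table: MethylomeTable,
    n_bins: int = 20,
    min_cov: int = 1,
    context: str | None = "CG",
) -> HistogramResult:
    """Per-CpG methylation-ratio histogram of covered sites.

    Only sites with ``n_total >= min_cov`` (and, by default, CG context)
    enter; ratios come from the table's counts.
    """
    df = table.sites
    if context is not None:
        df = df[df["context"] == context]
    df = df[df["n_total"] >= max(1, min_cov)]
    return ratio_histogram(df["ratio"].to_numpy(), n_bins=n_bins)


@dataclass
class CompartmentMeans:
    """Mean methylation ratio and site count per genome compartment.

    A site inside both a promoter and a gene-body interval is counted as
    promoter (priority promoter > gene body > intergenic); ``all`` averages
    every site.  Empty compartments are reported as None, not 0.
    """

    means: dict
    counts: dict

    COMPARTMENTS = ("all", "promoter", "gene_body", "intergenic")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "compartment": list(self.COMPARTMENTS),
                "mean_ratio": [self.means.get(c) for c in self.COMPARTMENTS],
                "n_sites": [self.counts.get(c, 0) for c in self.COMPARTMENTS],
            }
        )


def compartment_means(
    table: MethylomeTable,
    annotation: IntervalTrack,
    context: str | None = "CG",
    min_cov: int = 1,
) -> CompartmentMeans:
    """Unweighted per-site mean methylation by genome compartment.

    ``annotation`` carries intervals labelled ``promoter`` and/or
    ``gene_body``; everything else is intergenic.
    """
    extra = set(annotation.labels) - {"promoter", "gene_body"}
    if extra:
        raise ValidationError(f"unexpected annotation labels: {sorted(extra)}")
    df = table.sites
    if context is not None:
        df = df[df["context"] == context]
    df = df[df["n_total"] >= max(1, min_cov)]
    chroms = df["chrom"].to_numpy()
    pos0 = df["pos"].to_numpy() - 1  # 1-based site -> 0-based point
    ratios = df["ratio"].to_numpy()
    in_prom = (
        annotation.contains_points(chroms, pos0, "promoter")
        if "promoter" in annotation.labels
        else np.zeros(len(df), dtype=bool)
    )
    in_body = (
        annotation.contains_points(chroms, pos0, "gene_body")
        if "gene_body" in annotation.labels
        else np.zeros(len(df), dtype=bool)
    )
    assign = np.where(in_prom, "promoter", np.where(in_body, "gene_body", "intergenic"))
    means: dict = {"all": float(np.mean(ratios)) if len(ratios) else None}
    counts: dict = {"all": int(len(ratios))}
    for comp in ("promoter", "gene_body", "intergenic"):
        sel = assign == comp
        counts[comp] = int(sel.sum())
        means[comp] = float(np.mean(ratios[sel])) if sel.any() else None
    return CompartmentMeans(means=means, counts=counts)


def derive_promoters(
    genes: IntervalTrack, upstream: int = 1500, downstream: int = 500
) -> IntervalTrack:
    """Promoter intervals around transcription start sites.

    TSS is the gene start on '+' and the gene end on '-'; the promoter spans
    ``upstream`` bp before to ``downstream`` bp after the TSS, clipped at 0.
    """
    df = genes.intervals
    if "strand" not in df.columns:
        raise ValidationError("gene track lacks strand information")
    minus = df["strand"].to_numpy() == "-"
    tss = np.where(minus, df["end"].to_numpy() - 1, df["start"].to_numpy())
    start = np.where(minus, tss - downstream + 1, tss - upstream)
    end = np.where(minus, tss + upstream + 1, tss + downstream)
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": np.maximum(start, 0),
            "end": end,
            "label": "promoter",
        }
    )
    return IntervalTrack(out, name="promoters")
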