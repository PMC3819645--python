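"""Sliding/tiling window comparisons of two methylomes.

Two flavours: fixed-width genomic tiles (default 100 kb) covering each
chromosome, and windows of k consecutive CpG sites (default 5, sliding by 1).
Both report the unweighted mean methylation ratio per sample and the
old-minus-young difference; windows differing by more than a threshold
(default 0.15) are counted as differential.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import PairedSiteTable

WINDOW_COLUMNS = ["chrom", "start", "end", "n_sites", "mean_young", "mean_old", "delta"]


def genomic_windows(
    pair: PairedSiteTable, size_bp: int = 100_000, min_sites: int = 10
) -> pd.DataFrame:
    """Non-overlapping genomic tiles with per-window mean methylation ratios.

    Tiles start at coordinate 0 on each chromosome; windows holding fewer
    than ``min_sites`` covered CpG sites are omitted.  Means are unweighted
    means over the sites in the window.
    """
    if size_bp <= 0:
        raise ValueError("size_bp must be positive")
    df = pair.sites
    if df.empty:
        return pd.DataFrame(columns=WINDOW_COLUMNS)
    tile = (df["pos"] - 1) // size_bp
    grouped = df.groupby([df["chrom"], tile], sort=True)
    agg = grouped.agg(
        n_sites=("pos", "size"),
        mean_young=("ratio_young", "mean"),
        mean_old=("ratio_old", "mean"),
    ).reset_index(names=["chrom", "tile"])
    agg = agg[agg["n_sites"] >= min_sites].copy()
    agg["start"] = agg["tile"] * size_bp
    agg["end"] = agg["start"] + size_bp
    agg["delta"] = agg["mean_old"] - agg["mean_young"]
    return agg[WINDOW_COLUMNS].reset_index(drop=True)


def cpg_windows(pair: PairedSiteTable, k: int = 5, step: int = 1) -> pd.DataFrame:
    """Windows of k consecutive paired CpG sites, advancing by ``step``.

    Windows never span chromosomes; a chromosome with fewer than k paired
    sites contributes none.  ``start``/``end`` are the 0-based half-open span
    from the first to the last member site.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if step < 1:
        raise ValueError("step must be >= 1")
    frames = []
    for chrom, sub in pair.sites.groupby("chrom", sort=True):
        n = len(sub)
        if n < k:
            continue
        pos = sub["pos"].to_numpy()
        ry = sub["ratio_young"].to_numpy()
        ro = sub["ratio_old"].to_numpy()
        cy = np.concatenate([[0.0], np.cumsum(ry)])
        co = np.concatenate([[0.0], np.cumsum(ro)])
        starts_idx = np.arange(0, n - k + 1, step)
        my = (cy[starts_idx + k] - cy[starts_idx]) / k
        mo = (co[starts_idx + k] - co[starts_idx]) / k
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": pos[starts_idx] - 1,
                    "end": pos[starts_idx + k - 1],
                    "n_sites": k,
                    "mean_young": my,
                    "mean_old": mo,
                    "delta": mo - my,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=WINDOW_COLUMNS)
    return pd.concat(frames, ignore_index=True)[WINDOW_COLUMNS]


def count_differential_windows(windows: pd.DataFrame, threshold: float = 0.15) -> int:
    """Number of windows whose |mean difference| exceeds ``threshold`` (strict)."""
    if windows.empty:
        return 0
    return int((windows["delta"].abs() > threshold).sum())
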