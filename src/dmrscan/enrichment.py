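"""Chromatin-context enrichment of DMRs and histone-mark metaprofiles.

Three analyses:

* fold enrichment of DMR midpoints across a chromatin-state segmentation
  (observed fraction of DMR centers per state divided by the state's genomic
  fraction), computed separately for hyper- and hypomethylated DMRs;
* fold enrichment of DMR overlap with an arbitrary region set (e.g. variably
  methylated regions) against the genome-average expectation;
* binary peak-presence profiles in 50-bp bins around DMR centers, with
  tricube-weighted local-linear (loess) smoothing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import IntervalTrack, ValidationError

UNSEGMENTED = "Unsegmented"


def _midpoints(dmrs: pd.DataFrame) -> np.ndarray:
    return ((dmrs["start"].to_numpy() + dmrs["end"].to_numpy()) // 2).astype(np.int64)


def state_enrichment(
    dmrs: pd.DataFrame,
    segmentation: IntervalTrack,
    genome_sizes: dict[str, int],
) -> pd.DataFrame:
    """Fold enrichment of DMR centers in chromatin states.

    Each DMR is assigned to the state containing its midpoint
    (floor((start+end)/2)); bases not covered by the segmentation count as the
    sentinel state ``Unsegmented`` so that observed fractions sum to 1.  The
    genomic fraction of a state is its merged bp over the total genome bp,
    and ``fold = observed / genomic``.  Computed separately for each DMR
    direction; states with zero genomic bp are reported with missing fold.
    """
    total_bp = sum(genome_sizes.values())
    if total_bp <= 0:
        raise ValidationError("genome_sizes must be positive")
    state_bp = {label: segmentation.total_bp(label) for label in segmentation.labels}
    covered = sum(state_bp.values())
    if covered > total_bp:
        raise ValidationError("segmentation covers more bp than the genome")
    state_bp[UNSEGMENTED] = total_bp - covered
    genomic_frac = {s: bp / total_bp for s, bp in state_bp.items()}

    frames = []
    for direction, sub in dmrs.groupby("direction", sort=True):
        mids = _midpoints(sub)
        labels = segmentation.assign_points(sub["chrom"].to_numpy(), mids)
        labels = np.where(labels == "", UNSEGMENTED, labels)
        n = len(sub)
        for state in sorted(state_bp):
            n_obs = int((labels == state).sum())
            observed = n_obs / n
            gfrac = genomic_frac[state]
            if gfrac == 0:
                assert n_obs == 0, "DMR assigned to a zero-bp state"
                fold = np.nan
            else:
                fold = observed / gfrac
            frames.append((direction, state, n_obs, observed, gfrac, fold))
    return pd.DataFrame(
        frames,
        columns=["direction", "state", "n_dmrs", "observed", "genomic", "fold"],
    )


@dataclass
class OverlapEnrichment:
    """DMR overlap with a region set versus the genome-average expectation."""

    n_dmrs: int
    n_overlap: int
    observed: float  # fraction of DMRs overlapping >=1 region by >=1 bp
    expected: float  # fraction of the genome covered by the regions
    fold: float


def region_overlap_enrichment(
    dmrs: pd.DataFrame,
    regions: IntervalTrack,
    genome_sizes: dict[str, int],
) -> OverlapEnrichment:
    """Fold enrichment of any-overlap between DMRs and a region set.

    ``observed`` is the fraction of DMRs touching at least one region by at
    least 1 bp; ``expected`` is the fraction of genome bp the (merged)
    regions cover; ``fold = observed / expected``.
    """
    region_bp = regions.total_bp(None)
    if region_bp == 0:
        raise ValidationError("region set covers 0 bp")
    total_bp = sum(genome_sizes.values())
    expected = region_bp / total_bp
    hits = regions.overlaps_intervals(
        dmrs["chrom"].to_numpy(), dmrs["start"].to_numpy(), dmrs["end"].to_numpy()
    )
    n_overlap = int(hits.sum())
    observed = n_overlap / len(dmrs) if len(dmrs) else float("nan")
    return OverlapEnrichment(
        n_dmrs=len(dmrs),
        n_overlap=n_overlap,
        observed=observed,
        expected=expected,
        fold=observed / expected,
    )


@dataclass
class MarkProfile:
    """Mean peak presence in fixed-width bins around DMR centers.

    ``offsets`` are bin-center distances (bp) from the DMR midpoint; ``raw``
    is the across-DMR mean of the binary bin-overlaps-a-peak indicator, so it
    lies in [0, 1].  ``smoothed`` is filled by :func:`loess_smooth`.
    """

    offsets: np.ndarray
    raw: np.ndarray
    smoothed: np.ndarray | None = None
    mark: str = ""
    dmr_set: str = ""

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offset": self.offsets,
                "raw": self.raw,
                "smoothed": self.smoothed if self.smoothed is not None else np.nan,
            }
        )


def mark_profile(
    dmrs: pd.DataFrame,
    peaks: IntervalTrack,
    flank: int = 5000,
    bin_size: int = 50,
    genome_sizes: dict[str, int] | None = None,
    mark: str = "",
    dmr_set: str = "",
) -> MarkProfile:
    """Binary peak-presence metaprofile around DMR midpoints.

    For every DMR center c and bin offset, the bin interval
    [c - flank + j*bin, c - flank + (j+1)*bin) scores 1 when it overlaps any
    peak.  The raw profile is the per-bin mean over DMRs; bins running off a
    chromosome end (when ``genome_sizes`` is given) are excluded from that
    DMR's contribution.
    """
    if flank <= 0 or flank % bin_size != 0:
        raise ValueError("flank must be a positive multiple of bin_size")
    if dmrs.empty:
        raise ValidationError("empty DMR set")
    n_bins = 2 * flank // bin_size
    offsets = -flank + bin_size * np.arange(n_bins) + bin_size / 2
    mids = _midpoints(dmrs)
    chroms = dmrs["chrom"].to_numpy()
    total = np.zeros(n_bins)
    denom = np.zeros(n_bins)
    bin_starts_rel = -flank + bin_size * np.arange(n_bins)
    for j in range(n_bins):
        bs = mids + bin_starts_rel[j]
        be = bs + bin_size
        ok = np.ones(len(mids), dtype=bool)
        if genome_sizes is not None:
            lens = np.array([genome_sizes.get(c, np.iinfo(np.int64).max) for c in chroms])
            ok = (bs >= 0) & (be <= lens)
        if not ok.any():
            continue
        hits = peaks.overlaps_intervals(chroms[ok], np.maximum(bs[ok], 0), be[ok])
        total[j] = hits.sum()
        denom[j] = ok.sum()
    raw = np.where(denom > 0, total / np.maximum(denom, 1), np.nan)
    return MarkProfile(offsets=offsets, raw=raw, mark=mark, dmr_set=dmr_set)


def loess_smooth(
    y: np.ndarray,
    x: np.ndarray | None = None,
    span: float = 0.10,
) -> np.ndarray:
    """Locally weighted linear (degree-1, tricube) smoothing.

    At each point the nearest ``max(3, ceil(span * n))`` points (by |x - xi|,
    ties broken by index for determinism) are fitted with a tricube-weighted
    straight line and the fit is evaluated at xi.  Reproduces constants and
    straight lines exactly; deterministic.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise ValidationError("loess needs at least 3 points")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    x = np.arange(n, dtype=float) if x is None else np.asarray(x, dtype=float)
    k = max(3, math.ceil(span * n))
    out = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        order = np.lexsort((np.arange(n), d))
        nbr = order[:k]
        dmax = d[nbr].max()
        if dmax == 0:
            out[i] = y[nbr].mean()
            continue
        w = (1.0 - (d[nbr] / dmax) ** 3) ** 3
        xn, yn = x[nbr], y[nbr]
        sw = w.sum()
        sx = (w * xn).sum()
        sy = (w * yn).sum()
        sxx = (w * xn * xn).sum()
        sxy = (w * xn * yn).sum()
        det = sw * sxx - sx * sx
        if det <= 0 or not np.isfinite(det):
            out[i] = sy / sw
            continue
        b = (sw * sxy - sx * sy) / det
        a = (sy - b * sx) / sw
        out[i] = a + b * x[i]
    return out


def smooth_profile(profile: MarkProfile, span: float = 0.10) -> MarkProfile:
    """Return a copy of ``profile`` with the loess-smoothed signal filled in."""
    finite = np.isfinite(profile.raw)
    smoothed = np.full_like(profile.raw, np.nan)
    if finite.sum() >= 3:
        smoothed[finite] = loess_smooth(
            profile.raw[finite], x=profile.offsets[finite], span=span
        )
    return MarkProfile(
        offsets=profile.offsets,
        raw=profile.raw,
        smoothed=smoothed,
        mark=profile.mark,
        dmr_set=profile.dmr_set,
    )
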