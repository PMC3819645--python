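"""Per-CpG Fisher exact testing and DMC-to-DMR clustering.

The two-sample comparison treats each strand-specific CpG site as a 2x2
contingency table of methylated/unmethylated calls::

                 methylated   unmethylated
    young sample    m_y        t_y - m_y
    old sample      m_o        t_o - m_o

A site with a two-sided Fisher exact p below alpha (default 0.05, no
multiple-testing correction — the region-level clustering is the filter) is a
differentially methylated CpG (DMC).  DMCs are chained along a chromosome
while consecutive gaps stay within ``max_gap`` bp (default 50); a chain is a
DMR candidate when it holds at least ``min_dmc`` DMCs (default 8) whose net
direction |n_up - n_down| is at least ``min_net`` (default 8).  Candidates
are then scored over ALL paired CpGs in their span (not only the DMCs):
pooled methylation difference and mean coverage, with inclusive thresholds
of 0.10 and 8 respectively, and labelled hyper- or hypomethylated in the old
sample by the sign of the pooled difference.

The Fisher test is computed vectorised over sites: for each site the full
hypergeometric support is enumerated and the two-sided p is the sum of point
probabilities not exceeding the observed one (relative tolerance 1e-7, the
usual convention for two-sided Fisher tests on discrete tables).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io import PairedSiteTable

DMC_COLUMNS = [
    "chrom",
    "pos",
    "strand",
    "n_meth_young",
    "n_total_young",
    "n_meth_old",
    "n_total_old",
    "p_value",
    "delta",
    "direction",
]

DMR_COLUMNS = [
    "chrom",
    "start",
    "end",
    "n_dmc",
    "n_up",
    "n_down",
    "net",
    "pooled_delta",
    "mean_coverage",
    "direction",
]

_REL_TOL = 1e-7


def fisher_exact_two_sided(
    m1: np.ndarray,
    t1: np.ndarray,
    m2: np.ndarray,
    t2: np.ndarray,
    chunk: int = 200_000,
) -> np.ndarray:
    """Vectorised two-sided Fisher exact p for tables [[m1, t1-m1], [m2, t2-m2]].

    For each site the hypergeometric distribution with population ``t1+t2``,
    ``m1+m2`` successes and ``t1`` draws is enumerated over its full support;
    the p-value sums the probabilities of all tables whose point probability
    is at most that of the observed table (within relative tolerance 1e-7).
    Equivalent to scipy.stats.fisher_exact(..., alternative="two-sided") but
    computed for many tables at once.
    """
    m1 = np.asarray(m1, dtype=np.int64)
    t1 = np.asarray(t1, dtype=np.int64)
    m2 = np.asarray(m2, dtype=np.int64)
    t2 = np.asarray(t2, dtype=np.int64)
    if np.any(m1 > t1) or np.any(m2 > t2) or np.any(m1 < 0) or np.any(m2 < 0):
        raise ValueError("counts must satisfy 0 <= m <= t")
    n = len(m1)
    out = np.empty(n, dtype=float)
    for lo_idx in range(0, n, chunk):
        sl = slice(lo_idx, min(lo_idx + chunk, n))
        out[sl] = _fisher_chunk(m1[sl], t1[sl], m2[sl], t2[sl])
    return out


def _fisher_chunk(m1, t1, m2, t2) -> np.ndarray:
    N = t1 + t2
    K = m1 + m2
    lo = np.maximum(0, K - t2)
    hi = np.minimum(K, t1)
    width = int((hi - lo).max()) + 1 if len(m1) else 1
    k = lo[:, None] + np.arange(width)[None, :]
    valid = k <= hi[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        pmf = hypergeom.pmf(k, N[:, None], K[:, None], t1[:, None])
        pmf_obs = hypergeom.pmf(m1, N, K, t1)
    pmf = np.where(valid, pmf, np.inf)
    include = pmf <= pmf_obs[:, None] * (1.0 + _REL_TOL)
    p = np.sum(np.where(include & valid, pmf, 0.0), axis=1)
    return np.minimum(p, 1.0)


def call_dmcs(pair: PairedSiteTable, alpha: float = 0.05) -> pd.DataFrame:
    """Differentially methylated CpGs: sites with two-sided Fisher p < alpha.

    Returns a DataFrame (one row per DMC, sorted by chrom/pos/strand) with the
    counts, p-value, methylation difference ``delta = ratio_old - ratio_young``
    and ``direction`` (+1 hypermethylated in old, -1 hypomethylated).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    df = pair.sites
    p = fisher_exact_two_sided(
        df["n_meth_young"].to_numpy(),
        df["n_total_young"].to_numpy(),
        df["n_meth_old"].to_numpy(),
        df["n_total_old"].to_numpy(),
    )
    keep = p < alpha
    out = df.loc[keep, [
        "chrom", "pos", "strand",
        "n_meth_young", "n_total_young", "n_meth_old", "n_total_old", "delta",
    ]].copy()
    out["p_value"] = p[keep]
    # a significant table cannot have identical ratios at these margins
    assert not (out["delta"] == 0).any(), "significant site with zero delta"
    out["direction"] = np.sign(out["delta"]).astype(int)
    return out[DMC_COLUMNS].reset_index(drop=True)


def cluster_dmcs(
    dmcs: pd.DataFrame,
    max_gap: int = 50,
    min_dmc: int = 8,
    min_net: int = 8,
) -> pd.DataFrame:
    """Chain DMCs into candidate clusters.

    A single linear scan per chromosome links consecutive DMCs (strand
    agnostic, positions interleave across strands) whenever the position gap
    is at most ``max_gap`` bp.  A chain survives iff it contains at least
    ``min_dmc`` DMCs and its direction counts satisfy |n_up - n_down| >=
    ``min_net``.  Returns one row per surviving cluster with the 1-based
    first/last member positions and direction tallies; deterministic and
    sorted.
    """
    if dmcs.empty:
        return pd.DataFrame(
            columns=["chrom", "first_pos", "last_pos", "n_dmc", "n_up", "n_down", "net"]
        )
    df = dmcs.sort_values(["chrom", "pos", "strand"], kind="mergesort")
    rows = []
    for chrom, sub in df.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy()
        direction = sub["direction"].to_numpy()
        breaks = np.diff(pos) > max_gap
        cluster_id = np.concatenate([[0], np.cumsum(breaks)])
        for cid in np.unique(cluster_id):
            sel = cluster_id == cid
            n = int(sel.sum())
            n_up = int((direction[sel] > 0).sum())
            n_down = n - n_up
            if n >= min_dmc and abs(n_up - n_down) >= min_net:
                rows.append(
                    (chrom, int(pos[sel].min()), int(pos[sel].max()), n, n_up, n_down,
                     abs(n_up - n_down))
                )
    return pd.DataFrame(
        rows, columns=["chrom", "first_pos", "last_pos", "n_dmc", "n_up", "n_down", "net"]
    )


def score_and_filter_dmrs(
    clusters: pd.DataFrame,
    pair: PairedSiteTable,
    min_cov: float = 8.0,
    min_delta: float = 0.10,
    max_width: int = 10_000,
) -> pd.DataFrame:
    """Score candidate clusters over all paired CpGs in their span and filter.

    ``pooled_delta`` pools counts over every paired site inside the span
    (DMC or not): sum(m_old)/sum(t_old) - sum(m_young)/sum(t_young).
    ``mean_coverage`` averages (t_young + t_old)/2 over those sites.  A DMR is
    kept iff mean_coverage >= ``min_cov`` and |pooled_delta| >= ``min_delta``
    (both inclusive) and its width does not exceed ``max_width`` (a sanity
    bound far above the expected <150 bp scale).  Coordinates become 0-based
    half-open.
    """
    if clusters.empty:
        return pd.DataFrame(columns=DMR_COLUMNS)
    by_chrom = {
        chrom: sub.sort_values("pos")
        for chrom, sub in pair.sites.groupby("chrom", sort=False)
    }
    rows = []
    for row in clusters.itertuples(index=False):
        sub = by_chrom[row.chrom]
        pos = sub["pos"].to_numpy()
        i0 = np.searchsorted(pos, row.first_pos, side="left")
        i1 = np.searchsorted(pos, row.last_pos, side="right")
        span = sub.iloc[i0:i1]
        ty = int(span["n_total_young"].sum())
        to = int(span["n_total_old"].sum())
        pooled_delta = span["n_meth_old"].sum() / to - span["n_meth_young"].sum() / ty
        mean_cov = float(((span["n_total_young"] + span["n_total_old"]) / 2).mean())
        start, end = row.first_pos - 1, row.last_pos
        if mean_cov < min_cov or abs(pooled_delta) < min_delta:
            continue
        if end - start > max_width:
            continue
        assert pooled_delta != 0.0
        rows.append(
            (
                row.chrom, start, end, row.n_dmc, row.n_up, row.n_down, row.net,
                float(pooled_delta), mean_cov,
                "hyper_old" if pooled_delta > 0 else "hypo_old",
            )
        )
    out = pd.DataFrame(rows, columns=DMR_COLUMNS)
    return out.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def call_dmrs(
    pair: PairedSiteTable,
    alpha: float = 0.05,
    max_gap: int = 50,
    min_dmc: int = 8,
    min_net: int = 8,
    min_cov: float = 8.0,
    min_delta: float = 0.10,
    max_width: int = 10_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """End-to-end DMR calling; returns (dmcs, dmrs)."""
    dmcs = call_dmcs(pair, alpha=alpha)
    clusters = cluster_dmcs(dmcs, max_gap=max_gap, min_dmc=min_dmc, min_net=min_net)
    dmrs = score_and_filter_dmrs(
        clusters, pair, min_cov=min_cov, min_delta=min_delta, max_width=max_width
    )
    return dmcs, dmrs


def validate_dmrs(
    dmrs: pd.DataFrame,
    min_dmc: int = 8,
    min_net: int = 8,
    min_cov: float = 8.0,
    min_delta: float = 0.10,
    max_width: int = 10_000,
) -> None:
    """Post-hoc re-check of every emitted DMR against the calling thresholds."""
    if dmrs.empty:
        return
    checks = {
        "n_dmc": (dmrs["n_dmc"] >= min_dmc).all(),
        "net": (dmrs["net"] >= min_net).all(),
        "net_consistent": (dmrs["net"] == (dmrs["n_up"] - dmrs["n_down"]).abs()).all(),
        "coverage": (dmrs["mean_coverage"] >= min_cov).all(),
        "delta": (dmrs["pooled_delta"].abs() >= min_delta).all(),
        "width": ((dmrs["end"] - dmrs["start"]) <= max_width).all(),
        "direction": (
            (dmrs["direction"] == "hyper_old") == (dmrs["pooled_delta"] > 0)
        ).all(),
    }
    failed = [name for name, ok in checks.items() if not ok]
    if failed:
        raise AssertionError(f"DMR invariants violated: {failed}")
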