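"""qRT-PCR delta-Ct processing and two-group rank testing.

Expression of target genes is quantified relative to an endogenous reference
as delta-Ct (target Ct minus reference Ct; higher delta-Ct = lower
expression).  Processing averages replicates per gene/subject, centers each
gene so its mean over subjects is zero, and clamps extreme values at +/-2.5
for display.  Differential expression between the two age groups is assessed
per gene with a two-sided Mann-Whitney U test — exact by enumeration (with
midranks for ties) up to 10 subjects per group, normal approximation with
tie correction above that.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

from .io import ValidationError, _open_text

DELTA_CT_COLUMNS = ["gene", "subject", "group", "replicate", "delta_ct"]


def read_delta_ct(path: str | Path) -> pd.DataFrame:
    """Read a long-format delta-Ct TSV (gene, subject, group, replicate, delta_ct)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DELTA_CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"delta-Ct table lacks columns: {missing}")
    groups = df.groupby("subject")["group"].nunique()
    if (groups > 1).any():
        raise ValidationError("a subject is assigned to more than one group")
    return df[DELTA_CT_COLUMNS]


def process_delta_ct(
    table: pd.DataFrame,
    clamp: float = 2.5,
    symmetric: bool = True,
) -> pd.DataFrame:
    """Replicate-average, per-gene center, and clamp delta-Ct values.

    Returns a gene x subject matrix.  Each gene's mean over subjects is
    subtracted so the age-independent average expression maps to zero; values
    beyond ``clamp`` are set to the clamp (symmetrically at -clamp too unless
    ``symmetric=False``, which clamps only the upper tail).  A gene observed
    in a single subject makes centering degenerate and raises.
    """
    per_subject = (
        table.groupby(["gene", "subject"], sort=True)["delta_ct"].mean().unstack()
    )
    n_subjects = per_subject.notna().sum(axis=1)
    if (n_subjects < 2).any():
        bad = n_subjects[n_subjects < 2].index.tolist()
        raise ValidationError(f"genes with a single subject: {bad}")
    centered = per_subject.sub(per_subject.mean(axis=1), axis=0)
    clamped = centered.clip(upper=clamp)
    if symmetric:
        clamped = clamped.clip(lower=-clamp)
    return clamped


def subject_groups(table: pd.DataFrame) -> pd.Series:
    """Subject -> group mapping from a long-format delta-Ct table."""
    return table.drop_duplicates("subject").set_index("subject")["group"]


def rank_sum_test(
    values: np.ndarray,
    groups: np.ndarray,
    exact_max_n: int = 10,
) -> float:
    """Two-sided Mann-Whitney U p-value for a two-group comparison.

    Exact by complete enumeration of all group assignments (ranks use
    midranks, extremeness is |U - mn/2|) when both groups have at most
    ``exact_max_n`` members; otherwise the tie-corrected normal
    approximation.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValidationError(f"need exactly two groups, got {list(labels)}")
    x = values[groups == labels[0]]
    y = values[groups == labels[1]]
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("a group is empty")
    if max(len(x), len(y)) <= exact_max_n:
        return _exact_mw_p(x, y)
    return float(mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue)


def _exact_mw_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided Mann-Whitney p over all C(n1+n2, n1) group assignments.

    Ranks are midranks (so with ties rank sums are half-integers; doubling
    makes everything integer and the arithmetic exact).  The full null
    distribution of the rank sum is built by dynamic programming —
    equivalent to enumerating every assignment — and the two-sided p is the
    probability of a U at least as far from its null mean n1*n2/2 as the
    observed one.
    """
    n1 = len(x)
    pooled = np.concatenate([x, y])
    ranks2 = np.rint(2 * rankdata(pooled)).astype(np.int64)  # doubled midranks
    total2 = int(ranks2.sum())
    # ways[k, s] = number of k-subsets of the doubled ranks summing to s
    ways = np.zeros((n1 + 1, total2 + 1), dtype=float)
    ways[0, 0] = 1.0
    for r in ranks2:
        ways[1:, r:] += ways[:-1, : total2 + 1 - r]
    mu2 = n1 * len(y)  # doubled null mean of U
    offset2 = n1 * (n1 + 1)
    u2_obs = int(ranks2[:n1].sum()) - offset2
    d_obs = abs(u2_obs - mu2)
    sums = np.arange(total2 + 1)
    extreme = np.abs(sums - offset2 - mu2) >= d_obs
    return float(ways[n1, extreme].sum() / ways[n1].sum())


def gene_pvalues(table: pd.DataFrame, exact_max_n: int = 10) -> pd.Series:
    """Per-gene Mann-Whitney p on replicate-averaged (uncentered) delta-Ct.

    Per-gene centering subtracts a constant per gene and cannot change
    within-gene ranks, so the test is computed on uncentered values.
    """
    per_subject = (
        table.groupby(["gene", "subject"], sort=True)["delta_ct"].mean().unstack()
    )
    groups = subject_groups(table).reindex(per_subject.columns)
    out = {}
    for gene, row in per_subject.iterrows():
        valid = row.notna()
        out[gene] = rank_sum_test(
            row[valid].to_numpy(), groups[valid].to_numpy(), exact_max_n=exact_max_n
        )
    return pd.Series(out, name="p_value")


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        matrix.to_csv(fh, sep="\t")
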