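"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dmrscan.io import IntervalTrack, MethylomeTable, PairedSiteTable


def make_table(rows, sample="", build="synthetic") -> MethylomeTable:
    """Build a MethylomeTable from (chrom, pos, strand, context, n_meth, n_total) rows."""
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "n_meth", "n_total"]
    )
    return MethylomeTable(df, sample=sample, build=build)


def make_pair(rows) -> PairedSiteTable:
    """Build a PairedSiteTable from (chrom, pos, strand, ym, yt, om, ot) rows."""
    df = pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "strand",
            "n_meth_young", "n_total_young", "n_meth_old", "n_total_old",
        ],
    )
    df["ratio_young"] = df["n_meth_young"] / df["n_total_young"]
    df["ratio_old"] = df["n_meth_old"] / df["n_total_old"]
    df["delta"] = df["ratio_old"] - df["ratio_young"]
    df = df.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(
        drop=True
    )
    return PairedSiteTable(df)


def make_track(rows, name="track") -> IntervalTrack:
    """Build an IntervalTrack from (chrom, start, end, label) rows."""
    return IntervalTrack(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "label"]), name=name
    )


@pytest.fixture
def tiny_methylomes():
    """A 5-site young/old pair on one chromosome plus a control contig."""
    young = make_table(
        [
            ("chr1", 100, "+", "CG", 5, 10),
            ("chr1", 101, "-", "CG", 6, 10),
            ("chr1", 200, "+", "CG", 0, 12),
            ("chr1", 300, "+", "CG", 12, 12),
            ("chr1", 400, "+", "CHH", 0, 10),
            ("chrM", 50, "+", "CG", 1, 500),
        ],
        sample="young",
    )
    old = make_table(
        [
            ("chr1", 100, "+", "CG", 9, 10),
            ("chr1", 101, "-", "CG", 8, 10),
            ("chr1", 200, "+", "CG", 1, 10),
            ("chr1", 300, "+", "CG", 11, 11),
            ("chr1", 400, "+", "CHH", 1, 10),
            ("chrM", 50, "+", "CG", 0, 400),
        ],
        sample="old",
    )
    return young, old


@pytest.fixture
def rng():
    return np.random.default_rng(0)
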