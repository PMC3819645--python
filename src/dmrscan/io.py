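"""Readers, writers and containers for per-CpG methylation tables and interval tracks.

Two on-disk dialects are supported for site tables:

``minimal``
    Six tab-separated columns, optional header line::

        chrom  pos  strand  context  n_meth  n_total

    ``pos`` is the 1-based coordinate of the cytosine, ``n_meth`` the number of
    unconverted (C) calls and ``n_total`` the number of C+T calls.

``methratio``
    The output of BSMAP's ``methratio.py``: a headered TSV whose relevant
    columns are ``chr``, ``pos``, ``strand``, ``context``, ``ratio``,
    ``C_count`` and ``CT_count``.  The ratio column is ignored after a
    consistency check; ratios are always recomputed from counts.

Interval tracks (chromatin-state segmentations, ChIP-seq peaks, gene models,
external region sets) are read from BED3/BED4/BED6.  Internally every
coordinate is 0-based half-open; site tables keep 1-based positions on disk.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable

import numpy as np
import pandas as pd

SITE_COLUMNS = ["chrom", "pos", "strand", "context", "n_meth", "n_total"]

_METHRATIO_REQUIRED = ["chr", "pos", "strand", "context", "C_count", "CT_count"]


class SiteTableError(ValueError):
    """Base class for site-table and track IO failures."""


class ParseError(SiteTableError):
    """A line could not be parsed (wrong column count, non-numeric field...)."""


class ValidationError(SiteTableError):
    """Parsed values violate an invariant (counts, ordering, duplicates)."""


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# Methylome tables
# ---------------------------------------------------------------------------

@dataclass
class MethylomeTable:
    """Strand-specific per-cytosine methylation calls for one sample.

    ``sites`` holds one row per (chrom, pos, strand) with integer call counts
    and the derived methylation ratio (NaN where ``n_total`` is 0).  Rows are
    sorted by (chrom, pos, strand) and keys are unique.
    """

    sites: pd.DataFrame
    sample: str = ""
    build: str = ""

    def __post_init__(self) -> None:
        self.sites = _validate_sites(self.sites)

    def __len__(self) -> int:
        return len(self.sites)

    def context_filter(self, context: str = "CG") -> "MethylomeTable":
        """Restrict to one dinucleotide context (default CpG)."""
        sub = self.sites[self.sites["context"] == context].reset_index(drop=True)
        return MethylomeTable(sub, sample=self.sample, build=self.build)

    def on_contig(self, chrom: str) -> "MethylomeTable":
        sub = self.sites[self.sites["chrom"] == chrom].reset_index(drop=True)
        return MethylomeTable(sub, sample=self.sample, build=self.build)


def _validate_sites(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in ("n_meth", "n_total", "pos"):
        df[col] = df[col].astype(np.int64)
    if (df["n_meth"] < 0).any() or (df["n_total"] < 0).any():
        raise ValidationError("negative call counts")
    bad = df["n_meth"] > df["n_total"]
    if bad.any():
        i = int(np.argmax(bad.to_numpy()))
        raise ValidationError(
            f"n_meth > n_total at {df.iloc[i]['chrom']}:{df.iloc[i]['pos']}"
        )
    if not df["strand"].isin(["+", "-"]).all():
        raise ValidationError("strand must be '+' or '-'")
    df = df.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)
    if df.duplicated(["chrom", "pos", "strand"]).any():
        dup = df[df.duplicated(["chrom", "pos", "strand"])].iloc[0]
        raise ValidationError(f"duplicate site {dup['chrom']}:{dup['pos']}{dup['strand']}")
    with np.errstate(invalid="ignore", divide="ignore"):
        df["ratio"] = np.where(
            df["n_total"] > 0, df["n_meth"] / df["n_total"].replace(0, 1), np.nan
        )
    return df[SITE_COLUMNS + ["ratio"]]


def read_site_table(
    path: str | Path,
    dialect: str = "minimal",
    sample: str = "",
    build: str = "",
) -> MethylomeTable:
    """Read a per-cytosine methylation call table.

    Parameters
    ----------
    path : file path (``.gz`` transparently decompressed)
    dialect : ``"minimal"`` or ``"methratio"`` (see module docstring)

    Ratios are always recomputed from counts; in the methratio dialect a
    warning is emitted when the file's own ratio deviates from the recomputed
    one by more than 0.01.
    """
    if dialect not in ("minimal", "methratio"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with _open_text(path) as fh:
        lines = fh.read().splitlines()
    if dialect == "minimal":
        df = _parse_minimal(lines)
    else:
        df = _parse_methratio(lines)
    return MethylomeTable(df, sample=sample, build=build)


def _parse_minimal(lines: list[str]) -> pd.DataFrame:
    rows = []
    start = 0
    if lines and lines[0].split("\t")[0].lower() in ("chrom", "chr", "#chrom"):
        start = 1
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 6:
            raise ParseError(f"line {lineno}: expected 6 columns, got {len(parts)}")
        chrom, pos, strand, context, n_meth, n_total = parts[:6]
        try:
            rows.append((chrom, int(pos), strand, context, int(n_meth), int(n_total)))
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from exc
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


def _parse_methratio(lines: list[str]) -> pd.DataFrame:
    if not lines:
        raise ParseError("empty methratio file")
    header = lines[0].rstrip("\n").split("\t")
    missing = [c for c in _METHRATIO_REQUIRED if c not in header]
    if missing:
        raise ParseError(f"methratio header lacks columns: {missing}")
    idx = {c: header.index(c) for c in header}
    rows = []
    stated = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < len(header):
            raise ParseError(f"line {lineno}: expected {len(header)} columns")
        try:
            rows.append(
                (
                    parts[idx["chr"]],
                    int(parts[idx["pos"]]),
                    parts[idx["strand"]],
                    parts[idx["context"]],
                    int(parts[idx["C_count"]]),
                    int(parts[idx["CT_count"]]),
                )
            )
            stated.append(float(parts[idx["ratio"]]) if "ratio" in idx else np.nan)
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from exc
    df = pd.DataFrame(rows, columns=SITE_COLUMNS)
    stated_arr = np.asarray(stated, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        recomputed = np.where(
            df["n_total"] > 0, df["n_meth"] / df["n_total"].replace(0, 1), np.nan
        )
    off = np.abs(stated_arr - recomputed) > 0.01
    if np.nansum(off) > 0:
        warnings.warn(
            f"{int(np.nansum(off))} methratio rows have a stated ratio deviating "
            "from counts by >0.01; ratios recomputed from counts",
            stacklevel=2,
        )
    return df


def write_site_table(table: MethylomeTable, path: str | Path) -> None:
    """Write a table in the minimal dialect (headered TSV, 1-based positions)."""
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(SITE_COLUMNS) + "\n")
        cols = [table.sites[c].to_numpy() for c in SITE_COLUMNS]
        for row in zip(*cols):
            fh.write("\t".join(str(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Paired tables
# ---------------------------------------------------------------------------

@dataclass
class PairedSiteTable:
    """Position-joined two-sample methylation counts.

    Contains only sites with non-zero total calls in both samples; ``delta``
    is ``ratio_old - ratio_young`` and lies in [-1, 1].  ``n_dropped_young`` /
    ``n_dropped_old`` count the sites present in only one sample.
    """

    sites: pd.DataFrame
    build: str = ""
    n_dropped_young: int = 0
    n_dropped_old: int = 0

    def __len__(self) -> int:
        return len(self.sites)

    def swapped(self) -> "PairedSiteTable":
        """Return the table with the two samples exchanged (negates deltas)."""
        df = self.sites.rename(
            columns={
                "n_meth_young": "n_meth_old",
                "n_total_young": "n_total_old",
                "n_meth_old": "n_meth_young",
                "n_total_old": "n_total_young",
                "ratio_young": "ratio_old",
                "ratio_old": "ratio_young",
            }
        ).copy()
        df["delta"] = df["ratio_old"] - df["ratio_young"]
        return PairedSiteTable(
            df[list(self.sites.columns)],
            build=self.build,
            n_dropped_young=self.n_dropped_old,
            n_dropped_old=self.n_dropped_young,
        )


def pair_methylomes(
    young: MethylomeTable, old: MethylomeTable, context: str | None = "CG"
) -> PairedSiteTable:
    """Inner-join two methylomes on (chrom, pos, strand).

    Sites covered (n_total > 0) in only one sample are dropped, as are
    zero-coverage records.  ``context`` restricts to one dinucleotide context
    before joining (``None`` keeps all contexts).
    """
    if young.build != old.build:
        raise ValidationError(
            f"genome build mismatch: {young.build!r} vs {old.build!r}"
        )
    a = young.sites
    b = old.sites
    if context is not None:
        a = a[a["context"] == context]
        b = b[b["context"] == context]
    a = a[a["n_total"] > 0]
    b = b[b["n_total"] > 0]
    merged = a.merge(
        b,
        on=["chrom", "pos", "strand"],
        how="inner",
        suffixes=("_young", "_old"),
    )
    if merged.empty:
        raise ValidationError("no sites covered in both samples")
    merged = merged.rename(
        columns={"ratio_young": "ratio_young", "ratio_old": "ratio_old"}
    )
    out = merged[
        [
            "chrom",
            "pos",
            "strand",
            "n_meth_young",
            "n_total_young",
            "n_meth_old",
            "n_total_old",
            "ratio_young",
            "ratio_old",
        ]
    ].copy()
    out["delta"] = out["ratio_old"] - out["ratio_young"]
    out = out.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(
        drop=True
    )
    return PairedSiteTable(
        out,
        build=young.build,
        n_dropped_young=len(a) - len(out),
        n_dropped_old=len(b) - len(out),
    )


# ---------------------------------------------------------------------------
# Interval tracks
# ---------------------------------------------------------------------------

@dataclass
class IntervalTrack:
    """Labelled genomic intervals, 0-based half-open.

    Wraps a DataFrame with columns chrom, start, end, label (and optionally
    strand).  ``merged()`` collapses overlapping/adjacent same-label intervals;
    point and interval queries operate on the merged representation.
    """

    intervals: pd.DataFrame
    name: str = ""
    _merged_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        df = self.intervals.copy()
        for col in ("start", "end"):
            df[col] = df[col].astype(np.int64)
        if (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]].iloc[0]
            raise ValidationError(
                f"interval start >= end: {bad['chrom']}:{bad['start']}-{bad['end']}"
            )
        if (df["start"] < 0).any():
            raise ValidationError("negative interval start")
        self.intervals = df.sort_values(
            ["chrom", "start", "end"], kind="mergesort"
        ).reset_index(drop=True)
        self._merged_cache = {}

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def labels(self) -> list[str]:
        return sorted(self.intervals["label"].unique())

    def merged(self, label: str | None = None) -> pd.DataFrame:
        """Merged (disjoint, sorted) intervals, optionally for one label.

        Adjacent and overlapping same-label intervals are unioned.
        """
        key = label
        if key in self._merged_cache:
            return self._merged_cache[key]
        df = self.intervals
        if label is not None:
            df = df[df["label"] == label]
        out = merge_intervals(df)
        self._merged_cache[key] = out
        return out

    def total_bp(self, label: str | None = None) -> int:
        m = self.merged(label)
        return int((m["end"] - m["start"]).sum())

    def contains_points(
        self, chroms: np.ndarray, positions: np.ndarray, label: str | None = None
    ) -> np.ndarray:
        """Boolean mask: is each 0-based point inside a (label-restricted) interval."""
        m = self.merged(label)
        out = np.zeros(len(chroms), dtype=bool)
        chroms = np.asarray(chroms)
        positions = np.asarray(positions)
        for chrom, sub in m.groupby("chrom", sort=False):
            sel = chroms == chrom
            if not sel.any():
                continue
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            p = positions[sel]
            idx = np.searchsorted(starts, p, side="right") - 1
            ok = (idx >= 0) & (p < ends[np.clip(idx, 0, len(ends) - 1)])
            out[sel] = ok
        return out

    def assign_points(self, chroms: np.ndarray, positions: np.ndarray) -> np.ndarray:
        """Label each 0-based point by the interval containing it.

        Requires a disjoint track (e.g. a segmentation); where intervals of
        different labels overlap the earliest-starting one wins.  Points in no
        interval get the empty string.
        """
        m = merge_free_sorted(self.intervals)
        out = np.full(len(chroms), "", dtype=object)
        chroms = np.asarray(chroms)
        positions = np.asarray(positions)
        for chrom, sub in m.groupby("chrom", sort=False):
            sel = chroms == chrom
            if not sel.any():
                continue
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            labels = sub["label"].to_numpy()
            p = positions[sel]
            idx = np.searchsorted(starts, p, side="right") - 1
            idxc = np.clip(idx, 0, len(ends) - 1)
            ok = (idx >= 0) & (p < ends[idxc])
            lab = np.where(ok, labels[idxc], "")
            out[sel] = lab
        return out

    def overlaps_intervals(
        self, chroms: np.ndarray, starts: np.ndarray, ends: np.ndarray
    ) -> np.ndarray:
        """Boolean mask: does each query interval overlap any track interval by >=1 bp."""
        m = self.merged(None)
        out = np.zeros(len(chroms), dtype=bool)
        chroms = np.asarray(chroms)
        qs = np.asarray(starts)
        qe = np.asarray(ends)
        for chrom, sub in m.groupby("chrom", sort=False):
            sel = chroms == chrom
            if not sel.any():
                continue
            ts = sub["start"].to_numpy()
            te = sub["end"].to_numpy()
            # rightmost track interval starting before the query's end
            idx = np.searchsorted(ts, qe[sel], side="left") - 1
            idxc = np.clip(idx, 0, len(te) - 1)
            out[sel] = (idx >= 0) & (te[idxc] > qs[sel])
        return out


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union overlapping or adjacent intervals per (chrom, label)."""
    if df.empty:
        return df.reset_index(drop=True)[["chrom", "start", "end", "label"]]
    try:
        import pyranges as pr

        g = pr.PyRanges(
            df.rename(
                columns={"chrom": "Chromosome", "start": "Start", "end": "End"}
            )[["Chromosome", "Start", "End", "label"]]
        )
        merged = g.merge(by="label").df
        out = merged.rename(
            columns={"Chromosome": "chrom", "Start": "start", "End": "end"}
        )[["chrom", "start", "end", "label"]]
        out["chrom"] = out["chrom"].astype(str)
    except Exception:  # pragma: no cover - pyranges always present in practice
        out = _merge_intervals_np(df)
    return (
        out.sort_values(["chrom", "start", "end"], kind="mergesort")
        .reset_index(drop=True)
        .astype({"start": np.int64, "end": np.int64})
    )


def _merge_intervals_np(df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (chrom, label), sub in df.groupby(["chrom", "label"], sort=False):
        sub = sub.sort_values("start")
        cur_s, cur_e = None, None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e, label))
                cur_s, cur_e = s, e
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e, label))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])


def merge_free_sorted(df: pd.DataFrame) -> pd.DataFrame:
    """Sort a (presumed disjoint) labelled track without merging labels."""
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
        drop=True
    )


def read_interval_track(
    path: str | Path,
    label_source: str = "name_column",
    fixed_label: str = "region",
    merge: bool = False,
    name: str = "",
) -> IntervalTrack:
    """Read a BED3+ file into an IntervalTrack.

    ``label_source="name_column"`` takes labels from BED column 4 (falling
    back to ``fixed_label`` for 3-column lines); ``"fixed"`` labels every
    interval with ``fixed_label``.  With ``merge=True`` overlapping/adjacent
    same-label intervals are unioned on load.
    """
    if label_source not in ("name_column", "fixed"):
        raise ValueError(f"unknown label_source {label_source!r}")
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"line {lineno}: expected >=3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-numeric coordinates") from exc
            if start >= end:
                raise ValidationError(f"line {lineno}: start >= end ({start} >= {end})")
            if label_source == "name_column" and len(parts) >= 4 and parts[3]:
                label = parts[3]
            else:
                label = fixed_label
            strand = parts[5] if len(parts) >= 6 else "."
            rows.append((chrom, start, end, label, strand))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "label", "strand"])
    if merge:
        df = merge_intervals(df)
        df["strand"] = "."
    return IntervalTrack(df, name=name or str(path))


def write_interval_track(track: IntervalTrack, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for row in track.intervals.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.label}\n")


def write_dmr_bed(dmrs: pd.DataFrame, path: str | Path) -> None:
    """Write called DMRs as BED6.

    Name is a sequential DMR id, score is 1000*|pooled_delta| clamped to
    [0, 1000], strand is '.'.
    """
    with _open_text(path, "wt") as fh:
        for i, row in enumerate(dmrs.itertuples(index=False), start=1):
            score = int(round(min(1000, max(0, 1000 * abs(row.pooled_delta)))))
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\tDMR_{i:05d}\t{score}\t.\n"
            )
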