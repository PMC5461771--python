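"""Readers and writers for the tabular formats the pipeline touches.

Per-CpG methylation-call tables come in two tab-delimited dialects:

``methratio``
    chrom, 1-based position, strand, unconverted-C reads, total reads —
    the shape produced by methratio-style extraction from bisulfite
    alignments.
``coverage``
    Bismark-coverage-style: chrom, start, end, percent methylated,
    methylated count, unmethylated count.  The percent column is ignored
    and recomputed from counts.

Internal coordinates are 1-based inclusive throughout; only BED output
converts to 0-based half-open.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CpGSiteCall",
    "SampleTable",
    "read_methcalls",
    "write_methcalls",
    "write_dmrs_bed",
    "write_table",
    "chrom_order",
]

CALL_COLUMNS = ["chrom", "pos", "strand", "unconverted", "total"]


@dataclass(frozen=True)
class CpGSiteCall:
    """One CpG locus with unconverted / total bisulfite read counts."""

    chrom: str
    pos: int
    strand: str
    unconverted: int
    total: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.unconverted < 0 or self.total < 0:
            raise ValueError("counts must be non-negative")
        if self.unconverted > self.total:
            raise ValueError(
                f"unconverted ({self.unconverted}) exceeds total ({self.total})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def ratio(self) -> float:
        """Methylation ratio unconverted/total; NaN when uncovered."""
        return self.unconverted / self.total if self.total > 0 else math.nan


@dataclass
class SampleTable:
    """All CpG calls of one sample, sorted by (chrom, pos).

    ``calls`` is a DataFrame with columns chrom, pos, strand, unconverted,
    total.  Chromosomes keep their input (karyotype) order of first
    appearance; within a chromosome positions are strictly increasing per
    strand.  Zero-coverage rows are retained (``total == 0``) so that
    downstream filters, not the reader, decide exclusion.
    """

    sample_id: str
    condition: str = "control"
    sex: str = "U"
    calls: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=CALL_COLUMNS))

    def __post_init__(self) -> None:
        if self.condition not in ("carrier", "control"):
            raise ValueError(f"condition must be 'carrier' or 'control', got {self.condition!r}")
        self.calls = _validate_calls(self.calls)

    @property
    def n_sites(self) -> int:
        return len(self.calls)

    def ratios(self) -> pd.Series:
        tot = self.calls["total"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = self.calls["unconverted"].to_numpy(dtype=float) / tot
        return pd.Series(np.where(tot > 0, r, np.nan), index=self.calls.index, name="ratio")


def chrom_order(chroms: Iterable[str]) -> list[str]:
    """Order of first appearance — the pipeline's deterministic chromosome order."""
    seen: dict[str, None] = {}
    for c in chroms:
        seen.setdefault(c, None)
    return list(seen)


def _validate_calls(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CALL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"calls table missing column(s): {missing}")
    df = df[CALL_COLUMNS].reset_index(drop=True)
    if len(df) == 0:
        return df
    if (df["pos"] < 1).any():
        raise ValueError("positions must be >= 1")
    if (df["unconverted"] < 0).any() or (df["total"] < 0).any():
        raise ValueError("counts must be non-negative")
    if (df["unconverted"] > df["total"]).any():
        raise ValueError("unconverted exceeds total")
    order = chrom_order(df["chrom"])
    df = df.assign(_c=pd.Categorical(df["chrom"], categories=order, ordered=True))
    df = df.sort_values(["_c", "pos", "strand"], kind="mergesort").drop(columns="_c")
    if df.duplicated(subset=["chrom", "pos", "strand"]).any():
        dup = df[df.duplicated(subset=["chrom", "pos", "strand"], keep=False)].iloc[0]
        raise ValueError(
            f"duplicate call at {dup['chrom']}:{dup['pos']}({dup['strand']})"
        )
    return df.reset_index(drop=True)


def _parse_int(token: str, what: str, lineno: int) -> int:
    try:
        v = int(token)
    except ValueError:
        raise ValueError(f"line {lineno}: {what} is not an integer: {token!r}") from None
    return v


def read_methcalls(
    path: str | os.PathLike,
    dialect: str = "methratio",
    *,
    sample_id: str | None = None,
    condition: str = "control",
    sex: str = "U",
    collapse_strands: bool = False,
) -> SampleTable:
    """Read a per-CpG methylation-call table into a :class:`SampleTable`.

    A header line is auto-detected (non-numeric position field).  Rows are
    re-sorted; the input order is not trusted.  Malformed rows (wrong
    column count, negative counts, unconverted > total) raise ``ValueError``
    naming the line number, as do duplicate (chrom, pos, strand) rows.

    Parameters
    ----------
    dialect
        ``"methratio"`` (chrom, pos, strand, unconverted, total) or
        ``"coverage"`` (chrom, start, end, percent, methylated count,
        unmethylated count; strand recorded as ``+``).
    collapse_strands
        Merge a minus-strand call at position ``p`` into the plus-strand
        call of the same CpG dinucleotide at ``p - 1`` by summing counts.
        Off by default: no collapsing rule is assumed.
    """
    if dialect not in ("methratio", "coverage"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    ncols = 5 if dialect == "methratio" else 6
    pos_col = 1
    rows: list[tuple[str, int, str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if lineno == 1 and len(parts) >= 2 and not parts[pos_col].strip().lstrip("-").isdigit():
                continue  # header
            if len(parts) != ncols:
                raise ValueError(
                    f"line {lineno}: expected {ncols} tab-delimited columns, got {len(parts)}"
                )
            if dialect == "methratio":
                chrom, pos_s, strand, unc_s, tot_s = parts
                pos = _parse_int(pos_s, "position", lineno)
                unc = _parse_int(unc_s, "unconverted count", lineno)
                tot = _parse_int(tot_s, "total count", lineno)
                if strand not in ("+", "-"):
                    raise ValueError(f"line {lineno}: strand must be '+' or '-', got {strand!r}")
            else:
                chrom, start_s, _end_s, _pct, meth_s, unmeth_s = parts
                pos = _parse_int(start_s, "start position", lineno)
                unc = _parse_int(meth_s, "methylated count", lineno)
                unmeth = _parse_int(unmeth_s, "unmethylated count", lineno)
                if unmeth < 0:
                    raise ValueError(f"line {lineno}: negative unmethylated count")
                tot = unc + unmeth
                strand = "+"
            if pos < 1:
                raise ValueError(f"line {lineno}: position must be >= 1")
            if unc < 0 or tot < 0:
                raise ValueError(f"line {lineno}: negative count")
            if unc > tot:
                raise ValueError(f"line {lineno}: unconverted ({unc}) exceeds total ({tot})")
            rows.append((chrom, pos, strand, unc, tot))
    df = pd.DataFrame(rows, columns=CALL_COLUMNS)
    if collapse_strands:
        df = _collapse_strands(df)
    sid = sample_id if sample_id is not None else os.path.splitext(os.path.basename(path))[0]
    return SampleTable(sample_id=sid, condition=condition, sex=sex, calls=df)


def _collapse_strands(df: pd.DataFrame) -> pd.DataFrame:
    """Sum the '-' call at pos p into the '+' call at p-1 of the same CpG."""
    plus = df[df["strand"] == "+"].set_index(["chrom", "pos"])
    minus = df[df["strand"] == "-"]
    merged_rows = []
    leftover = []
    for row in minus.itertuples(index=False):
        key = (row.chrom, row.pos - 1)
        if key in plus.index:
            plus.loc[key, "unconverted"] += row.unconverted
            plus.loc[key, "total"] += row.total
        else:
            leftover.append(row)
    merged_rows.append(plus.reset_index())
    if leftover:
        merged_rows.append(pd.DataFrame(leftover, columns=CALL_COLUMNS))
    out = pd.concat(merged_rows, ignore_index=True)
    return out[CALL_COLUMNS]


def write_methcalls(table: SampleTable, path: str | os.PathLike, header: bool = True) -> None:
    """Write a SampleTable in the methratio dialect (round-trip safe)."""
    df = table.calls[CALL_COLUMNS]
    df.to_csv(path, sep="\t", index=False, header=header)


def write_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write any result table tab-delimited with a header, NaN as 'NA'."""
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def bed_score(min_p: float) -> int:
    """BED score: min(1000, round(-10*log10(min block P))); 0 when undefined."""
    if min_p is None or not np.isfinite(min_p):
        return 0
    if min_p <= 0:
        return 1000
    return int(min(1000, round(-10.0 * math.log10(min_p))))


def write_dmrs_bed(dmrs: Sequence, path: str | os.PathLike) -> None:
    """Write DMR calls as BED6+2 (0-based half-open intervals).

    Columns: chrom, start-1, end, name, score, '.', n_dmbs, mean_delta.
    The score encodes the best member-block P value as
    ``min(1000, round(-10*log10(P)))``.  An empty collection yields an
    empty file with no header.
    """
    lines = []
    for i, dmr in enumerate(dmrs, start=1):
        region = dmr.region
        score = bed_score(dmr.min_p)
        delta = "NA" if dmr.mean_delta is None or not np.isfinite(dmr.mean_delta) else f"{dmr.mean_delta:.4f}"
        lines.append(
            f"{region.chrom}\t{region.start - 1}\t{region.end}\tDMR{i}\t{score}\t.\t"
            f"{region.n_dmbs}\t{delta}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
        if lines:
            fh.write("\n")
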